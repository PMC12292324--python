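# Methods

## The model

`stnsim` simulates a single subthalamic-nucleus (STN) projection neuron as
a hybrid of a conductance-based membrane model and a threshold/reset spike
rule, bombarded by Poisson synaptic input, with pair-based
spike-timing-dependent plasticity (STDP) acting on the excitatory peak
conductances.

### Membrane equation

The subthreshold membrane potential follows a Langevin equation driven by
six intrinsic currents, the synaptic current, an applied current with
additive Gaussian white noise, and optionally a sinusoidal DBS current:

    dV = [ -I_L - I_Na - I_K - I_T - I_Ca - I_AHP
           - g_E (V - E_E) - g_I (V - E_I) + I_dbs + mu_app ] dt
         + sigma_app dW

with

    I_L   = g_L (V - E_L)
    I_Na  = g_Na m_inf(V)^3 h (V - E_Na)
    I_K   = g_K n^4 (V - E_K)
    I_T   = g_T a_inf(V)^3 b_inf(r)^2 r (V - E_T)
    I_Ca  = g_Ca c^2 (V - E_Ca)
    I_AHP = g_AHP (V - E_AHP) Ca / (Ca + k1)

The gating variables h, n, r, c relax to their logistic steady states with
voltage-dependent time constants and the rate scalars phi = 0.75, 0.75,
0.2, 0.08; intracellular calcium obeys
d(Ca)/dt = eps (I_Ca - I_T - k_Ca Ca) with eps = 3.75e-5, k_Ca = 22.5/ms.
Sodium activation m, and the T-current activations a and b, are treated as
instantaneous.  A spike is recorded whenever V crosses V_th = -55 mV; V is
reset to -70 mV and the neuron enters a refractory period
t_ref = mu_ref + sigma_ref * N(0,1), clipped at zero.  During
refractoriness the membrane is clamped at the reset potential while
gating, calcium, conductances and plasticity traces keep evolving
(`refractory_mode="clamp"`; an `"integrate"` variant that lets V evolve
spike-suppressed is config-selectable).

Everything is integrated by forward Euler at dt = 0.1 ms; the noise term
uses the Euler-Maruyama increment sigma_app*sqrt(dt)*N(0,1)
(`noise_scheme="euler_maruyama"`; a piecewise-constant-current variant is
selectable).

### Units and the effective capacitance

Conductance-times-voltage products (nS * mV) are treated as currents in
pA and time is in ms.  The Euler update uses an *effective* capacitance
of 1, i.e. dV = dt * (sum of currents): with a literal 10 nF capacitance
and currents of tens of pA the membrane time scale would be seconds, four
orders of magnitude slower than the millisecond-scale firing this model
is meant to produce (roughly 150 spikes/s at the healthy operating
point).  The unit bookkeeping is therefore nominal, which is common in
reduced models of this family; `cm` remains a parameter.

### Synaptic input

20 excitatory and 80 inhibitory presynaptic trains fire as Bernoulli
approximations of 10 Hz Poisson processes (per-bin probability
rate * dt).  Each excitatory spike at synapse i adds that synapse's peak
conductance g_i to the pooled conductance g_E (tau_E = 2 ms); inhibitory
spikes add a fixed 0.5 nS to g_I (tau_I = 5 ms).  Reversal potentials are
not part of the published parameter set; the package uses E_E = 0 mV
(AMPA) and E_I = -65 mV, i.e. shunting GABA-A inhibition at the chloride
reversal.  This choice was calibrated: with strongly hyperpolarising
inhibition (E_I = -80 mV) the model cannot reach the reported ~150
spikes/s of the healthy cell at t_ref = 6 ms, while at E_I = -65 mV the
healthy plateau (~151 spikes), the PD refractory-noise plateau (~135
spikes) and the human/animal firing-rate/CV statistics are all
reproduced simultaneously.  Both reversals are configurable.

### Plasticity

The pair-based STDP rule is implemented online with exponential traces:
a postsynaptic trace M <= 0 (decay tau_minus, decremented by A_minus at
each postsynaptic spike) and one presynaptic trace P_i >= 0 per synapse
(decay tau_plus, incremented by A_plus at each spike of neuron i).  At a
presynaptic spike, w_i += M * g_max (depression); at a postsynaptic
spike, w_i += P_i * g_max for every synapse (potentiation).  Weights are
hard-clipped to [0, g_max] with g_max = 1.5 nS (the initial excitatory
peak conductance, so weights start at the ceiling).  For isolated spike
pairs this reproduces the closed-form biphasic window
dW = A_plus exp(dt_pair/tau_plus) (pre-before-post) and
-A_minus exp(-dt_pair/tau_minus) (post-before-pre); simultaneous spikes
change nothing.

The window amplitudes and time constants are not part of the published
parameter set.  Defaults: A_plus = 0.005, tau_plus = 20 ms,
A_minus = 0.0105, tau_minus = 30 ms.  The pair was chosen
depression-dominant (A_minus tau_minus > A_plus tau_plus); a
rate-balanced pair (e.g. A_minus tau_minus = A_plus tau_plus) produces no
net weight drift under Poisson firing and hence no measurable plasticity
effect in one-second trials, which would contradict the reported
reductions of spike count and interspike-interval variability under
STDP.  A_minus lies inside the range swept by the sensitivity analysis
(0.001-0.02).

### Randomness

Each run derives named, independent RNG streams (excitatory trains,
inhibitory trains, membrane noise, refractory jitter, shared/private
injected currents) from one seed, so toggling a noise source never
shifts another stream's draws, and every result is bit-reproducible from
its config.

## Study conditions

* healthy cell: I_app = 33 pA; Parkinsonian cell: I_app = 23 pA.
* simulation-based conditions: t_ref = 6 ms.
* human-fitted PD condition: t_ref = 21 ms, sigma_app = sigma_ref = 8.
* animal-fitted PD condition: t_ref = 28 ms, sigma_app = sigma_ref = 18.
* trial protocol: 10 one-second trials (T = 1000 ms), trial k seeded
  with base_seed + k; the plastic and non-plastic arms share per-trial
  seeds (paired design, which removes input variance from the contrast).
  T = 1000 ms makes the reported firing rate (Hz) and spike count
  numerically equal, as in the reference tables.
* statistics: CV_ISI = population SD of the ISIs over their mean
  (undefined, reported as NaN, below three spikes); Welch two-sample
  t-test at alpha = 0.05 for condition contrasts.

## Correlation transfer

The two-neuron experiment injects currents
I_i = mu + sigma (sqrt(1-c) xi_i + sqrt(c) xi_c) into two unconnected
model neurons (the square-root mixing keeps the variance c-independent,
so the input correlation equals c; the literal linear mixing is
config-selectable).  Output correlation is the plain sums-of-products
correlation of 10-ms binned spike counts.

Three protocol choices matter and are deliberate:

* The Poisson bombardment is disabled: it is an independent noise source
  an order of magnitude stronger than the injected currents and would
  mask the transfer entirely.
* The neuron is placed at a fluctuation-driven operating point
  (mu = -5 pA, sigma = 4 pA, calcium started at its operating value
  ~0.03, first 500 ms discarded).  At the strongly driven PD/healthy
  operating points spike timing is pinned by the refractory period and
  output correlations vanish; in addition the slow calcium transient
  (time constant ~1.2 s) otherwise produces a shared firing-rate ramp
  that masquerades as correlation.
* The default mixing grid is c in {0, 0.2, 0.4, 0.6, 0.8}.  At c = 1
  the two neurons receive literally identical input and reproduce each
  other's spike train; that duplication limit (r_out -> 1) is a
  reliability phenomenon, not correlation transfer, and breaks the
  linearity that holds on [0, 0.8].

With these choices the transfer curve is approximately linear
(R^2 > 0.9, slope ~0.56) and lies below the identity line, i.e. the
neuron attenuates input correlations.

## What the synthetic conditions do and do not show

All inputs are generated internally (Poisson trains, Gaussian noise,
Gaussian refractory jitter); no recorded data enters the pipeline.  The
tests therefore demonstrate internal consistency of the model and
reproduction of the published simulation statistics, not agreement with
electrophysiological recordings; the published comparison to patient and
animal firing statistics is inherited only through the printed reference
values.  Poisson bombardment has no autocorrelation structure, unlike
real cortical/pallidal input, and the single-compartment cell has no
network feedback.

## Numerical choices and degenerate inputs

* dt = 0.1 ms everywhere; conductance and trace decays use the Euler
  factor (1 - dt/tau).
* Calcium is clamped at zero if the balance equation undershoots (the
  printed influx sign makes Ca -> 0 possible); clamp events are counted
  on the result object.  The classic influx sign is config-selectable.
* Negative sampled refractory periods are clipped to zero and counted.
* The T-current is implemented exactly as printed (including the extra
  factor r and E_T = 0); the classic Rubin-Terman form is selectable via
  `t_current_variant`.
* Spike times are reported at (step+1)*dt; integer step indices are also
  exposed so that exact-periodicity checks are not subject to float
  rounding of k*dt.
* Fewer than three spikes: CV_ISI is NaN (distinct from the exact 0 of a
  periodic train).  Zero-variance series: correlation is NaN.

## Known limitations

* The effective-capacitance and reversal-potential choices are a
  calibration of under-specified constants, not measurements; other
  (cm, E_I) pairs can produce the same statistics.
* In the human/animal table protocols the STDP effect on the *spike
  count* is below integer resolution in one-second trials (the arms can
  tie exactly under paired seeds); the CV_ISI reduction is reproduced,
  and clear count reductions appear in the short-refractory (t_ref=6 ms)
  noisy conditions.
* The depression sweep reproduces the direction and approximate endpoint
  counts, but not the full printed dynamic range (printed 155 -> 143 and
  154 -> 141; the model gives a shallower decline from a slightly lower
  healthy baseline and a clearly lower Parkinsonian baseline ~133).
  Matching the printed Parkinsonian zero-noise baseline (~150) and the
  printed noise-plateau (~135) simultaneously is not possible in this
  architecture: the published pair implies a 10% spike-count drop caused
  by refractory jitter alone, which a hard refractory floor with
  mean-preserving jitter cannot produce.
* No temperature dependence, channel stochasticity (beyond the additive
  current noise), multi-compartment morphology, or network coupling.
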