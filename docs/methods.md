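# Methods

## The model

The package simulates a local sensory-cortex circuit as a recurrent
network of `N = 2000` leaky integrate-and-fire neurons (`NE = 1600`
excitatory, `NI = 400` inhibitory) with exponential synapses.  Membrane
potentials obey

    tau_m dV/dt = -V + tau_m (I_rec + I_bg + I_stim),

with threshold `V_th`, reset `V_r`, and absolute refractory period
`tau_ref`; recurrent and background currents are low-pass filtered spike
trains with time constants `tau_syn,E` and `tau_syn,I`.  Background drive
is, per cell, the superposition of `C_ext` independent Poisson synapses,
implemented as a single Poisson process of the summed rate (statistically
identical because the synapses are independent and equally weighted).

Two architectures are built with identical summed synaptic weight:

* **uniform** - fixed in-degree random connectivity with homogeneous
  weights `J_ab`;
* **clustered** - `p = 18` non-overlapping assemblies containing a
  fraction `f = 0.05` of each population; within-assembly weights are
  potentiated (`J+_ab`), between-assembly and assembly-background weights
  are depressed to the unique value `J-_ab` that conserves the total
  weight, and background-background weights stay at `J_ab`.

Arousal enters as a modification of the background input rates: a uniform
mean increase (`nu_ext = nu0 (1 + Delta_M)`) or a quenched across-cell
spread (`nu_ext = nu0 + z * Delta_H * nu0`, `z ~ N(0,1)`, clipped at
zero).  Every assembly experiences the same realization of the quenched
draw, so all clusters receive the same spatially-averaged input, and one
realization of `z` is shared across a `Delta_H` grid so each cell's input
varies monotonically with arousal.  Stimuli are smooth
difference-of-exponential currents delivered to 50% of the assemblies and
50% of the E cells within each targeted assembly (matched total cell
count in uniform networks), five stimuli in analogy with five tone
frequencies.

## Default parameters and how they were chosen

The defaults (in `metastable.params.NetworkSpec`) use scaled synaptic
efficacies `j` with physical weight `j/sqrt(N)` mV: `j_EE = 1.0`,
`j_EI = 8.0`, `j_IE = 1.2`, `j_II = 5.5`, intracluster
`j+_EE = 15.75`, `j+_EI = 16.0`, `j+_IE = 2.4`, `j+_II = 6.6`;
`tau_m = 20 ms`, `tau_syn = 5 ms`, `tau_ref = 5 ms`, `V_th = 4 mV`,
`V_r = 0`; external drive `C_ext = 320`, `j_ext,E = 17`, `j_ext,I = 11`,
`nu0,E = 5 spk/s`, `nu0,I = 4.4 spk/s`; connection probabilities
`p_EE = 0.27`, all others 0.5.

These values were calibrated with the package's own mean-field theory and
short pilot simulations to place the model in a definite dynamical
regime, chosen as the study's reference conditions:

* the uniform network is asynchronous-irregular (near-zero pairwise
  spike-count correlations, CV(ISI) ~ 0.7, rates ~ 10 spk/s E / 15 spk/s
  I);
* at the reference intracluster coupling `j+_EE = 15.75` the clustered
  network is metastable: assemblies switch stochastically between a
  low-rate state and a high-rate state (~40-60 spk/s), the modal number
  of simultaneously active assemblies is 3, and activation periods last
  a few hundred ms;
* increasing input heterogeneity `Delta_H,E` over [0, 0.4] accelerates
  switching, lowers active-assembly rates, raises inactive-assembly
  rates, and ultimately dissolves the assembly states - the regime in
  which decoding accuracy is maximal at intermediate arousal.

Potentiated inhibitory pathways (`j+_EI`, `j+_IE`, `j+_II`) give each
active assembly self-limiting local inhibition; without them the network
collapses into a frozen single-winner state.  The membrane scale
(`V_th = 4 mV` above reset) makes the intracluster coupling strong
relative to threshold at the reference `j+_EE`; all voltages can be
rescaled jointly without changing the dynamics.

## Integration

The network equations are linear between spikes, so the integrator uses
the exact exponential propagator over each step and forces spike times to
the grid (default `dt = 0.05 ms`).  Voltage is clamped at reset during
the refractory period; synaptic currents continue to evolve (the
alternative - clamping currents as well - is not used; only the voltage
clamp is part of the model definition).  Initial membrane potentials are
uniform on `[V_r, V_th)` per trial.  Separate named RNG streams drive
connectivity, quenched arousal draws, stimulus targets, initial
conditions and the Poisson background, so each source of randomness is
independently reproducible.

## Mean-field theory

Population rates satisfy `nu = Phi(mu(nu), sigma(nu))` over the
`2(p+1)` populations (p E clusters + background, same for I), where `Phi`
is the LIF transfer function for exponential synapses:

    Phi^-1 = tau_ref + tau_m sqrt(pi) * int_{q_r}^{q_t} e^{x^2} erfc(-x) dx,
    q = (V - tau_m mu) / (sqrt(tau_m) sigma) + a sqrt(tau_syn / tau_m).

The boundary-shift constant is implemented as `a = |zeta(1/2)|/sqrt(2)
~ 1.0327`, the standard colored-noise correction when the integration
variable is scaled by `sqrt(2 Var V)`; the frequently printed variant
`-zeta(1/2)/2 ~ 0.73` corresponds to a different scaling convention and
is not used (the constant is config-exposed).  The integral is evaluated
with an exact `erfi` term for the growing part plus Gauss-Legendre
quadrature of the smooth `erfcx` remainder, giving machine-precision
values for all arguments; rates deeper than `q_t > 26` underflow to 0.

Branches with `nA` active clusters are found by biasing the initial rates
(`nu_high,E = 50`, `nu_low,E = 2` spk/s by default) and iterating a
damped fixed point with a root-finder fallback (tolerance 1e-10); a
branch "exists" when the converged solution actually has the sought
active/inactive structure.  With quenched disorder the unknowns become
each population's mean rate and across-cell rate variance; the Gaussian
quenched variable is integrated with 41-node Gauss-Hermite quadrature.
At the default coupling the `nA = 1..3` branches exist at
`Delta_H = 0`; because the branch region shrinks with noise, scans
across `Delta_H` (the analogue of the published ones) are run at a
larger theory-side coupling (`j+_EE ~ 18`), mirroring the original
offset procedure in which the theory coupling is matched to the
simulated active-cluster rate rather than taken verbatim.

## Effective two-cluster theory

A reduced network (two E clusters with fraction `f = 0.08` each, one E
and one I background population, intercluster weights *not* depressed,
`j+_EE,reduced = 10`, `j_IE,reduced = 2.4`) is analyzed with the
in-focus/ambient reduction: cluster rates are frozen, background rates
adapt self-consistently, and the induced cluster rates define a 2D flow
map whose zeros are the fixed points.  The reduced parameters differ
from the full network because the reduction has no inhibitory
co-clustering; they were chosen so that the theory is in the two-attractor
phase at zero arousal (two symmetric wells ~ (43, 8) spk/s linked by a
saddle on the diagonal).  The 1D effective potential is the negative
line integral of the flow along a well-saddle-well path built from
straight segments (the flow vanishes at all three anchor points, so the
potential's extrema coincide with the fixed points); the barrier height
`h` is the potential difference between the saddle and the deeper well.
With arousal the quenched average uses mean rates only (across-cell rate
variance set to zero).  `h` decreases monotonically and the wells merge
near `Delta_H ~ 0.07` for the reduced defaults - note the reduced and
full networks do not share a `Delta_H` scale - so the default scan grid
is [0, 0.15].

## Analyses

* **Cluster metrics** - single-neuron rates (Gaussian kernel, SD 25 ms -
  the stated "width" is interpreted as the SD - on a 1 ms grid) averaged
  over assembly members; "active" means rate >= 15 spk/s.  P(nA),
  conditional active/inactive rates, and the mean activation duration are
  pooled over the window [-0.8, -0.1] s before onset; activations clipped
  by the window edges count with their visible length.  Evoked metrics
  (cluster signal = targeted-minus-nontargeted mean rate; reliability =
  difference in fractions staying >= 1 spk/s above baseline for >= 25 ms)
  are evaluated in the peak decoding window supplied by the decoder.
* **Decoding** - spike counts in 100 ms windows (20 ms steps for the
  model, 10 ms available for session data), multiclass linear
  discriminant with a small ridge (shrinkage 0.01) on the pooled
  covariance, 10 repeats of stratified 5-fold cross-validation (50 fits),
  earliest window wins ties.  Model feature sampling draws one cell per
  assembly plus one background cell (p+1 = 19 features), or p+1 random E
  cells in uniform networks, averaged over feature-sample runs.
  Significance uses 100 stratified 80/20 label shuffles (95th
  percentile).  Session pooling z-scores per-decile peak accuracies
  within a session and bins them by pupil diameter (bins of 10% of
  maximum); mid-versus-extreme comparisons use Wilcoxon signed-rank tests
  with the stated 25%/75% inclusion rules.
* **Variability** - d' = |mu_a - mu_b|/sqrt((s_a^2+s_b^2)/2) averaged
  over stimulus pairs, cells, and time; the population index D'_sc is the
  maximum of the cell-averaged timecourse.  Fano factors use 100 ms
  windows (20 ms steps); the spontaneous value is the window immediately
  before onset and the evoked value is read at the minimum of the
  cell-averaged timecourse within 200 ms after onset; cells with zero
  mean count are excluded.  Spectra use the multitaper point-process
  estimator (1 ms bins, TW = 5, 9 DPSS tapers, 2.5 s windows), divided by
  the mean rate so a homogeneous Poisson train is flat at 1; low-frequency
  power averages 1-4 Hz inclusive.
* **Empirical pipeline** - pupil traces are resampled to 1 ms,
  max-normalized, jumps above 0.08 between adjacent samples remove
  [-250, +500] ms, smoothing is a 1/30 s moving average, and the trace is
  re-normalized (the 0.5 ms comparison lag of the original videos is one
  sample on the 1 ms grid).  Unit QC evaluates template amplitudes in
  5-minute windows by Gaussian KDE: multimodal windows (peak-height
  ratio <= 10 and peak separation >= 40 percent difference) in >= 10% of
  windows reject the unit; units whose tallest peak sits within 15% of
  the noise floor in more than 10% (but not all) of windows with a
  >= 25% peak-location range are rejected as floor drift; overall rate
  < 0.25 spk/s rejects.  "Percent difference" is |a-b|/mean(a,b)*100
  throughout.  Tone responsiveness compares 100 ms windows (1 ms steps)
  ending within 200 ms after onset against all windows fully inside the
  200 ms baseline, using the asymptotic Mann-Whitney U test (vectorized
  via count tables; identical to the reference implementation) with
  Bonferroni correction and a >= 5 ms contiguous-significance
  requirement.  Rate-arousal relationships use Spearman correlations over
  pupil-decile bins (p < 0.05 for a sign).

## Synthetic sessions

The generator emulates what the empirical pipeline consumes: a clipped
Ornstein-Uhlenbeck pupil trace (mean 0.55, SD 0.15, timescale 45 s) with
sharp step artifacts at known times; units with lognormal baseline rates,
mixed-sign exponential rate-pupil coupling, log-frequency Gaussian tone
tuning with 10-30 ms latency; doubly stochastic spiking (inhomogeneous
Poisson by thinning with slow multiplicative gain noise whose amplitude
decreases with pupil, so the Fano factor falls with arousal); optional
inverted-U structure in which evoked gains are scaled by a Gaussian bump
at mid pupil; and template-amplitude series of three classes (stable,
bimodal, floor-drifting).  It does not emulate probe-drift physics,
video pupillometry, spike-sorting errors, or spike-count correlations
between units, so recovery benchmarks certify the pipeline's logic and
statistical power under the generator's assumptions, not performance on
real recordings.

## Problem sizes and numerical choices

Study-scale runs use a scaled-down protocol chosen as the package's
reference workload: 3 network realizations x 5 arousal levels x 5
stimuli x 10 trials (evoked, 1.7 s trials, onset at 1 s) plus 10
spontaneous trials of 2.6 s per condition, integrated at `dt = 0.1 ms`
(the exact propagator makes the grid a spike-time quantization only);
decoding averages 5 feature-sample runs; discriminability and Fano
analyses use a 400-cell subsample including >= 5 candidates per assembly.
Spectra subsample every fourth E cell.  The white-noise transfer-function
oracle samples the membrane potential as an exact OU process (25 neurons
x 4 s per grid point, `dt = 1 us`, 0.5 s burn-in) on a 5x5 grid spanning
the network's operating range (`tau_m*mu` 3-5 mV, `sqrt(tau_m)*sigma`
1-3 mV); the finite-`tau_syn` boundary-shift correction is first-order
only (residual ~2-5% at `tau_syn/tau_m = 0.05`), which is why the oracle
is evaluated in the white-noise limit that defines the transfer function.

## Known limitations

* The cluster signal decreases monotonically with `Delta_H` in this
  parameter set rather than rising slightly before falling.
* At large `Delta_H` the rate distribution becomes unimodal near the
  15 spk/s activation threshold, so threshold crossings inflate the
  nominal "active cluster" counts and the activation-duration estimate
  turns non-monotonic at the top of the grid (the endpoint-to-endpoint
  decrease remains robust).
* Mean-field and simulation couplings differ (the theory's cluster
  branches appear at larger `j+_EE`), as in the original offset
  procedure; comparisons between theory and simulation are qualitative.
* The arousal axis of the reduced two-cluster model is not commensurate
  with the full network's `Delta_H`.
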