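# Methods

## The model

`hvcx` simulates a single-compartment conductance-based model of songbird
HVC_X projection neurons (HVC neurons projecting to basal-ganglia nucleus
Area X). The membrane potential obeys

    C_m dV/dt = -I_L - I_K - I_Na - I_CaL - I_CaT - I_A - I_SK - I_h + I_app

with mV/ms/pA/pF/nS units so every term balances in pA. The currents are

- `I_Na = g_Na m_inf(V)^3 h (V - E_Na)` — fast sodium with instantaneous
  activation and one inactivation gate;
- `I_K = g_K n^4 (V - E_K)` — delayed rectifier;
- `I_CaT = g_CaT a_inf(V)^2 b (V - E_Ca)` — low-threshold T-type calcium
  whose inactivation gate `b` deinactivates slowly (tau 80 ms) at
  hyperpolarized potentials, producing post-inhibitory rebound firing;
- `I_SK = g_SK [Ca]^2/([Ca]^2 + k_s^2) (V - E_K)` — calcium-activated
  potassium driven by a first-order calcium pool fed by the two calcium
  currents (influx 0.0015 uM per pA*ms, removal tau 50 ms, baseline
  0.05 uM, k_s 0.5 uM); this is the spike-frequency-adaptation mechanism;
- `I_h = g_h r (V - E_h)` — hyperpolarization-activated cation current
  (tau 100 ms), the source of the depolarizing sag;
- `I_CaL`, `I_A`, `I_L` — fixed high-threshold calcium, A-type potassium
  and leak currents.

Steady-state gates are Boltzmann sigmoids `1/(1 + exp((half - V)/slope))`
(negative slope for inactivation/hyperpolarization-activated gates);
voltage-dependent time constants are Gaussian bumps. Every constant is
explicit in the versioned file `src/hvcx/reference_params.yaml`
(`hvcx-reference-1`). The calcium reversal is fixed at +120 mV (ohmic, no
GHK correction): any consistent rescaling of the calcium pool is absorbed
into the fitted `g_SK`.

The five maximal conductances `g_Na, g_K, g_SK, g_h, g_CaT` are the
quantities estimated from data; `g_CaL` is fixed because its effect on
fits is indistinguishable from `g_SK`, and `g_A` because it is very small
in this cell type. Adult capacitance is 50 pF; the juvenile variant uses
75 pF (larger somata), selected with `reference_parameters(juvenile=True)`.

The kinetics constants are a documented stand-in parameterization, tuned
once so the reference conductance set reproduces the qualitative HVC_X
phenotype, and then frozen: resting potential near -72 mV, ~+7 pA to hold
at -70 mV, input resistance ~144 MOhm (species range 181 +/- 35), an
adapting 8-spike train riding a depolarized plateau at +100 pA, ~17 mV sag
and rebound firing at -140 pA, no sag or rebound when `g_h = g_CaT = 0`,
and spike counts monotone in stimulus amplitude and monotonically
suppressed by `g_SK`. They are a concrete member of the model class, not a
reproduction of any published constant set.

### Numerics

Fixed-step 4th-order Runge-Kutta at dt = 0.02 ms, compiled with numba,
with zero-order hold of the stimulus across each step. Divergence
(|V| > 200 mV or non-finite state) raises an error naming the offending
conductances. Holding at a target voltage is closed-form: with all gates
at steady state and the calcium pool at its stationary value, the bias
current equals the steady total ionic current, making the target an exact
fixed point. Convergence: halving dt changes subthreshold traces by less
than 0.1 mV sample-wise and shifts spike times by less than 0.1 ms. A
sample-wise bound cannot hold on the spike upstroke itself — a 0.05 ms
phase shift maps to several mV at ~150 mV/ms — so spike-train convergence
is stated in time, not voltage.

The chaotic stimulus is the x-component of a Lorenz system (sigma 10,
rho 28, beta 8/3), one Lorenz time unit mapped to 50 ms, seeded initial
condition, five time units of burn-in, mean-subtracted and rescaled to
the requested peak amplitude. Responses to chaotic stimuli are never
scored by the fit error (its features are step-pulse quantities).

## Feature extraction

Spikes are upward crossings of dV/dt >= 10 mV/ms that climb at least
10 mV above the crossing voltage within 3 ms; crossings within a 2 ms
refractory window merge. Threshold is the voltage at the first sample of
the crossing run; amplitude is peak minus threshold; duration is full
width at half amplitude. For noisy traces (provenance `synthetic-cohort`
or `external`, or a recorded noise sigma) the trace is Savitzky-Golay
smoothed (0.5 ms window, order 3) before differentiation; model traces
skip smoothing. At 0.3 mV additive noise the detector reproduces the
noise-free spike count and thresholds to within a fraction of a mV.

Plateau amplitude is the mean of inter-spike voltage minima during the
pulse minus rest (with < 2 spikes: mean pulse voltage excluding 10 ms
around spikes, minus rest). Sag ratio is (V_ss - V_min)/(V_base - V_min)
on the hyperpolarizing pulse; rebound firing counts spikes in the 200 ms
after offset. Input resistance is dV_ss/dI from 5-25 pA hyperpolarizing
steps. These definitions are explicit substitutes for criteria that the
underlying experimental literature states only graphically; anything not
computable is NaN, never zero.

## Fitting

The error between a model and a biological response to the canonical
+100/-140 pA pulse pair is a sum of normalized squared differences over
eight features: plateau amplitude, spike amplitude, spike duration, spike
count, the timing of each individual spike, resting potential, sag ratio,
and rebound firing. Since these have heterogeneous units, each difference
is divided by a fixed species-scale constant before squaring (10 mV for
voltages, 5 ms for times, 1 for counts, 0.1 for sag ratio), making the
sum unit-free, symmetric, and zero iff all compared features agree. Spike
trains are matched in order up to the shorter count; each unmatched spike
adds (pulse duration / 5 ms)^2; a waveform feature defined on exactly one
side adds a fixed penalty of 4. Absolute error values therefore depend on
these conventions — only orderings and ratios are meaningful.

`GridSearchFit(...).fit()` evaluates every point of a 5-D grid: simulate
both canonical pulses, extract features, apply the disregard rule — any
candidate whose +100 pA spike count differs from the biological trace is
discarded before the error is computed — and return the global minimum,
with lexicographic (g_Na, g_K, g_SK, g_h, g_CaT) tie-breaking. The
published full-resolution grid (g_Na 200-2500 by 20, g_K 50-750 by 10,
g_SK and g_h 0-15 by 0.2, g_CaT 0-10 by 0.2; 2,426,127,936 candidates) is
cluster-scale; the desk default subsamples each axis (5 points/axis =
3,125 candidates, roughly a minute per neuron on one CPU). The search
path synthesizes the 200 ms pre-pulse segment analytically (the cell sits
at its holding fixed point) and gives the depolarizing candidate a short
post-pulse tail, which is exactly equivalent to the full simulation for
every scored feature; the randomized-restart local search utility can
never beat the exhaustive result on the same grid.

Prediction scoring simulates the fitted model at held-out amplitudes
(75/150/175 pA) and reports the error ratio against the 100 pA fit;
count mismatches use the penalty (a prediction cannot be discarded).
Cross-validation takes one best-fit neuron per bird and forms the matrix
of 150 pA prediction errors of bird j's model against bird k's response,
each normalized by bird j's own 100 pA fit error; the summary is mean
off-diagonal over mean diagonal.

## Population statistics

All covariances are sample covariances (1/(N-1)), so the trace volume —
sqrt of the summed squared deviations over N-1 — satisfies
V(B)^2 = trace(cov) exactly. The geometric volume is sqrt(det cov)
(a length^5 hyperellipsoid measure, zero and flagged when rank-deficient,
in particular whenever a bird has <= 5 neurons). Both are normalized by
the same quantity computed on a pooled species reference supplied by the
caller, never hard-coded. Mahalanobis distance uses the pooled sample
covariance of the two birds and falls back to the pseudo-inverse (with a
flag) when singular.

MANOVA is implemented from the T = B + W decomposition with Wilks'
lambda = |W|/|W+B| and Rao's F approximation (exactly the one-way ANOVA F
when there is a single covariate); the canonical covariates are spike
rate and the first three ISIs, with neurons of fewer than four spikes
removed. Pairwise mode Bonferroni-corrects by the number of testable
pairs (both birds needing at least as many neurons as covariates), and
reports both that count and the nominal C(n,2). The implementation is
cross-checked against statsmodels' MANOVA in the test suite.

The bespoke tests follow the source procedures: same-bird vs across-bird
distances in a 2-D feature plane (seeded sampling, unpaired two-tailed
t); same-order spike-time ratios accumulated within spike-count groups
(singleton groups dropped) compared between birds by a two-tailed
two-sample F test of variances; pairwise first-spike waveform
mean-squared differences compared by the same F test; and rundown checks
testing amplitude ratios (later/first, last/first cell) against 1.0.
Calibration caveat: the pooled paper-style procedures reuse cells across
pairs (shared first-cell denominators, repeated cells in pairwise MSDs),
which makes the plain F and t tests anticonservative under that
dependence. The calibration suites therefore use null generators with
independent values (two cells per bird; one fresh waveform pair per MSD),
which is the regime in which these classical tests are exact. Interpret
pooled-dependent p-values as descriptive.

The song-coupling analysis regresses pairwise song similarity on
between-bird conductance-centroid distance over the non-identical
lower-triangle entries (pooled R and slope-t p, or per-bird rows),
supporting Euclidean and Mahalanobis distances and a
leave-one-conductance-out control (e.g. dropping g_SK). Volume-covariate
regressions are OLS on the covariate or its natural log. PCA
variance-explained shares standardize columns by default (flag exposed;
zero-variance columns dropped with a warning).

## The synthetic cohorts

A bird is a centroid in 5-D conductance space plus independent per-axis
multiplicative log-normal jitter; the within-bird "fold-variation" is
reported as exp(2 * SD of log values) — the multiplicative 2-sigma spread,
a sample-size-free statistic matching the generator contract
fold = exp(2 sigma).

- **adult** — centroids across the full species ranges (g_Na and g_K
  log-uniform, their spans being large multiplicative ranges; the rest
  uniform); fold spreads 1.23 (g_Na), 1.24 (g_K), 1.14 (g_SK), 1.17
  (g_h), 1.19 (g_CaT), the species' average per-animal variation.
- **juvenile** — centroids restricted to the low-g_Na (200-700 nS) /
  low-g_SK (0.5-4 nS) sub-box; inflated fold spreads dominated by g_h
  (4x) and g_K (2.5x) with little g_CaT variation (1.2x), and 35% of
  neurons with essentially no h-current (no sag, no rebound). The
  inflation factors are free parameters — the source observations are
  qualitative — chosen so juvenile dispersion clearly exceeds adult.
- **cdaf** (continuous delayed auditory feedback) — per-bird dispersion
  set so the expected trace volume follows a + b ln(motifs sung) with
  a = 4 nS and b = 150 nS (anchored so the law meets the top of the adult
  per-bird range near 5.9 motifs; default exposure ladder 35..700
  motifs). The scatter is additive Gaussian — dissolved clustering, not a
  tight multiplicative cluster — with variance shares 60/35/2/2/1 across
  g_Na/g_K/g_SK/g_h/g_CaT, capped at 0.55x the centroid so the
  non-negativity clip stays a tail event; cDAF centroids sit in the
  high-conductance region (g_Na 1800-2500, g_K 500-750) so this budget is
  feasible, and g_SK centroids are shifted low (0-4 nS).

Traces are the model's canonical-pulse responses plus additive white
Gaussian voltage noise (default 0.3 mV); no channel noise is simulated.
Song similarity mixes a linear decreasing transform of centroid distance
(weight = coupling) with symmetric Gaussian noise (weight 1 - coupling,
scaled 4x), affinely mapped onto (0, 100]; at coupling 1 similarity is an
exactly linear decreasing function of centroid distance, at coupling 0.8
the pooled correlation concentrates around R ~ -0.7, and at coupling 0 it
vanishes. All randomness flows from the single config seed.

What the generator does *not* emulate: correlated conductance structure
within birds, electrode/access artifacts, bridge-balance errors, channel
noise, temperature effects, or real song acoustics (similarity matrices
are generated, not computed from audio). Passing tests therefore
demonstrate the internal consistency of the analysis chain — generator
statistics are recovered by the estimators at stated tolerances — not
agreement with any particular recording.

## Problem sizes and known limitations

The validation suite runs desk-scale: recovery uses the 5^5 grid (3,125
candidates/neuron; one noise-free neuron recovered exactly and 10 noisy
neurons within one grid step), calibration suites use 1,000 seeded
replicates per test, and structure recovery uses 8-bird cohorts.
Per-bird sample trace volumes carry chi-type noise (relative SD roughly
13-15% at 12-16 neurons/bird), so the slope of the cDAF volume-vs-
log(motifs) law has ~30% standard error at 8 birds regardless of
generator fidelity; the regression operation's 20%-recovery property is
checked on volumes drawn directly from the law, and the cohort-level
check asserts a positive, significant slope on a 12-bird wide ladder.
Fitting identifies conductances only up to the error function's feature
set: on very coarse grids, axes with weak phenotypic leverage for a given
target (often g_CaT, or g_Na when few spikes are emitted) are recovered
to within one step only when the target lies on the grid, which is the
regime the recovery guarantees address.
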