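# Methods

This note documents the models, conventions and numerical choices the
package makes, what the synthetic-data generator does and does not
emulate, and the known limitations.

## The measurement definitions

All measurements operate on voltage in mV, current in pA and time in ms
(readers normalize units on load; 20 V/s ≡ 20 mV/ms is fixed
internally so all slopes are reported in mV/ms).

* **RMP** — mean voltage over a zero-current epoch: a zero-amplitude
  sweep if present, otherwise the 50 ms baseline immediately before step
  onset (window configurable). The mean is used rather than the mode: it
  is the simplest unbiased estimator and the window is configurable. A
  baseline sample above −20 mV flags spike contamination and the
  measurement is refused rather than biased.
* **Rin** — steady-state ΔV/ΔI on the hyperpolarizing sweep nearest
  −100 pA (default), steady state being the mean over the final 20 % of
  the step; a ΔV–I least-squares slope over all hyperpolarizing sweeps
  is available as `method="fit"`. Both are provided because the
  single-step estimator matches the one printed step amplitude of the
  standard protocol while the fit uses more data when it exists; for a
  linear (ohmic) cell the two coincide, which is tested.
* **Sag ratio** — (|peak| − |steady state|)/|peak| of the deflection
  from baseline during a hyperpolarizing step. Cells with sag > 5 % are
  classified as having a prominent H-current; the boundary is **strict**
  (0.05 exactly is not prominent) because the rule is stated as ">5 %".
* **Spike detection** — upward crossing of 0 mV followed by a local
  maximum; the trace must fall back below the criterion before the next
  event (refractory guard), so merged depolarizations count once.
* **AP threshold** — voltage where dV/dt first reaches 20 mV/ms on the
  upstroke. The search walks backward from the peak through the
  supra-criterion region; the crossing is linearly interpolated between
  the straddling samples (interpolation can be disabled, since whether
  the original analyses interpolated is generally unknowable; at 50 kHz
  the difference is < 0.05 mV on realistic upstrokes).
* **Half-width** — time between the interpolated upward and downward
  crossings of threshold + amplitude/2. If repolarization never
  recrosses the half level before the next spike or step end, the value
  is flagged undefined, never extrapolated.
* **mAHP** — threshold voltage minus the voltage trough in
  (peak, peak + 100 ms], truncated at the next spike's threshold time or
  the step offset, whichever comes first; truncation is recorded. The
  window is peak-anchored (anchoring at the threshold recrossing is a
  configuration away); truncation at the next spike attributes
  inter-spike troughs to the preceding AP, which is what per-AP mAHP
  series in trains require.
* **Rheobase** — smallest ladder current whose sweep spikes. On a
  discrete ladder this is resolution-limited, so the ladder increment is
  recorded alongside the estimate, and a sweep at the ladder floor that
  already spikes is flagged.
* **7-AP train** — the sweep with exactly seven spikes at the lowest
  such current; if none exists the nearest count is taken (preferring
  the count below seven on ties) and flagged approximate. ISI₁ and ISI₆
  come from the spike threshold times of that train;
  accommodation = (ISI₆ − ISI₁)/ISI₆ and may be negative.
* **Derivatives** — dV/dt by central differences; d²V/dt² by the direct
  three-point stencil. Savitzky–Golay pre-smoothing exists behind a flag
  and is off by default: input traces are assumed already
  hardware-filtered (10 kHz), and at 50 kHz the raw stencils resolve the
  upstroke. Tie-breaks are deterministic everywhere: first qualifying
  sample for the threshold search, lowest current for the n-spike sweep,
  earliest and deepest trough for the breakpoint.

## Phase-plot decomposition

The breakpoint between the AIS and SD components is the most negative
strict local minimum of d²V/dt² strictly between the threshold time and
the time of maximal dV/dt, reported with its prominence (any strict
local minimum is accepted by default; a prominence floor is
configurable). A monophasic upstroke — no interior local minimum —
leaves the decomposition undefined rather than inventing a breakpoint.

`b` is the peak dV/dt of the upstroke. The operational definition of
`a` is genuinely ambiguous in the field's figure-based presentations, so
two labeled conventions are implemented and every output row names the
one used:

* `b_minus_breakpoint` (default): `a = b − dV/dt(breakpoint)` — the SD
  contribution above the AIS shoulder, measured at the curvature trough.
* `ais_peak`: the shoulder is the AIS component's own dV/dt maximum
  before the breakpoint, `a = b − max(dV/dt over threshold→breakpoint)`.

On the analytic two-sigmoid construction (components with designed
maximal slopes 100 and 400 mV/ms) the default convention recovers the
analytically solved ratio to 0.03 % and `ais_peak` recovers
300/400 = 0.75 to 0.3 %. The ratio is invariant to voltage offsets and
to uniform time rescaling, both tested.

## The synthetic-trace simulator

Two compartments — soma (150 pF) and AIS (6 pF) — coupled by a 120 nS
axial conductance. Whole-cell conductances in nS so that g·V is in pA.

Gating (all first-order, exponential-Euler updates):

| current | form | kinetics |
|---|---|---|
| Na (soma, Nav1.2-like) | g m³h (V − 60) | m∞ midpoint −26 mV, slope 6; τ_m 0.08 ms; h∞ midpoint −36 mV, slope 10; τ_h(V) = 0.4 + 4.5/(1+exp((V+40)/6)) ms |
| Na (AIS, Nav1.6-like) | g m³h (V − 60) | same shapes, activation midpoint shifted by `na_halfact_shift` (−10 mV default) |
| K delayed rectifier | g n² (V + 90) | n∞ midpoint −20 mV, slope 10; τ_n 1.2 ms; 15 % of g_K sits in the AIS |
| SK | g c (V + 90) | pool c += 1 per somatic spike (0 mV upward crossing), τ decay 60 ms |
| H (HCN-like) | g r (V + 30) | r∞ midpoint −82 mV, slope 9; τ_r 50 ms |
| leak | g (V − E_L) | soma only |

The shallow, only-moderately-hyperpolarized Na inactivation with a
voltage-dependent τ_h is deliberate: with steeper or faster inactivation
the model accommodates itself out of firing during the slow approach to
threshold that long current steps produce. The AIS carries no leak, so
in the passive limit (all active conductances zero) the input resistance
is exactly 1000/g_leak MΩ and the resting potential exactly E_L — the
closed forms the RC recovery tests assert. The tightly coupled AIS
capacitance makes the effective passive time constant
(C_soma + C_AIS)/g_leak.

Because the AIS sodium activates ~10 mV below the somatic sodium and
sees a 25× smaller capacitance, spikes initiate there; the somatic
upstroke then shows the AIS-driven shoulder followed by the SD
component, i.e. a biphasic rising phase with a d²V/dt² trough — the
property the phase module needs, verified across the whole default
parameter grid.

**Integration.** Fixed-step, 4 substeps per 50 kHz sample (Δt = 5 µs);
gates by exponential Euler, membrane voltages by a semi-implicit update
(conductances frozen within a substep), which is unconditionally stable
for the linear-in-V part. Each sweep is preceded by 300 ms of unrecorded
settling; every sweep is checked for non-finite voltages and the
offending parameter set is reported on failure. Ground-truth spike times
are the linearly interpolated upward crossings of 0 mV at substep
resolution.

**Noise.** Ornstein–Uhlenbeck current noise (τ = 5 ms) injected at the
soma, scaled so the resting voltage s.d. approximates `noise_sd`; off by
default so that all analytic limits are exact and traces are bit-wise
reproducible under a fixed seed (distinct seeds diverge when noise is
on, also tested).

**Defaults and the cohort templates.** The default parameter set was
chosen once to place the extracted measurements in the range typical of
layer-5 prefrontal pyramidal cells at ~35 °C: Rin ≈ 129 MΩ, RMP ≈
−68 mV, sag ≈ 0.10, rheobase 150 pA, 7-AP train at 350 pA, half-width
≈ 1.1 ms, mAHP ≈ 25 mV, dV/dt_max ≈ 350 mV/ms, Slope_SD ratio ≈ 0.85.
The "shifted" cohort template moves four dials in the directions the
two-hit (maternal immune activation + social isolation) phenotype
reports: leak 4.8 → 3.7 nS (higher Rin), leak reversal −70 → −73 mV
(hyperpolarized RMP), g_SK 12 → 16 nS (larger mAHP), somatic Na share
0.80 → 0.88 at fixed total (larger Slope_SD ratio). Cohorts draw
per-cell parameters by multiplicative jitter (fractional s.d. 0.1,
clipped at zero with clipping logged) and ±1 mV-scale additive jitter on
the leak reversal.

**Monotonicity grid.** The dial-recovery checks run on the documented
grid g_H ∈ {0.8, 1.6, 3.2} nS × g_SK ∈ {8, 12, 16} nS × somatic Na
fraction ∈ {0.5, 0.65, 0.8} (total Na 4500 nS): sag must rise strictly
with g_H, mAHP with g_SK and the ratio with the Na fraction along each
axis at every setting of the other two dials. The g_SK axis starts at
8 nS: below that the model fires an initial doublet at rheobase and the
mAHP window truncates at the next spike, which makes the g_SK → mAHP map
noisy (the truncating window definition, not the simulator, is the
source of that fragility).

**What the generator does not emulate.** Dendritic morphology, synaptic
input, temperature dependence, electrode/access artifacts,
bridge-balance errors, channel stochasticity and slow drift are absent,
and no attempt is made to fit the simulator to any real cell — the
templates mirror reported directions, not magnitudes. Passing tests
therefore demonstrate that the extractors recover what generated the
data under clean, known conditions; they do not certify performance on
noisy biological recordings.

## Statistics

Normality per group by Shapiro–Wilk at α = 0.05 (the field's standard
small-sample choice; configurable), both groups must pass; then a
two-tailed unpaired Student's t-test, otherwise a two-sided Mann–Whitney
U. Groups of fewer than 3 values or with zero range route to the rank
test; two identical constant groups short-circuit to a degenerate result
with p = 1. The Mann–Whitney p is exact — exhaustive enumeration over
all C(n_a+n_b, n_a) assignments, valid with ties — whenever the pooled
sample is ≤ 12, and the tie-corrected normal approximation above that.
Every result records the route taken, so reports are reproducible. No
multiple-testing correction is applied; the comparison table instead
carries one row per parameter so the reader can see the number of
comparisons. Mean ± SEM uses the n−1 sample standard deviation; SEM is
flagged undefined at n = 1.

Immunoblot normalization divides each lane by its loading-control
(tubulin) density and the resulting ratios by the control-lane mean, so
control outputs average exactly 1; zero-control lanes are excluded with
a warning.

## Pipeline and reproducibility

The pipeline runs simulate (or load) → extract → compare and emits
`features.csv` (one row per cell), `comparison.csv` (one row per
parameter with per-parameter n — cells whose value is undefined are NA,
never zero, and drop out of that row's n only), the same comparison
restricted to prominent-H cells (a pure filter that cannot alter
full-cohort numbers), and `provenance.json` with the package version,
the full configuration, its hash and the seed. Identical config + seed
reproduces every output byte-for-byte.

**Problem sizes.** The validation suite and the acceptance script use
25 cells per group for the two-group direction cohorts (the scale of a
typical patch-clamp group comparison),
the 27-cell monotonicity grid, and full 31-sweep ladders at 50 kHz;
smaller ladders are used in unit tests where only rheobase-range
behavior matters.

## Known limitations

* The threshold criterion (20 mV/ms) interacts with the AIS shoulder:
  in strongly AIS-dominated parameter regions the somatic dV/dt crosses
  the criterion during the shoulder, giving thresholds a few mV more
  hyperpolarized than the somatic-Na activation would suggest — the same
  behavior real phase plots show.
* The mAHP of a rheobase AP can exceed typical biological values when
  SK is strong, because the model's trough combines the SK current with
  the delayed-rectifier tail; the definition is applied verbatim either
  way.
* Exact Mann–Whitney enumeration is O(C(n, n_a)) and is therefore capped
  at pooled n = 12; above the cap the tie-corrected asymptotic p is
  used, which differs from the exact value in the third decimal at
  n ≈ 13–20.
* Vendor acquisition formats (ABF, NWB) are not bundled; the reader
  contract accepts plugins, and the HDF5/CSV dialects are the canonical
  interchange.
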