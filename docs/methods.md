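# Methods

## Scope

`patchkit` re-implements, as a tested pipeline, the standard desk
analysis of whole-cell current-clamp recordings from cortical
interneurons: per-cell feature extraction from square-pulse protocols,
Hill-sigmoid characterization of the firing-rate-vs-current (F-I)
relation, scaled-template detection of spontaneous synaptic currents,
unsupervised electrophysiological typing, and normality-gated paired
statistics for drug comparisons.  Because no laboratory data ship with
the package, a synthetic-neuron generator with exact ground truth
drives all tests and the reproduction script.

## The synthetic neuron

The generator is a hybrid of an adaptive-exponential integrate-and-fire
(AdEx) subthreshold model and a pasted, stereotyped action-potential
waveform.  The subthreshold membrane equation is

    C dV/dt = -g_L (V - E_L) + g_L Δ_T exp((V - V_T)/Δ_T) - w
              - g_h h (V - E_h) - (g_BK,tonic + g_bk(t)) (V - E_K)
              - g_tonic (V - E_Cl) - g_GIRK (V - E_K) + I_inj + I_OU

with subthreshold/spike-triggered adaptation `w` (parameters `a_w`,
`b_w`, `tau_w`), an HCN-like sag conductance `g_h` with a sigmoidal
steady-state activation (`V_half_h`, `k_h`) and time constant `tau_h`,
a tonic Cl⁻ conductance (GABAaR-like), a GIRK K⁺ leak (engaged by
GABAbR agonism), and Ornstein-Uhlenbeck current noise.  Integration is
fixed-step exponential Euler at dt = 0.05 ms — one sample at the 20 kHz
acquisition rate — with no adaptive stepping, so identical inputs and
seeds give bit-identical sweeps.  Voltages outside [-150, +80] mV away
from a pasted waveform raise an integration error.

**Why a pasted waveform.**  Integrate-and-fire models have no AP
downstroke, so spike amplitude, half-width and AHP depth would be
artifacts of the reset.  When the integrated voltage reaches `V_cut`
the output is replaced by a deterministic waveform: linear rise to the
peak, linear fall to `onset - ahp_depth`, exponential relaxation toward
`V_reset`.  Every spike-shape quantity therefore has a closed form
(e.g. half-width = rise/2 + fall·A/(2(A + ahp_depth)) for amplitude A),
which the feature-extraction tests check sample-exactly.  Spike
amplitude declines geometrically across a sweep toward a floor of 75%
of the first amplitude; the first-to-second decline equals the
`droop_per_spike` parameter, giving the amplitude-change feature
(A₂-A₁)/A₁ an exact ground truth.  The waveform occupies the
integration as an absolute refractory period (~8 ms), capping firing
around 120 Hz — above every rate the protocols evoke.

**BK channel mechanism.**  The BK-like K⁺ conductance has two parts,
both multiplied by the extracellular-Ca²⁺ factor `ca_scale` ∈ [0, 1]
(1 ≈ 2.5 mM recording ACSF, 0 ≈ 1 mM physiological ACSF, where BK is
functionally silent): a tonic fraction (`bk_tonic_frac`, default 0.3)
active between spikes, and a spike-triggered increment decaying with
`tau_BK`.  The tonic part raises rheobase and the F-I midpoint; the
triggered part deepens adaptation and lowers attained rates.  A purely
spike-triggered conductance cannot move rheobase at all (it is inactive
before the first spike), so the tonic fraction is what allows BK
blockade to left-shift the F-I curve, as observed experimentally.

**Pharmacology.**  Drug conditions are pure transformations of a neuron
spec: baclofen (GABAbR agonist) adds `g_GIRK` = 0.15 nS (sized to give
the observed ~6% input-resistance drop) and multiplies `g_BK` by a
suppression factor 0.2 — the factor is a free calibration knob, since
the magnitude of the GABAbR→BK pathway is not quantified; paxilline
zeroes `g_BK`; picrotoxin zeroes the tonic Cl conductance; glutamate
receptor blockade silences the OU background drive.  Applying a
condition never mutates the input spec, so reverting is keeping the
original.  With these mechanics the qualitative drug directions emerge
rather than being coded: at high Ca, BK blockade lowers rheobase and
GABAbR agonism (net BK relief > GIRK) raises maximal firing; at low Ca
the BK terms vanish, leaving only GIRK, so GABAbR agonism lowers firing
and BK blockade does nothing.

**Presets.**  Three reference phenotypes mirror the canonical
interneuron types: `type1` (continuous-adapting; τ ≈ 28 ms, R_in ≈ 410
MΩ, rheobase ≈ 60 pA), `type2` (bursting, via a reset just below the
spike cutoff plus strong slow adaptation; highest R_in and τ, lowest
rheobase, prominent sag and rebound spike from a strong `g_h`), and
`type3` (irregular, OU-noise-driven with σ = 8 pA ≈ 1 mV membrane
noise; fastest τ, lowest R_in, highest rheobase).  Cohorts draw cells
around a preset with 5% log-normal jitter on conductances and a ±1 mV
threshold shift.  The default cohort is 17/3/5 cells per type,
mirroring the 68/12/20% type proportions reported for layer-2/3 VIP
interneurons.

**What the generator does not emulate:** electrode/access-resistance
artifacts, bridge imbalance, liquid-junction potentials, channel
kinetics beyond the single-gate sag model, dendritic filtering, and
real biological feature correlations beyond the per-type parameter
jitter.  Passing tests therefore certify the *analysis operations* —
that features, fits, detections and clusters are computed correctly
against known ground truth — not that the model reproduces any real
recording.

## Feature extraction

Operational definitions (18 features per cell):

- **Spikes**: upward 0 mV crossings followed by a local maximum, 1 ms
  refractory.  Spikes with peak-to-threshold amplitude < 5 mV
  (spikelets during depolarization block) are excluded from all counts.
- **Threshold**: voltage where the two-point forward dV/dt first
  reaches 5 mV/ms, walking backward from the peak through the
  contiguous suprathreshold-slope run, at most 10 ms.  No smoothing by
  default (a Savitzky-Golay option exists for noisy data).
- **Shape**: amplitude = peak - threshold; half-width by linear
  interpolation of the two half-amplitude crossings; fast/medium AHP as
  the depth below threshold of the minimum within (peak, peak + 4 ms]
  and (peak, peak + 6 ms].  The windows are anchored at the spike peak
  — the unambiguous fiducial — and depths are reported unclamped (a
  decay that never dips below threshold gives a negative value).
- **Excitability**: rheobase = first step with ≥ 1 accepted spike;
  frequencies = count / 0.5 s; mean frequency averaged over all
  depolarizing steps.  AP-shape scalars, mean ISI and amplitude change
  are measured at the step whose count is nearest 50% of the maximum
  (ties toward the lower current).
- **Firing pattern** (one categorical feature): *burst* if the first
  ISI < 0.5× the median of the remaining ISIs (≥ 3 spikes at the
  half-max step), else *adaptive* if last/first ISI > 1.3, else
  *neither*.  These operational cutoffs are package choices; published
  descriptions of burst/adapting firing are qualitative.
- **Passive**: V_m = pre-pulse baseline; R_in from the -10 pA test
  pulse, using the single-exponential fit's extrapolated plateau
  (a 100 ms pulse is ~2.5 τ for a slow cell, so a windowed mean alone
  would undershoot); τ from the same fit, cross-checked against the 63%
  rise-time criterion and rejected (with a warning) if the fit RMSE
  exceeds 20% of the deflection; Cp = τ/R_in.  Repeated test pulses are
  averaged — the protocol delivers one before every sweep, so ~20
  repeats are the realistic budget.  Sag amplitude = |V_min - V_steady|
  during the -200 pA pulse (steady = last 50 ms); rebound = any spike
  within 100 ms of pulse offset.  A voltage-clamp charging-transient
  capacitance (Q/ΔV) is provided for data recorded with a membrane
  test.
- Cells missing more than 4 of 18 features are excluded and logged.

## Hill F-I characterization

The F-I curve (one point per depolarizing step, zero-rate points kept —
they constrain the midpoint) is fitted with f(x) = a·xᵇ/(cᵇ + xᵇ) by
bounded nonlinear least squares: a₀ = max F, c₀ = first current at
≥ a₀/2, b₀ = 2; bounds a ∈ (0, 3a₀], b ∈ (0, 100], c ∈ (0, 3·max I];
tolerances 1e-10, ≤ 10⁴ evaluations.  f(c) = a/2 holds identically.
Reported gain ("steepness") is the midpoint slope a·b/(4c) in Hz/pA —
the unit gain is conventionally quoted in — with the dimensionless
exponent b kept alongside.  Fits reaching a bound or the evaluation cap
are flagged unconverged; fits whose plateau exceeds the largest
observed rate are flagged as extrapolated maxima.  Fewer than 4 points,
flat curves, or a single distinct nonzero rate refuse to fit.

## Event detection

Spontaneous APs reuse the 0 mV criterion; frequency = events/duration.

PSCs use the optimally-scaled sliding-template method: at every offset
the unit-peak biexponential template (default 0.5 ms rise, 5 ms decay,
20 ms length) is fitted with free scale and baseline offset, and the
detection score is scale / √(SSE/(N-2)) — the standard statistic for
which the default criterion 3.5 is calibrated.  The free offset makes
detection exactly DC-invariant; the unit peak makes the fitted scale
the event amplitude.  Candidate score maxima closer than the template's
analytic time-to-peak are merged, and greedy non-maximum suppression
within half the template length removes the secondary maxima that one
strong event produces across its score plateau (without it, precision
collapses to ~0.4 at 2 Hz event rates).  The 20 ms template length (4
decay constants) keeps the fit window short enough that a neighboring
event rarely contaminates the SSE.  Events are accepted when score ≥
criterion and amplitude ≥ 5 pA.  Raising the criterion is monotone
(never adds events).

## Typing pipeline

Features are z-scored before clustering — they span four orders of
magnitude (pA vs ratios), so unscaled Euclidean/Ward distances would be
meaningless.  The boolean rebound flag is encoded 0/1; the categorical
firing pattern is encoded as two 0/1 dummies by default (19 columns; a
single ordinal column {0, 0.5, 1} is available for a strict 18-column
matrix).  Missing values are median-imputed with a logged flag (for
clustering only); constant columns are dropped with a warning.

Ward's minimum-variance linkage on Euclidean distances is cut at k = 3
by default (configurable; no automatic k selection), and labels are
renumbered by descending cluster size.  A random forest (500 trees,
impurity importances normalized to sum 1, stratified 5-fold CV, or
leave-one-out when a class has < 5 members, explicit seed) quantifies
feature contributions to cluster allocation; PCA of the same matrix
gives the factor map, with each component signed so its
largest-magnitude loading is positive.

## Statistics

Data are screened with Shapiro-Wilk at α = 0.05.  For paired
comparisons the gate is applied to the paired differences (the screened
quantity is the one the test assumes normal); p ≥ 0.05 selects the
paired t test, otherwise Wilcoxon's signed-rank (exact null for n ≤ 25
without ties/zeros, normal approximation with continuity correction
above).  All-zero differences report p = 1 with a flag.  Simulation
shows the two-stage procedure's type-I error stays near the nominal
0.05 (≈ 0.05 at n = 10 over 5,000 Gaussian-null replicates).  Group
comparisons use one-way ANOVA with Holm-Šidák pairwise post hocs when
every group passes the gate, else Kruskal-Wallis with Dunn's rank
z-tests (tie-corrected, Holm-adjusted so adjusted ≥ raw).  Percent
changes are 100·(post - pre)/pre, reported at full precision and
rounded to the nearest integer; published drug-effect percentages
reproduce under this convention except two values (a 28% and a 49%)
that appear to have been truncated rather than rounded.

## Reproduction script problem sizes

`scripts/acceptance.py` uses: the published condition means for the
worked-example percent changes (n = 34/10/8/12 cells) and the published
34/6/10 type sizes for the cluster share; 30-point F-I grids with 100
noisy replicates (σ = 2 Hz) for Hill recovery; a 25-cell (17/3/5)
synthetic cohort for clustering recovery; single preset-type1 cells per
drug condition for the direction contracts; one 60 s PSC trace
(2 Hz, amplitudes ≥ 8 pA, 1.5 pA noise) for detection performance; and
5,000 replicates at n = 10 for the statistical-gate calibration.  These
sizes give stable results across seeds (clustering ARI and drug
directions are seed-independent at the default noise levels) while the
whole script completes in well under a minute.

## Known limitations

- The generator's drug effect sizes are calibrated to reproduce
  directions, not published effect magnitudes; percent changes from
  simulated cohorts will not numerically match published values.
- Burst/adaptive cutoffs (0.5× median; 1.3 ratio) are operational
  choices; real classifications may differ near the boundaries.
- The AHP windows are anchored at the spike peak; analyses anchored at
  threshold crossing will report slightly different latencies.
- Cp = τ/R_in assumes a single passive compartment; for sag-rich cells
  the estimate is biased by the active conductances.
- ABF/NWB readers are adapters requiring optional third-party backends
  (`pyabf`, `pynwb`); the native format is the TSV sweep dialect.
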