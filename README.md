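# patchkit

Analysis of whole-cell current-clamp recordings from cortical
interneurons: per-cell electrophysiological feature extraction,
Hill-sigmoid F-I characterization, spontaneous-event detection,
unsupervised typing, and normality-gated drug-condition statistics —
plus a synthetic-neuron generator with exact ground truth so the whole
pipeline is testable without laboratory data.

It is written for electrophysiologists and neuroinformatics developers
who run square-pulse protocols (500 ms depolarizing step families in
+10 pA increments, a -200 pA sag/rebound pulse, a -10 pA test pulse,
gap-free records at 20 kHz) and want the standard desk analysis as a
scripted, reproducible pipeline instead of a point-and-click session.

## What it computes

**Features (18 per cell).** Rheobase, membrane capacitance, resting
potential, input resistance, maximum and mean firing rate, sag
amplitude, rebound spike, burst-or-adaptive firing pattern, fast and
medium AHP, F-I midpoint and steepness, membrane time constant, spike
threshold (5 mV/ms dV/dt criterion), amplitude change, AP half-width,
and mean inter-spike interval. Spikes are 0 mV-overshooting events;
spikes under 5 mV amplitude are excluded as spikelets.

**F-I curves.** Firing rate F against injected current x is fitted with
the Hill sigmoid

    f(x) = a · x^b / (c^b + x^b)

where `a` is the maximum rate (Hz), `c` the midpoint (pA, f(c) = a/2),
and the neuronal gain is reported as the midpoint slope
f′(c) = a·b/(4c) in Hz/pA. The fit is exposed statsmodels-style:
`HillModel(curve).fit()` returns a results object with parameters,
diagnostics and a `summary()` table.

**Events.** Spontaneous APs by threshold search; spontaneous PSCs by
Clements–Bekkers optimally-scaled template matching (score
scale/√(SSE/(N−2)), criterion 3.5, 5 pA amplitude cutoff).

**Typing.** Ward minimum-variance clustering of the z-scored feature
matrix cut at k = 3, random-forest feature importances with
cross-validated accuracy, and a PCA factor map.

**Statistics.** Shapiro–Wilk-gated paired t / Wilcoxon tests and
ANOVA + Holm–Šidák / Kruskal–Wallis + Dunn group comparisons, with
percent-change summaries.

See `docs/methods.md` for the model equations, operational definitions
and design choices.

## Worked example

Simulate the continuous-adapting reference neuron, extract its
features, and fit the F-I curve:

```python
from patchkit import synth
from patchkit.features import excitability_scalars, passive_properties
from patchkit.fihill import HillModel, build_fi
from patchkit.synth import Protocol, simulate_sweeps

spec = synth.make_presets()["type1"]
steps = simulate_sweeps(spec, Protocol(kind="step_family"), "control", seed=1)
exc = excitability_scalars(steps)
print("rheobase: %.0f pA   max rate: %.0f Hz   pattern: %s"
      % (exc.rheobase_pA, exc.max_freq_Hz, exc.burst_or_adaptive))

test = simulate_sweeps(spec, Protocol(kind="test_pulse", repeats=20),
                       "control", seed=1)
sag = simulate_sweeps(spec, Protocol(kind="sag_pulse"), "control", seed=1)
p = passive_properties(test, sag)
print("R_in: %.0f MOhm   tau: %.1f ms   Cp: %.0f pF   sag: %.1f mV"
      % (p.R_in_MOhm, p.tau_ms, p.capacitance_pF, p.sag_amplitude_mV))

print(HillModel(build_fi(steps, exc.counts)).fit().summary())
```

prints

```
rheobase: 60 pA   max rate: 38 Hz   pattern: adaptive
R_in: 409 MOhm   tau: 28.3 ms   Cp: 69 pF   sag: 12.9 mV
Hill F-I fit: f(x) = a x^b / (c^b + x^b)
  n points                    20
  a (max freq, Hz)        52.683
  b (exponent)             2.859
  c (midpoint, pA)       145.869
  gain a*b/4c (Hz/pA)     0.2581
  RMSE (Hz)                0.827
  converged                 True
  note: plateau extrapolated beyond observed rates
```

The cell fires from 60 pA, adapts (ISIs lengthen through each step),
and its fitted F-I curve reaches half of its 52.7 Hz ceiling at
146 pA with a gain of 0.26 Hz per pA of injected current; the plateau
note says the 200 pA protocol did not fully saturate the cell, so the
ceiling is an extrapolation.

## Command line

The `patchkit` console script orchestrates end-to-end runs:

```sh
patchkit demo --out demo_out --seed 1        # 25-cell cohort, control vs baclofen
patchkit run --config myrun.cfg              # config-driven pipeline
patchkit simulate --scenario cell.cfg --seed 3 --out sweeps.tsv
patchkit fit --sweeps sweeps.tsv --out hill.csv
patchkit cluster --features features.csv --k 3 --seed 1 --out out/
```

A run writes the feature matrices, Hill-fit table, cluster labels,
importance and PCA tables, paired comparisons, and a JSON manifest;
re-running the same config reproduces every table byte-for-byte.
Sweeps travel in a diff-able TSV dialect (`patchkit.io`); ABF/NWB
adapters are available when `pyabf`/`pynwb` are installed.

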