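# spikephase

Intrinsic-excitability analysis for somatic current-clamp recordings of
cortical pyramidal cells — the measurement pipeline behind a typical
"Table 1" of a patch-clamp study — together with behavioral scoring
formulas, two-group statistics, and a conductance-based synthetic-trace
simulator that makes every extractor testable by parameter recovery.

## Who this is for

Cellular electrophysiologists (and modelers validating extraction code)
who need reproducible, scriptable versions of the standard intrinsic
measurements:

* **Passive properties** — resting membrane potential (RMP); input
  resistance `Rin = ΔV_ss / ΔI` from a −100 pA step; sag ratio
  `(|peak| − |steady state|)/|peak|` of the hyperpolarizing deflection,
  with the `> 5 %` prominent-H-current classification.
* **Single-AP features** (from the rheobase sweep) — threshold at the
  dV/dt = 20 V/s crossing, peak amplitude, half-width at half amplitude
  above threshold, medium afterhyperpolarization (mAHP = threshold −
  trough within 100 ms), dV/dt extrema.
* **Spike-train features** — rheobase, spike latency, the F–I curve, the
  current evoking a 7-AP train, ISI₁, ISI₆ and the accommodation ratio
  `(ISI₆ − ISI₁)/ISI₆`.
* **Phase-plot decomposition** — the somatic AP upstroke contains an
  axon-initial-segment (AIS) component followed by a somatodendritic
  (SD) component, separated by a trough of d²V/dt²; with `b` the peak
  dV/dt and `a` the maximal SD slope, the **Slope_SD ratio `a/b`**
  indexes the perisomatic (Nav1.2-like) sodium contribution.
* **Behavioral scores** — prepulse inhibition
  `PPI = 100 − (prepulse-trial startle / startle-only startle) × 100`,
  radial-arm-maze working-memory errors (re-entry into a visited arm),
  open-field jump time (Z-axis-only beam-break bins).
* **Group statistics** — per-group Shapiro–Wilk routing into a
  two-tailed unpaired t-test or a two-sided Mann–Whitney U (exact by
  enumeration for pooled n ≤ 12, ties included), mean ± SEM summaries,
  and immunoblot loading-control normalization.

The simulator is a two-compartment (soma + AIS) Hodgkin–Huxley-style
model whose dials map one-to-one onto the measurements: the HCN-like
conductance drives the sag, the SK-like conductance the mAHP and
accommodation, and the somatic/AIS sodium balance the Slope_SD ratio —
so extractors are validated by recovering what the simulator put in.

## Worked example

```python
from spikephase import NeuronParams, ProtocolSpec, simulate_cell, passive_features
from spikephase.spikes import extract_cell_features
from spikephase.phase import first_ap_of_train, slope_sd_ratio

rec, truth = simulate_cell(NeuronParams(), ProtocolSpec.default_ladder(), seed=7)
pf = passive_features(rec)
fs = extract_cell_features(rec)
sweep, ap1, _ = first_ap_of_train(rec)
dec = slope_sd_ratio(sweep, ap1)
print(pf.rmp, pf.input_resistance, fs.train.rheobase, dec.slope_sd_ratio)
```

prints (for the default cell, seed 7):

```
RMP             -67.7 mV      Rin        129 MOhm     sag 0.104
rheobase          150 pA      threshold  -45.0 mV     half-width 1.09 ms
mAHP             25.5 mV      dV/dt max  349 mV/ms
7-AP train at     350 pA      ISI1 58.9  ISI6 78.3    accommodation 0.25
Slope_SD ratio  0.845         (a = 309, b = 366 mV/ms)
```

— a model cell resting at −67.7 mV with a 129 MΩ input resistance and a
prominent sag, firing from 150 pA with an accommodating train; 84.5 %
of its peak upstroke slope is carried by the somatodendritic component.
The `examples/` directory holds one narrative script per capability
(simulation + extraction, phase decomposition, group comparison,
behavioral scoring); each prints the numbers above with a line on what
they mean.

A thin CLI wraps the pipeline:
`spikephase all --n 10 --seed 1 --out results/` simulates a two-group
cohort and writes `features.csv`, `comparison.csv`,
`subgroup_comparison.csv` (prominent-H cells only) and
`provenance.json` (config hash + seed; reruns are byte-identical).

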