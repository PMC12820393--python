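# protprof

Fecal protease activity profiling from kinetic fluorogenic-substrate plate
assays.

Proteolytic activity in stool is a candidate non-invasive readout for
distinguishing gastrointestinal disorders — ulcerative colitis (UC) and
Crohn's disease (CD) within inflammatory bowel disease, and irritable bowel
syndrome (IBS) — from healthy controls (HC).  The assay this package
analyzes incubates diluted stool extracts with a panel of 14 short
peptide–AMC conjugates (elastase-, furin-, SKI-1/S1P-, trypsin- and
cathepsin-like motifs) at four pH levels (5.5, 6.5, 7.5, 8.0) in black
96-well plates, reading fluorescence every 5 minutes for 75 minutes.
Cleavage of the terminal peptide bond releases the AMC fluorophore, so the
early slope of each progress curve, in relative fluorescence units per
minute (RFU/min), estimates motif-specific protease activity.

`protprof` implements the full analysis chain plus a synthetic-data
generator with emitted ground truth, so the whole pipeline is testable
without any measured data:

1. **Plate I/O** — tidy long-format kinetics CSVs, sample sheets, the
   packaged 14-substrate panel, and layout validation.
2. **QC** — per-extract intrinsic fluorescence (extract + buffer wells,
   no substrate); exclusion of extracts whose baseline exceeds an absolute
   or empty-well-referenced adaptive threshold
   (`mean(empty) + k·SD(empty)`, default `k = 10`); subtraction of each
   extract's intrinsic trace from its digestion curves.
3. **Kinetics** — per-plate normalization by
   `factor(plate x) = mean empty-well RFU of plate x / reference value`
   (reference value: the same quantity on a designated reference plate);
   deterministic detection of the early linear phase (windows within the
   first 20 min, longest first, accepted when the maximum deviation from
   the window's own least-squares line is within a tolerance plus a
   tail-noise allowance); ordinary least-squares slope = activity in
   RFU/min; mean ± SD over triplicates.
4. **Profiling** — the samples × (substrate, pH) activity matrix, cohort
   mean profiles (the heatmap view), and normalized substrate- or
   class-level contributions `f(unit) = rate(unit) / Σ rate` with negative
   means clamped to zero.
5. **Statistics** — two-sided Student's pooled-variance t-tests (Welch
   optional) with 95% CIs, paired tests for matched disease phases,
   ROC/AUC for single-substrate discrimination (AUC = tie-aware
   Mann–Whitney probability), percent inhibition
   `100·(1 − rate_inhibited / rate_control)` for paired inhibitor/control
   plates, and optional Benjamini–Hochberg correction.
6. **Pipeline/CLI** — `protprof run` executes simulate → QC → kinetics →
   profiling → stats into a deterministic report bundle with a manifest of
   every threshold applied.

## Worked example

The packaged demo configuration simulates a small campaign (19 samples in
four cohorts, 14 substrates × 4 pH, triplicates, ~20% high-background
extracts) and runs the full chain:

```sh
protprof run --config src/protprof/data/demo_config.yaml --out demo_bundle
protprof report --bundle demo_bundle
```

prints

```
protease activity profiling report
==================================
config hash: 861183bd1d7f  seed: 20
19 samples on 56 plates; 3 samples excluded (QC threshold 200.4 RFU)

cohorts:
  CD: 5 samples; most active substrate Ac-KHPHLVRQKR-AMC
  HC: 3 samples; most active substrate R-AMC
  IBS: 3 samples; most active substrate Pyr-RTKR-AMC
  UC: 5 samples; most active substrate Ac-RRHL-AMC
...
cohort comparisons: 168 tests, 94 with p < 0.05

ROC discriminations:
  UC_vs_CD:Ac-RSVL-AMC:pH5.5: AUC = 1.000
```

Reading this: three samples were excluded because their intrinsic
(substrate-free) fluorescence exceeded the adaptive empty-well threshold of
200.4 RFU — these emulate extracts contaminated by soluble fluorophores.
The per-cohort "most active substrate" lines recover the simulated group
structure (furin-motif dominance in IBS, broad elevation with strong
cathepsin-like cleavage in UC), and the cathepsin substrate Ac-RSVL-AMC at
pH 5.5 separates the simulated UC and CD cohorts (at these small cohort
sizes the sample AUC is saturated; the generator's group-mean ratio is 2:1
with lognormal CV 0.6).  The bundle directory holds the underlying CSVs:
QC report, activity table, cohort profile, contributions, stats report, ROC
curves, and a manifest with every policy and normalization factor used.

The heatmap view of cohort profiles is available from the library:

```python
from protprof.profiling import plot_profile_heatmap
```

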