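# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `protprof`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The measurement model

A digestion well contains diluted stool extract plus one fluorogenic
peptide–AMC substrate in a pH-controlled buffer.  Cleavage of the terminal
peptide bond releases free AMC, whose fluorescence (excitation ~365 nm,
emission ~460 nm) accumulates in proportion to cleaved product.  Early in
the reaction, before substrate depletion, product accumulates linearly in
time, so the slope of the initial portion of the progress curve — in
RFU/min — is the activity estimate.  Because stool extracts are complex
mixtures of host and microbial proteases with overlapping specificities,
the readout is substrate-centric: a rate quantifies the cleavability of a
motif, not the concentration of any single enzyme, and no conversion to
molar units is attempted (no AMC standard curve is part of the pipeline).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes; it
is first-class, tested code, not a fixture.

**Progress curves.** `RFU(t) = g_p (B_i + v τ (1 − e^{−t/τ})) + ε` with
`ε ~ N(0, σ_noise²)` per read.  The single-exponential product-formation
curve is the simplest model with an exact linear early phase (slope `g_p v`
at `t = 0`) and a saturating tail; `τ → ∞` gives an exactly affine trace.
Defaults: reads at 0, 5, …, 75 min; `τ = 40` min (visible curvature after
~15–20 min); `σ_noise = 15` RFU.  Noise is additive and homoscedastic — a
deliberate simplification; real plate reads are roughly signal-proportional
at high intensity.  Because noise is added after the gain, the "scaling
gains scales all RFU by k" property is exact only in the noiseless limit,
and is tested there.

**Cohort structure.** True rates are
`v[i, s, pH] = μ[cohort(i), s, pH] · exp(N(0, σ²))` with
`σ² = ln(1 + cv²)`; default `cv = 0.6` ("considerable" inter-individual
variability; no quantitative spread is available to emulate, so this is a
free parameter chosen to make cohorts overlap visibly without destroying
group trends).  The multiplier is drawn independently per (sample,
substrate, pH).  An alternative — one shared multiplier per sample,
modelling global protease load — would induce correlations across the
panel; the independent choice is the direct reading of the generative
formula and makes per-condition calibration checks exact.  The limitation:
synthetic per-sample profiles are less correlated across substrates than
real ones, so multivariate classifiers would look artificially weak on
synthetic data (none are part of the pipeline).

**Default effect matrix.** The packaged matrix of mean rates
(`default_effect_matrix`) is *illustrative, not measured*: HC near-silent
everywhere (~3–6 RFU/min); CD and UC broadly elevated (hundreds of
RFU/min) with UC relatively richer in cathepsin-like activity and the only
cohort with strong cathepsin-substrate preference just above neutral pH;
IBS dominated by furin-motif substrates with a dip at pH 7.5; the short
furin substrate Ac-PHLVRQKR-AMC a poor substrate everywhere; the cathepsin
substrate Ac-RSVL-AMC separating UC from CD at pH 5.5 (group means 90 vs
45).  Rates decay to 25% outside a substrate's pH-optimum range and are
globally halved at pH 5.5.

**Backgrounds and gains.** Each sample has a constant-in-time intrinsic
baseline `B_i ~ N(20, 5²)` RFU clipped at zero — soluble fluorophores
(e.g. incompletely absorbed mesalazine) persist after centrifugation, and
no photobleaching drift is modelled (an assumption, encoded as constancy).
With probability 0.2 a sample is a high-background extract and `B_i` is
inflated 50-fold.  Plates have lognormal gains `g_p = exp(N(0, 0.05²))`;
empty wells read `g_p · 50` RFU plus noise, substrate-only wells
`g_p · 30` RFU (no spontaneous hydrolysis drift is modelled).

**Reproducibility.** One seed drives five fixed substreams
(`SeedSequence(seed, spawn_key=(k,))` for k = 0…4: high-background flags,
baselines, rate multipliers, plate gains, read noise), so a dataset is
bit-identical under the same seed and any single stream can be re-drawn in
isolation for recovery tests.

## QC policy

"Excessively high" intrinsic fluorescence is not a universal constant, so
exclusion is a recorded policy: `absolute(threshold_rfu)` or `adaptive(k)`
with threshold `mean(empty reads) + k · SD(empty reads)`, default
`k = 10`.  A sample's score is the mean of its per-plate intrinsic
baselines (contamination is a property of the extract, visible on every
plate).  Every flag records the threshold that produced it.  Excluded
samples are dropped from group statistics but retained, flagged, in the
activity table for audit.  Corrected traces may contain negative reads
(noise); they are kept — slope fitting is offset-invariant, and clipping
would bias low-activity estimates upward.

## Kinetics

**Order of operations** is fixed: (1) divide all reads of a plate by its
normalization factor, (2) subtract the (normalized) intrinsic trace,
(3) window detection, (4) OLS.  Steps 1–2 commute within a plate, and
because OLS slopes scale linearly, normalizing raw traces is equivalent to
normalizing fitted slopes; the raw-trace order is used so every
intermediate trace is on the common scale.  The reference plate is
user-designated, defaulting to the first plate in input order.  Only
relative plate gains are identifiable: rescaling the reference plate
rescales every activity by the same constant, which is why the invariance
tests scale non-reference plates.

**Window detection.** Candidate windows are contiguous read ranges inside
`[0, t_max_window]` (default 20 min — "the first 5–20 minutes" is read as
a window within the first 20 minutes, with configurable bounds) with at
least `min_points = 4` reads spanning at least `t_min_window = 5` min,
ordered longest-first then earliest-start.  The first window whose maximum
absolute deviation from its own least-squares line is at most
`linearity_tol · (RFU span) + 3 · noise_estimate` is accepted;
`noise_estimate` is the SD of first differences over the trace tail (reads
past the window bound).  An R²-threshold rule was rejected because R² is
undefined-to-meaningless on flat traces, and near-zero traces are common
(healthy controls).  Instead, traces whose full-window slope is below
`activity_floor_rfu_per_min` (default 1.0) skip the search and report the
default window with `low_activity = true`.  If no window passes, the one
with the smallest deviation-to-allowance ratio is returned (deterministic
tie-break by enumeration order).  The detector is validated against an
independently coded exhaustive search.

**Slopes and replicates.** OLS via `scipy.stats.linregress`; the intercept
(residual baseline) is discarded; a perfectly flat window returns slope 0
with undefined (NaN) R².  Replicates aggregate to mean and sample SD
(n − 1); a single replicate reports SD as missing, never 0.  Negative
fitted slopes are retained (they are legitimate noise realizations around
zero) and clamped only where a non-negative quantity is mathematically
required (contribution fractions).

## Profiling

Cohort profiles are arithmetic means over non-missing, non-excluded
samples, with the contributing n recorded per cell.  Contributions are
computed from cohort means (matching the mean-based heatmap view) rather
than per-sample-then-averaged — the alternative would weight samples
equally rather than RFU-equally and is noted as a variant, not
implemented.  Normalization scope is `per_ph` by default (each (cohort,
pH) block sums to 1); `across_ph` pools all pH conditions per cohort.
Negative means are clamped to zero for fractions only; raw means are
reported unclamped.  Heatmap rendering clips display values (default
0–600 RFU/min) without touching stored data.

## Statistics

Student's pooled-variance t-test (not Welch) is the default to match the
equal-SD assumption of the emulated design; Welch is available behind a
flag.  All p-values are two-sided.  Degenerate-variance conventions are
fixed and documented: both groups constant and equal → statistic 0,
p = 1; constant and unequal → ±∞, p = 0.  No multiple-testing correction
is applied by default across the 14 × 4 substrate/pH grid (matching the
emulated analysis); Benjamini–Hochberg is available and recorded when
used.  For acute-vs-remission comparisons of the same patients the paired
test is the default for matched phases (the unpaired form is also
available, as both appear in practice for such designs).

ROC curves threshold at every distinct score; the AUC equals the
trapezoidal area and the tie-aware Mann–Whitney probability exactly
(curve construction via scikit-learn; correctness is cross-checked in
tests against brute-force pairwise enumeration, which is kept independent
of the implementation).  Percent inhibition is
`100 · (1 − rate_inhibited / rate_control)`, undefined (missing) for
non-positive control rates, and negative values (apparent activation) are
reported as-is.  Paired inhibitor/control plates are normalized against
the control plate's empty-well mean — a shared reference — so
plate-gain differences cancel before rates are compared.

## Verification strategy and problem sizes

Tests favour exact oracles: closed-form curves, hand-coded OLS and pooled-t
formulas, brute-force window search and pairwise AUC, and
simulation-recovery checks against emitted truth.  Problem sizes are
chosen to make each property sharp at desk scale: 500 traces for slope
recovery (noise at 2% of final signal gives ~93–94% coverage of ±2·stderr
intervals, the t-distribution value for 14 residual degrees of freedom);
1000 random traces for the window-detector equivalence; 200 samples with a
50× baseline multiplier for QC recovery (the contaminated and clean
baseline distributions are then separated by far more than the adaptive
threshold width, so exact recovery is the correct expectation); 50
samples/cohort for the 30% cysteine-fraction construct; 10,000 replicates
for t-test null calibration; 5000 per group for the binormal AUC construct
(separation `√2·Φ⁻¹(0.73)`, giving a true AUC of 0.73).  Exactness claims
(offset cancellation) are tested bitwise on a dyadic RFU grid, where
offset additions are lossless in binary floating point.

## Known limitations

- No Michaelis–Menten inference, pH–activity continuous curves, or
  enzyme-concentration calibration; rates are relative (RFU/min).
- The generator does not model signal-proportional noise, read dropout,
  edge effects, within-plate spatial gradients, or microbiome composition.
- Vendor plate-reader exports (wide grids, binary/xlsx) must be
  pre-converted to the tidy CSV; only that layout is parsed.
- Synthetic cohort effects are illustrative; passing recovery tests shows
  the estimators are correct under the stated generative model, not that
  real cohorts separate.
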