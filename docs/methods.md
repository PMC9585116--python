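# Methods

`exposcreen` reimplements, as a tested pipeline over synthetic data with
known ground truth, the desk side of a non-targeted LC-QTOF suspect-screening
comparison of two pregnancy cohorts (Fresno and San Francisco): feature-level
quality control, suspect matching and deduplication, isomer annotation,
propensity-matched differential-detection statistics, and external
comparisons against a targeted silicone-wristband screen and tract-level
pollution percentiles.

## The synthetic study

No public data exist for this design, so every input is generated by
`exposcreen.synth` with the effect structure recorded in a ground-truth
sidecar (`truth.json`).  Defaults emulate the study's shape at desk scale:

* **Cohort** — 75 participants per city; four categorical matching
  covariates (age category, race/ethnicity, education, marital status) whose
  distributions differ by city, so matching is non-trivial; cord serum for
  ~85% of participants.  Tract percentiles: Fresno pesticide percentiles
  Beta(4, 1.6)·100 versus Beta(1.2, 8)·100 in San Francisco (stochastic
  dominance), pollution-burden percentiles moderately higher in Fresno.
* **Chemical database** — configurable number of unique formulas (default
  300 at pipeline scale) with monoisotopic masses uniform on the 100–1000 Da
  scan range and 1–6 isomers each; PubMed/PubChem mention counts and
  production volumes are log-normal (heavy-tailed) so min–max-scaled
  evidence discriminates; isomers carry zero or more source categories.
* **Panel and effects** — 120 assayable chemicals (one isomer per formula).
  20% are differentially detectable: presence probability 0.9 in Fresno vs
  0.3 in San Francisco (10% reversed).  Null chemicals share one presence
  probability per chemical, uniform on (0.2, 0.8).  Pesticide-annotated
  chemicals additionally shift their detection log-odds by
  `coupling · (pesticide_pctile − 50)/50` with default coupling 1.5.
* **Abundance model** — log-normal: when a chemical is present in a
  participant, log abundance is `μ_c + batch_shift + σ·(√r·z_p + √(1−r)·ε)`
  with `μ_c ~ U(ln 12000, ln 80000)`, `σ = 0.5`; the shared participant
  latent `z_p` with `r = 0.7` induces the maternal–cord log-abundance
  correlation.  Absent cells are 0.  Detection is operationalised as
  abundance ≥ 5000, matching the pipeline's detection limit.  No abundance
  distribution is reported for data of this kind; log-normal is the natural
  choice given the pipeline's log transformation.
* **Batches** — San Francisco samples split over batches 1 and 2, Fresno in
  batch 3 (city–batch confounding is part of the design under test);
  additive log shifts per batch default to (0, +0.5, −0.5).
* **Mass error** — Gaussian in ppm, truncated at ±5 ppm (the instrument's
  worst-case accuracy), SD 0.8 ppm.  The SD is calibrated to the
  mass-accuracy-only match score (below): a continuously reference-mass
  corrected QTOF keeps typical residual error well under 1 ppm, and with SD
  0.8 about 94% of true features pass the score-70 gate.  A wider SD (e.g.
  2 ppm) makes half the panel batch-exclusive, which the location/scale
  batch correction then erases — an interaction worth simulating
  deliberately, not by default.
* **Retention time** — chemical base RT uniform on (0.5, 18.5) min;
  between-batch jitter SD 0.2 min, within-batch SD 0.1 min, so cross-batch
  matching is exercised but usually succeeds inside the 0.5-min window.
* **Nuisance structure** — two technical replicates per sample
  (multiplicative log-SD 0.05), a 2% rate of singleton extractions (one
  replicate zeroed), 20% of chemicals ionising in both modes (secondary
  mode scaled 0.7×), 10% of chemical-batch-mode features spawning a split
  duplicate (same noise model for mass, RT within ±0.35 min of the parent,
  thinner presence), and 10% of chemicals receiving water-blank signal at
  0.8× their typical abundance so most of their sample cells fail the 2×
  blank rule.
* **Wristbands** — a 120-chemical targeted screen, 70% of it sharing
  formulas with the serum database and the rest emulating GC-only analytes
  (PCB-like formulas absent from the LC database); 55% of screen chemicals
  are present in the environment at all, with per-chemical detection
  probability uniform on (0.05, 0.9); wear time ~N(35, 5) days (floor 7),
  silicone mass ~N(4.5, 0.3) g.  Wristband concentrations are *not* coupled
  to serum abundances, so the cross-platform abundance correlation is null
  by construction.

What the generator does **not** emulate: raw chromatograms or spectra,
adducts and isotopologues, correlated chemical co-occurrence, non-detects
with left-censored intensity, missing covariates, or any coupling between
wristband and serum levels.  Passing tests therefore demonstrate that the
pipeline's logic and statistics behave as specified under a known
generating model — not that the instrument-side assumptions hold for real
sera.

## Feature pipeline conventions

All boundaries are inclusive and covered by tests:

* **Blank rule** — per batch, the mean water-blank abundance of a feature is
  the procedural-blank reference; a study-sample cell is kept iff it is
  ≥ 2× that reference (exactly 2× qualifies).  Filtering is applied per
  cell, the conservative reading that reduces to whole-feature removal when
  every cell fails; a feature with no surviving study cell is dropped.
  Matrix blanks and spikes are carried in QC output but not used to filter.
* **Formula matching** — nearest database formula by |ppm| (denominator:
  formula mass), tolerance 5 ppm.  The vendor match score (mass accuracy +
  isotope patterns) is irreproducible without raw spectra; the score here is
  `100·(1 − |ppm|/5)`, so the conventional threshold of 70 corresponds to
  |ppm| ≤ 1.5.  Both knobs are config keys.  Unmatched features are counted
  in `qc_report.json` and dropped from suspect analysis.
* **Detection** — abundance ≥ 5000, applied before duplicate ranking and
  re-applied after batch correction.
* **Duplicates** — within a formula group, two features match if their
  masses differ by ≤ 15 ppm of the smaller mass and RTs by ≤ 0.5 min;
  groups are connected components of this relation (features sharing a
  match are duplicates even if they do not match each other).  One feature
  per group is retained: highest detection frequency, ties to smaller
  |ppm error|, then smallest feature id — which makes the retained set
  invariant to input order (property-tested, with a BFS oracle for the
  components).  The same relation merges modes within batch and harmonizes
  chemicals across batches; a cross-batch component holding two same-batch
  features keeps the higher-frequency one per batch and warns.
* **Replicates** — cells observed in both technical replicates are averaged;
  cells observed in exactly one are treated as not extracted (0).
* **Batch-exclusive chemicals** are kept by default (zero abundance in
  batches that lack them); `drop_unreplicated_across_batches` removes them,
  since the source description of that step is ambiguous.

## Annotation

For a formula with k isomers, the blind probability is 1/k.  The evidence
score is the mean (configurable weights) of PubMed count, PubChem count and
production volume, each min–max scaled over the **whole database** (not
within formula, preserving cross-formula comparability; a constant column
scales to 0; missing values count as 0).  The final score is the plain mean
of blind probability and evidence score; ranking ties break on isomer name.
When several suspect chemicals share a formula, isomers are assigned by
rank: most probable isomer to the chemical with the highest detection
frequency, and so on — a bijection onto the top-k isomers; more chemicals
than isomers is an error at the operation level, and the pipeline-level
annotator leaves the overflow unassigned.

## Statistics

* **Propensity model** — main-effects logistic regression of the Fresno
  indicator on indicator-coded covariates, fitted by IRLS to gradient
  tolerance 1e-8 with a ridge penalty of 1e-6 (intercept unpenalised) so
  separable data remain well-posed.  Cross-checked against statsmodels GLM.
* **Matching** — 1:1 nearest neighbour without replacement on the
  propensity score; Fresno participants processed in descending score
  order, ties to the smaller participant id, making the procedure
  deterministic.  Robustness re-runs perturb scores by a configurable
  jitter.  Matching is done separately per matrix (maternal/cord) on the
  participants with that sample type.
* **Batch correction** — parametric empirical-Bayes location/scale
  adjustment of log abundances (0 → 0.1 before the log): per-chemical
  standardisation after a batch+covariate least-squares fit, per-batch mean
  and variance estimates shrunk toward moment-matched normal /
  inverse-gamma priors across chemicals, iterative joint solve, then
  rescaling and restoration of covariate effects.  Matches `sva::ComBat` to
  ~1e-6 on a frozen reference fixture.  Covariate columns perfectly
  confounded with batch are dropped with a warning; a single batch passes
  through unchanged.  Note the shrinkage scale: for a shift that is uniform
  across chemicals the residual between-batch difference is of order
  0.5·√(δ/n_b) per chemical (≈0.09 log units at 75 samples/batch, ≈0.04 at
  300) — this is the algorithm's behaviour, not an implementation artefact,
  and recovery tests are therefore run at 300 samples/batch.
* **Fisher's exact test** — two-sided by the probability-mass convention:
  the sum of hypergeometric probabilities of all same-margin tables whose
  probability does not exceed the observed one (1e-7 relative slack); any
  zero margin gives p = 1.  Verified against an exact-integer enumeration
  oracle for every table with N ≤ 24 and against scipy on random tables.
  Being an exact conditional test it is conservative: its attained size at
  n = 75 per city is ≈0.037–0.041 rather than 0.05, which the calibration
  tests account for (the unit suite checks type-I rate ≤ nominal).
* **Differential detection** — per chemical, the 2×2 detected × city table
  over matched samples; differential means p < 0.05 with no multiplicity
  correction by default (an FDR option exists).  Abundance ratios are
  Fresno/San Francisco means of post-correction natural-scale abundances
  (`ratio_on_corrected=False` switches to raw).
* **Diagnostics** — batch mixing is quantified as the one-way ANOVA R² of
  batch on the top principal components of the sample cloud, reported
  before and after correction.
* **External comparisons** — wristband concentrations are ng per g silicone
  per week (`raw/g/(days/7)`); wristband detection frequency is the
  fraction of wearers with concentration > 0 (zero being the targeted
  screen's reporting floor).  Cross-platform linkage is by shared formula
  and detection-frequency rank, injective within formula.  Geographic
  correlations are Spearman (midrank ties, t-approximation p), per city,
  between per-participant detected-chemical counts (per source category)
  and tract percentiles.  The serum-abundance versus wristband-concentration
  correlation pools participant-chemical pairs over rank-matched formulas
  on log scales.

## Known limitations

* The city–batch confounding of the study design (Fresno analysed in its
  own batch) means the batch correction absorbs part of any true city
  effect.  Detection-frequency differences largely survive (flag-rate power
  loss is bounded in the acceptance tests), but the correction can invert
  the *abundance* contrast of strongly differential chemicals: their
  post-correction Fresno/SF abundance ratios fall below 1 even when Fresno
  detections dominate.  Interpret corrected ratios as conservative; the raw
  alternative is one flag away.
* Chemicals observed in only a subset of batches carry structural zeros
  into the correction, which drags their detections toward the pooled mean;
  with default noise this affects a small minority of the panel.
* The annotation score is a heuristic prior (literature presence and
  production volume), not spectral evidence; assignments are "suspect"
  level, never confirmations.
* The wristband comparison shares only formulas across platforms, so
  structure-level disagreement is invisible.

## Problem sizes

Default pipeline scale: 300 formulas, 120-chemical panel, 75 participants
per city (150 maternal + ~130 cord samples plus blanks), three batches, two
modes — a full run takes a few seconds.  Simulation-based tests use 100
replicates at study scale for detection-level statistics (Fisher power and
calibration, geographic correlation power), 50 replicates at 60 chemicals ×
150 samples for correction-and-power checks, and 10 replicates at 60 × 600
for shift recovery; these sizes are the package's chosen desk-scale study
conditions and are stated here so reruns can reproduce them.
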