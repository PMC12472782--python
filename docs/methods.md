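# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical edge-case rules.

## Study design and power analysis

The pipeline targets a balanced 2×2 design: genotype (WT vs TG) crossed
with treatment (VEH vs DCI), optionally with sex (M/F) as a stratification
factor. The a-priori power computation assumes the *normalizing-treatment*
scenario: the vehicle-treated transgenic cell sits at
`control × (1 − 0.35)` while WT-VEH, WT-DCI and TG-DCI all sit at the
control mean, with a common within-cell SD of `0.20 × control`. Treating
the WT-DCI cell as unchanged is the minimal assumption consistent with a
treatment that restores the transgenic phenotype; no treatment effect in
wild types is posited.

For a 2×2 cell-mean pattern μ, the two-way decomposition gives interaction
effects `γ_ij = μ_ij − grand − row_i − col_j`. Under this scenario
|γ| = 0.0875 in every cell, Cohen's f = RMS(γ)/σ = 0.4375, and the
interaction F statistic at n per cell is distributed noncentral
F(1, 4(n−1), λ) with λ = n·Σγ²/σ² = 0.765625·n. Power is the upper tail
beyond the central-F critical value at α (the F test is one-tailed; the
"two-sided α = 0.05" of the underlying contrast corresponds to the F test
at α = 0.05, matching standard fixed-effects ANOVA power software).
`solve_n` scans integers upward from 2: power(10) = 0.768,
power(11) = 0.808, so the minimal n is 11 per cell; the working design
adds one animal per cell against attrition (12 per cell, N = 48). A
vectorized Monte-Carlo two-way ANOVA (`monte_carlo_interaction_power`)
serves as an independent cross-check of the analytic power.

## Synthetic data generator

`generate_matrix` emulates the statistical structure the analysis assumes:

- **Baselines** are log-uniform over `10^4 … 10^9` (default
  `baseline_log10_range = (4, 9)`), reflecting abundance spreads of several
  orders of magnitude between the most and least expressed proteins.
- **Spiked effect**: a fraction of proteins (default 5%) carries the
  genotype effect *only in the TG-VEH cell*, at `baseline × (1 ± 0.35)`,
  split evenly between up- and down-regulation so both volcano tails are
  exercised. All other cells, including TG-DCI, sit at baseline
  (treatment normalizes).
- **Noise** is multiplicative Gaussian: `value = cellmean × (1 + ε)`,
  ε ~ N(0, cv²) redrawn when ε ≤ −1 so abundances stay positive. The
  default cv = 0.20 is the design's within-cell variability. cv ≥ 1 is
  rejected (the truncation would dominate the distribution).
- **Depth**: each sample receives a log-normal multiplier
  `exp(N(0, depth_sigma²))` applied uniformly to all its proteins;
  default `depth_sigma = 0.1`, a modest sample-to-sample loading/depth
  variation that normalization must remove. (It is raised in tests that
  specifically exercise depth confounding.)
- **Design size**: `n_per_cell` counts samples per
  genotype × treatment × sex cell when `sexes` is on; the default
  (6 with sexes on) reproduces the working design of 12 animals per 2×2
  cell and 48 samples total.
- **Outliers**: `inject_outliers` multiplies a chosen fraction of cells
  (< 10%) by a gross factor (default 10×) and returns the touched cells,
  providing ground truth for the QC stage. Generation itself is clean by
  default (`outlier_rate = 0`).

A single `numpy` Generator keyed by the seed drives all draws; identical
configs produce bit-identical matrices.

What the generator does **not** emulate: peptide/spectrum-level structure,
missing-at-random censoring (missingness arises only from QC removal),
protein–protein abundance correlation, sex-specific effect sizes, and
heavy-tailed or intensity-dependent error models. Passing the recovery
tests therefore demonstrates correctness of the pipeline's logic under its
own stated assumptions, not performance on real instrument data.

## Outlier QC

Within each genotype × treatment (× sex) group, every value of every
protein gets a score: the mean absolute distance to its k nearest other
values of that protein's group vector, computed on log10 abundances
(distances on raw intensities would be dominated by baseline magnitude).
Defaults: `k = min(3, group n − 1)`; groups with fewer than 3 samples are
skipped with a warning.

Flagging calibration required care at group sizes of 4–6:

- A robust z from the median/MAD of a *single protein's* ≤ 6 scores is far
  too unstable (measured ~10% of clean cells flagged at z = 3.5). The z is
  therefore computed against the **pooled** score distribution of all
  proteins in the group — legitimate because scores live on the log scale,
  where a constant CV gives comparable score magnitudes across proteins.
- Raw KNN distances are strongly right-skewed, and a symmetric robust z on
  them still over-flags (~3% clean); a log transform over-compresses the
  upper tail and misses genuine 10× outliers whose nearest clean neighbour
  happens to sit high. A **cube-root** transform sits between the two:
  on the generator's own noise model it flags every injected 10× cell
  while flagging 0.3–0.6% of clean cells at the conventional z = 3.5.
- Flag-and-remove is **iterated to a fixpoint** (recompute scores and
  pooled statistics on the cleaned matrix, flag again, repeat; typically
  2–4 passes): this makes `remove_outliers` exactly idempotent.

Flagged cells become missing — removed, not imputed; downstream means,
totals and tests use the available values.

## Normalization

All four schemes are per-sample multipliers; missing values are excluded
from totals and means so removed outliers do not deflate factors.

- *down-scaling* (pipeline default): `factor_s = min stratum total / total_s`
  within each sex stratum — factors in (0, 1], at least one exact 1 per
  stratum, post-normalization totals equal the stratum minimum.
- *mean-based*: grand mean of per-sample means over the sample mean.
- *total-count*: grand mean of totals over the sample total.
- *housekeeping*: same form on the mean of reference proteins
  (e.g. β-actin, β-tubulin), which must be present and complete.

`evaluate_normalizations` reports, per method (and raw): the CV of
post-normalization sample totals (averaged across strata), the median
within-cell CV across proteins, and the mean |Δ log2 relative expression|
versus raw over the lowest-abundance quartile — an operationalization of
"consistent results with minimal distortion, particularly for weakly
expressed proteins". The pipeline default remains down-scaling regardless
of the table; the table is reported for transparency. Factor computation
runs after QC by design (a `qc.enabled` flag allows swapping the order by
disabling QC).

## Differential analysis

Per protein, `FC = mean(case)/mean(control)` and `log2FC = log2(FC)`;
records with fewer than one value per side or non-positive means are
`untested`. Testing needs ≥ 3 values per group. Shapiro–Wilk at
α = 0.05 on each group routes to:

- **Student's t** (classical equal-variance form — not Welch) when both
  groups pass;
- **Mann–Whitney U**, two-sided, otherwise — exact null distribution when
  both groups have ≤ 8 observations and no ties (the normal approximation
  is poor at n = 4–6), else the tie- and continuity-corrected asymptotic
  form. Constant groups (Shapiro–Wilk undefined) route here; two constant
  equal groups are `degenerate` with p = 1.

Volcano classification is the joint rule with strict inequalities on p and
log2FC and an inclusive 25% minimum arithmetic change; the cuts +0.32 and
−0.41 are kept as literal constants (they bracket ±25% on the ratio scale:
log2 1.25 ≈ +0.322, log2 0.75 ≈ −0.415) and are exposed as parameters.
Note the pair is asymmetric, so exchanging case and control maps
down→up always but up→down only for |log2FC| > 0.41. No multiplicity
correction is applied at this stage — the network stage deliberately
consumes unadjusted calls to keep interaction subgraphs connected — and
FDR control enters at candidate selection.

Default contrast: genotype (TG vs WT) within the vehicle arm; a treatment
contrast (DCI vs VEH within one genotype) is available.

## Candidate selection

Relative variance is the one-way ratio over the genotype × treatment
cells: sample variance (G−1 denominator) of group means over the pooled
within-group sample variance. Groups need ≥ 2 non-missing values; a zero
pooled variance is guarded by ε = 1e−12 and the ratio capped at 1e12; a
zero between-group variance gives exactly 0. The top ⌈0.05·m⌉ scores are
selected with boundary ties all included (the count may exceed the
ceiling; it is reported). BH adjustment (statsmodels step-up) is applied
to the *selected* candidates' test p-values.

## Network and enrichment (offline)

Live database queries are replaced by local files. STRING-export edge
tables (protein1/protein2/combined_score, integer 0–1000) are filtered at
combined score ≥ 400 ("medium confidence" — the conventional default when
no cut is stated), deduplicated keeping the max score, self-loops dropped.
Components of the significant-protein induced subgraph are returned
largest-first (ties by lexicographically smallest member) with a minimum
size of 3. Enrichment uses the upper hypergeometric tail P(X ≥ overlap)
against a universe defaulting to all quantified proteins (standard
practice; overridable), BH within each annotation category, and a top-20
flag per category (all terms retained in the output).

## Problem sizes and tolerances

Tests and the recovery benchmark run at 2000 proteins × 48 samples over
seeds 1–10 (spiked) and 1–5 (null), sizes at which every stochastic bound
holds with margin while the whole suite stays fast: measured mean spike
sensitivity 0.87 and mean empirical FDP 0.07 against bounds of ≥ 0.80 and
≤ 0.20, and a null (no-spike) call rate of ~0.4% against ≤ 2%. Monte-Carlo
cross-checks use 10⁴ ANOVA replicates and 10⁵ hypergeometric resamples
with 3-binomial-SE tolerances. Exactness checks (BH vs step-up oracle,
exact Mann–Whitney vs label enumeration) use atol ≤ 1e−10.

## Known limitations

- Per-group pooling of KNN scores assumes within-group noise is
  comparable across proteins on the log scale; strongly
  intensity-dependent CVs would mis-calibrate the robust z.
- The down-scaling diagnostic table compares scaling methods only; none
  of the four schemes corrects intensity-dependent (non-linear) bias.
- The exact Mann–Whitney is limited to n ≤ 8 per group without ties;
  with ties the asymptotic approximation is used regardless of size.
- The recovery benchmark measures the spec'd volcano rule, not the
  candidate-selection stage, against truth; relative-variance selection
  is validated structurally (count, ties, FDR) and by spike enrichment.
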