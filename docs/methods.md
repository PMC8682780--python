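# Methods

## Statistical model

The enrichment engine tests, per feature (protein or peptide), whether the
crosslinked condition is enriched over its control. Two designs are
supported.

*One-sample ratio mode.* Each SILAC experiment contributes one
log₂(crosslinked/non-crosslinked) value per protein: +log₂(H/L) for a
forward experiment (heavy channel crosslinked), −log₂(H/L) for a reverse
experiment. The null hypothesis is mean 0. Proteins must be observed in at
least one forward and one reverse experiment (hence ≥ 2 assays) to be
tested — the label-swap requirement removes bead- and channel-specific
artefacts by construction.

*Two-group mode.* Rows are log₂ intensities with a two-level condition
factor (crosslinked vs released fractions at the peptide level; with/without
treatment at the protein level). The estimate is the difference of group
means with pooled variance on n₁ + n₂ − 2 degrees of freedom; unbalanced
and partially missing rows are handled by using the observed counts.

*Empirical-Bayes moderation.* Per-feature sample variances s² with residual
df d are assumed drawn from a scaled inverse-chi-square prior with df d₀ and
scale s₀². The prior is fitted by closed-form moment matching on
z = log s²: with e = z − ψ(d/2) + log(d/2), the excess of Var(e) over the
expected sampling variance ψ′(d/2) determines d₀ via the trigamma inverse
(Newton iteration, tolerance 1e-8, max 50 steps), and s₀² follows from the
mean of e. If there is no excess dispersion the prior is degenerate:
d₀ = ∞ and s₀² is the geometric mean of the sample variances, so every
feature is tested against the common variance with a normal reference
distribution. d₀ = 0 is the no-moderation limit and recovers the ordinary
t-test exactly. The posterior variance is s̃² = (d₀ s₀² + d s²)/(d₀ + d) —
always between s² and s₀² — and the moderated t statistic
t = estimate/(s̃ √v) is referred to a t distribution on d₀ + d df, with
v = 1/n (one-sample) or 1/n₁ + 1/n₂ (two-group). The implementation was
checked against limma's `lmFit`/`eBayes` on a frozen seeded dataset and
agrees to at least six significant figures in d₀, s₀², t and p.

Features whose imputed row has zero variance (e.g. a fully imputed control)
keep s² = 0; moderation gives them s̃² > 0 whenever d₀ s₀² > 0, so they stay
testable rather than producing infinite statistics.

*Multiple testing and tiers.* P-values are Benjamini–Hochberg adjusted
(step-up, NA excluded from the ranking). Calls use strict inequalities:
log₂FC > 1 with adj. p < 0.01 ("highly significant") and adj. p < 0.1
("significant"). Comparative and two-group modes report a single tier at
the 0.1 cutoff, matching the convention of condition-comparison analyses.

## Normalization and imputation

Intensity columns are quantile-normalized **within** each condition group
(crosslinked columns together, control columns together): each column's
observed values are replaced by the per-rank mean of the group's sorted
columns, interpolated linearly when columns differ in their number of
observed values. Missing cells stay missing and rank order is preserved;
columns with fewer than two observed values are left unchanged.

Imputation follows normalization (the pipeline order is normalize →
impute → test). Two rules:

- **Protein-level double purification (five replicates per condition):** a
  row/condition with at most two missing replicates is imputed with the
  mean of the observed ones; a control condition with all replicates
  missing is imputed with each column's observed minimum; three or four
  missing are left missing and fall to the evidence filter.
- **Peptide-level fractions (three replicates per fraction):** only a
  fraction with all replicates missing is imputed, again with the
  per-column observed minimum; partial missingness is handled by the test.

The per-column (rather than global) minimum was chosen because it mirrors
each sample's own detection limit; both choices are defensible, and the
column-wise one degrades gracefully when samples differ in depth.

## Contact mapping

Region annotations (domains and IDRs, 1-based inclusive coordinates) are
first consensus-merged: same-protein, same-class regions whose overlap
covers ≥ 0.7 of the shorter region are merged to their union, iterated to a
fixpoint, which makes the result idempotent and independent of input order.
The 0.7 threshold is a configurable default; "highly overlapping" has no
canonical value.

A peptide matches a region when the interval gap
`max(0, region.start − peptide.end, peptide.start − region.end)` is ≤ 10.
This gap is the minimal residue-to-residue distance between the intervals
(0 when they overlap), so "≤ 10 amino acids from the ends of the peptide"
is interpreted as boundary-coordinate difference: a peptide ending at 87
has gap 9 to a region starting at 96 and matches; gap 11 does not. A
peptide may match a domain and an IDR simultaneously, and a protein whose
peptides reach both classes is reported as "both" rather than prioritized
to either class. Domain-type ranking counts distinct proteins per type,
with names clustered by case-folding and stripping numeric suffixes
(`RRM_1`, `RRM_2` → `rrm`) unless an explicit clustering map is supplied.

Amino-acid composition enrichment is residue-level (length-weighted) over
the concatenated peptides of each set, with one pseudocount per amino acid
per set, reported as log₂(freq_query/freq_reference).

## Synthetic data: what it emulates and what it does not

The generator produces proteomes (lognormal lengths, median ≈ 420
residues), lays 0–3 non-overlapping regions per protein, and draws IDR
segments with elevated P/E/S/G composition and domains with elevated
hydrophobics, so composition recovery is a real signal. A configurable
fraction of proteins (default 10%) is planted as chromatin-enriched with
log₂ effect 2.0; each planted protein carries one contact sub-interval
inside a region of the configured class (default IDR). Tryptic digestion
(cleavage after K/R, including before proline; LysC sites are a subset and
add nothing) enumerates all peptides with ≤ 2 missed cleavages and length
7–35 — typical MS detectability bounds, configurable.

Quantification noise is log-normal with per-feature variances drawn from a
scaled inverse-chi-square law (d₀ = 4, s₀² = 0.09 on the log₂ scale by
default) — deliberately the same family the moderation assumes, so
calibration tests measure the estimator, not model misfit. Cells go
missing with probability logistic in −log₂ intensity (maximum 0.6,
midpoint 21, slope 1 against a baseline abundance of N(25, 2)), emulating
the abundance-dependent dropout that motivates minimum-value imputation.

Not emulated: protein-inference ambiguity (each peptide maps to one
protein), spectra and retention times, inter-protein abundance correlation,
ratio compression, and real annotation noise. Passing recovery tests
therefore demonstrates that the pipeline is correct and calibrated under
its stated model, not that real data meet that model.

Randomness: one master seed; per-stage child seeds are derived by fixed
offsets so each stage is independently reproducible.

## Problem sizes

The packaged recovery scenario uses 500 proteins (≈ 48,000 peptides after
digestion), 10% planted, three forward + three reverse SILAC experiments at
the protein level and three replicates per fraction at the peptide level.
Calibration simulations use 10,000 features with 3 + 3 replicates, five
seeds for the false-discovery proportion, and 2,000 variances for prior-df
recovery. At these sizes the whole test suite runs in seconds on one core.

## Known limitations

- The keyword lists behind the PTP/PFP and three-way categories are
  editable defaults; category proportions on real data depend entirely on
  the annotation source and keyword choices.
- One-sample mode takes SILAC ratios as given (requantification and
  protein inference are upstream concerns).
- The evidence filters operate on observed-value counts only; they do not
  model informative missingness.
- Quantile normalization with heavy, condition-biased missingness can
  distort tails; the generator's missingness (≲ 15% overall at defaults)
  stays well inside the regime where rank interpolation is benign.
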