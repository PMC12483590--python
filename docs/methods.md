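# Methods

This note documents the models and procedures proteoscope implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Site-specific glycan quantification

A *site-specific glycan* is the pair (glycosylation site, glycan
composition); its abundance is estimated by spectral counting — the number
of PSMs supporting that key in a sample, pooled over peptide sequence,
missed-cleavage count and precursor charge. Compositions are parsed from
the Byonic dialect `Token(count)…` into a multiset and canonicalized
(HexNAc, Hex, Fuc, NeuAc, then other tokens alphabetically), so spelling
variants of the same composition collapse to one key. If spectrum
identifiers are supplied, duplicates are rejected to prevent double
counting.

Classification uses mutually exclusive priority classes:
**sialylated** (NeuAc ≥ 1) ≻ **fucosylated** (Fuc ≥ 1) ≻
**high-mannose** (HexNAc = 2 and Hex ≥ 5) ≻ **other**. Priority ordering
is required because the three headline classes are reported as an
exhaustive partition; sialylated-and-fucosylated glycans are counted as
sialylated. High-mannose uses the standard biochemical definition
(chitobiose core, ≥ 5 mannoses, no decoration). Class fractions count
distinct keys, not spectra.

The consistency filter keeps a key if, in at least one cell line, it has
nonzero counts in **strictly more than half** of that line's replicates
(2 of 3 qualifies; 1 of 2 does not). The replicate denominator comes from
the sample metadata, not from the PSM table, so a replicate with no PSMs
at all still counts toward "half of the replicates".

## Abundance preprocessing

The pipeline order is filter → impute → transform → collapse, enforced by
scale tags on the matrix container (out-of-order calls raise). Detection
means non-missing **and** > 0.

* Detection filter: drop features detected in < 5% of samples (default,
  configurable).
* Imputation: every missing cell gets the single global minimum observed
  intensity, on the raw linear scale — a left-censoring reading of MS
  missingness. Imputation before transformation is the conservative
  ordering when the imputed value is a raw-scale minimum.
* log2(x+1) transform, then each sample column is shifted so its median
  equals the grand median of column medians. Any common target is
  equivalent up to a constant; the grand median keeps values in the data's
  own range.
* LogNormalize (`ln(1 + 10⁴·x / column sum)`) is provided for
  marker-scoring workflows; the scale factor is the upstream tool's
  default and configurable.
* Replicates are collapsed by arithmetic mean on the log scale.

Fold change is a difference of log2 means (group minus complement), not
the log of a ratio of linear means; the two differ under skew and the
difference-of-means form matches how the collapsed matrices are built.
Differential expression is a two-sided Wilcoxon rank-sum test per feature,
one group vs rest (exact distribution for small untied samples, normal
approximation with tie correction otherwise), Bonferroni-adjusted by the
total feature count; a feature is significant only when |log2FC| > 2 *and*
adjusted p < 0.05. Constant features get p = 1 by convention.

Marker scoring follows the published COSG formulation: with cᵢₖ the cosine
between feature i's expression vector (missing → 0, non-negative linear
scale) and group k's L2-normalized indicator,

    score = c³ / ((1 − μ)·c² + μ·Σₖ c²),   μ = 1 by default.

A feature expressed only and evenly in one group scores exactly 1
regardless of μ; a uniform feature scores (|g|/n)^{3/2} at μ = 1.
Zero-norm features score 0. Markers are flagged at score > 0.5.

## Kinase activity

Phosphosites are filtered at localization probability strictly > 0.75
(class-I sites). KSEA compares each kinase's substrate fold changes
against all measured sites in the same line:
z = (mean_s − mean_p)·√m / sd_p, two-sided normal p, BH FDR across kinases
*within* each line (the natural grouping when lines are screened
independently), active ⇔ FDR < 0.05 and m ≥ 6 ("more than five" read
strictly). Per-line fold change is the collapsed log2 value minus the mean
of all other lines.

The driver screen works on linear-scale replicate-level matrices, protein
and per-protein summed phosphosite intensity. A feature is a hit in its
top line (which must agree between levels) when the top-line mean is
≥ 1.5× every other line's mean at both levels, and the minimum replicate
in the top line strictly exceeds 50% of the maximum replicate in any
*other* line at both levels. The floor clause's reference population is
ambiguous in prose ("the rest" could mean other lines or the same line's
other replicates); the other-lines reading is the stricter default and the
same-line reading is available via `floor_reference="same_line"`.

Phospho-protein coupling is the per-site Spearman correlation with the
parent protein across cell lines, binned strong (r > 0.6), moderate
(0.4 < r ≤ 0.6), weak (0.2 < r ≤ 0.4), none (r ≤ 0.2); pairs with fewer
than 5 jointly observed lines are excluded and counted. Protein-adjusted
phosphosites are site log2 minus parent-protein log2 per line.

## MS ↔ RPPA

RPPA normalization is two-pass median centering of the antibody × sample
log2 matrix: the antibody margin first, then the sample margin. Each pass
zeroes its own margin exactly (bit-exactly when that dimension is odd,
because the median is then a data element); the first margin is generally
*not* still exactly zero after the second pass — one pass each is the
procedure, not a full median polish. The optional "linear" view is the
antilog 2^x of the centered values (the squaring wording in RPPA
NormLinear pipelines refers to base-2 antilogging; literal x² would
destroy sign).

Antibodies map to MS features via a representative accession. Detection
coverage partitions the non-phospho panel into ms_majority (target
detected in strictly more than 50% of samples), ms_minority (detected, but
in at most 50%) and ms_absent (unmapped or never detected). Concordance is
per-protein Spearman across collapsed cell-line values, and fold-change
concordance computes per-protein log2 FC between two line groups
identically on both platforms (each on its own normalized scale) and
correlates the FC vectors across proteins.

## Copy-number association

Copy number is log2(CN ratio + 1) (diploid → 1). Associations are
Spearman correlations across shared cell lines between a gene's copy
number and a feature's abundance; cis means the feature is the gene's own
product. Because the full gene × feature cross-product is quadratic, the
trans scan is restricted by default to a caller-chosen subset (explicit
lists or top-n by variance); hotspot summaries count associations with
|r| above a configurable threshold per chromosome arm, cis and trans
separately. No significance rule is claimed for hotspots; the threshold is
exposed.

## Synthetic data generator

The generator emulates a 54-line panel (lineage groups 7/8/8/5/5/5/16,
3 replicates) at the search-engine-output level; no spectra, retention
times or m/z are modeled. On the log2 scale: protein base ~ N(20, 2)
(typical LFQ dynamic range), per-(protein, lineage) effects ~ N(0, 0.5),
cell-line effects ~ N(0, 0.8), replicate noise ~ N(0, 0.2) (≈ 14% linear
CV, consistent with most proteins showing replicate CV < 20%). Markers
gain +log2(4) in their lineage and carry no random lineage effect, so the
planted fold is exact at zero noise. Missingness is left-censored: dropout
probability is logistic in log-intensity, rescaled so its mean equals the
configured rate (default 0.35, reproducing per-sample detection around
two-thirds of features). Planted kinases add +1.5 log2 to their substrate
sites in one line. Glycan keys draw classes from the mixture
(0.4972, 0.2516, 0.2511, 0.0001) (sialylated, fucosylated, high-mannose,
other) and compositions consistent with each class by construction; PSM
tables are exploded exactly from the drawn counts, so aggregation
bookkeeping can be checked with integer equality. Sparse line/replicate
presence (1% extra-line rate, 25% per-replicate detection) makes roughly a
third of keys consistently detected, matching the sparsity regime of
IMAC-co-enriched glycoproteomes.

Planted rank correlations (MS↔RPPA, CNA cis) use the Gaussian copula:
a Spearman target ρ_s is converted to Pearson ρ_p = 2·sin(πρ_s/6), and
noise SD = √(1/ρ_p² − 1) on a standardized signal. RPPA noise is injected
at the cell-line level (plus a small 0.1 replicate component) so the
*collapsed* comparison hits the target; defaults target a median
per-protein Spearman of 0.6 and cis Spearman of 0.6. One global seed fans
out to fixed per-table child streams, so generating one table never
perturbs another and identical configs are bit-identical.

What the generator does **not** emulate: peptide-level quantification and
razor-peptide ambiguity, batch effects and drift, correlated missingness
across samples, isoform-level antibody cross-reactivity, or realistic
chromosomal segment structure (arms are assigned round-robin). Passing
recovery tests therefore demonstrates correctness and calibration of the
*methods* under a clean generative model, not performance on real data.

## Validation battery and problem sizes

`proteoscope.validation` (used by both `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs: the spectral-counting and
consistency-filter brute-force oracles (1,000 PSMs; 500 rows × 5 lines ×
3 reps), glycan class bookkeeping (800 keys), KSEA null calibration
(1,000 kinases on 10,000 background sites) and power (100 runs, planted
+1.5 shift on SD 0.5), the driver screen (100 recovery + 100 null runs,
100 features × 20 lines × 3 reps, CV 10%), normalization post-conditions,
Wilcoxon type-I control (100 runs × 2,000 features × 54 samples, 7
groups), cross-platform recovery (250 proteins, 54 lines), and CNA
recovery (100 runs of 150 genes, plus 5 hotspot runs with a 15-pair
planted arm scanned against the top-100-variance features at |r| > 0.6).
These sizes keep the battery to roughly a minute on one core.

Known statistical margin: the driver screen's planted 2-fold signal clears
the 1.5-fold rule by log2(2/1.5) ≈ 0.415, about 3.5σ of line-mean noise at
10% replicate CV — so single-run recovery is ≈ 99.5%, not a certainty; the
fixed-seed battery recovers 100/100.

## Numerical conventions

Spearman correlations use average ranks for ties. KSEA raises when the
background SD is zero and omits kinases with no measured substrate.
Degenerate inputs fail loudly: all-missing matrices cannot be imputed,
zero column sums cannot be LogNormalized, empty site-glycan tables have no
class fractions. Bonferroni caps at 1. All randomness flows from a single
integer seed.
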