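# Methods

## Sensitivity correlation

The statistic at the core of the package is the sensitivity correlation
S = ρ_XY − ρ_XY|Z for an (mRNA X, lncRNA Y, miRNA Z) triplet, with the
partial correlation in its first-order closed form. S measures how much
of the X–Y co-expression is explained by the shared miRNA: if X and Y
are co-expressed only because Z represses both, conditioning on Z
removes the correlation and S ≈ ρ_XY; if the co-expression comes from a
common transcriptional program that Z knows nothing about, ρ_XY|Z ≈ ρ_XY
and S ≈ 0. When ρ_XZ = 0 but ρ_ZY ≠ 0 the partial correlation exceeds
the marginal one and S is negative — a miRNA correlated with only one
member of a pair can never look like a mediator.

Correlations are computed on FPKM values as provided (a log1p switch
exists in the pipeline configuration but defaults off) on pairwise-complete
observations, requiring at least three joint observations. Undefined
quantities — zero variance, |ρ| = 1 in the conditioning set — propagate
as NaN and are excluded from selections rather than coerced to zero.

## Thresholds

All thresholds are configuration values with the method's canonical
operating point as defaults, compared strictly:

| parameter | default | role |
| --- | --- | --- |
| missing_max | 0.10 | drop entity if missing-value fraction exceeds it (denominator: all samples, both conditions jointly) |
| utr_min | 500 nt | minimum mRNA 3'UTR length (inclusive: 500 is kept) |
| percentile | 99 | empirical percentile of the full mRNA×lncRNA correlation distribution; pairs strictly above are kept |
| s_threshold | 0.3 | triplets with S strictly above are kept (≈ a 30 % correlation drop) |
| enrichment_alpha | 0.01 | hypergeometric p strictly below passes |
| ttest_alpha | 0.05 | isoform paired t-test p strictly below passes |

No multiple-testing correction is applied to the enrichment p-values:
the raw per-triplet cut is part of the method's definition. Users
performing genome-scale screens should treat the network as a candidate
set, not a family-wise-error-controlled discovery list.

## Seed matching and the enrichment universe

A site is the reverse complement (in DNA alphabet) of the 6-mer seed,
mature-miRNA positions 2–7. Occurrences are counted at every position
(overlaps allowed; ambiguity codes never match); a transcript of length
L has max(L−5, 0) windows. Only the 6-mer class is implemented — no
7mer/8mer classes, thermodynamics or conservation. miRNAs with identical
seeds remain distinct entries sharing a site, because network edges are
per-miRNA.

The hypergeometric test needs a population; the convention here is
window-based: population N = all 6-mer windows over the indexed
transcripts, successes K = all occurrences of the miRNA's site,
sample n = the windows of the pair's two sequences, observed k = their
combined site count, p = P(≥ k) upper tail. This is a declared
convention of the package (the test's universe admits several
constructions); it is exactly unit-tested against combinatorial
enumeration, and its monotonicity in k is asserted as a property.

## Network

An undirected multigraph (competition is symmetric); at most one edge
per (pair, miRNA); node degree counts parallel edges, so a hub's edge
count can far exceed its neighbour count. Edges require enrichment
p < alpha and at least one site on *both* the mRNA's 3'UTR and the
lncRNA transcript. Construction is order-invariant and monotone in
alpha. Hub ranking breaks ties lexicographically for reproducibility.
Rewiring between conditions is summarised by shared/unique node and
(pair, miRNA) edge sets, Jaccard indices and per-node degree deltas.
When a condition yields no edges (a genuinely empty sponge program) the
pipeline halts naming the stage; comparisons then use an explicitly
empty network.

## Isoform titration analysis

"Variation" is the per-patient difference cancer − normal (not the
difference of condition means): the variation matrix has isoforms as
observations and patients as variables, which forces the paired design
throughout. The t-test is the two-sided *paired* Student's t-test on
per-patient differences (the data are matched samples); all-zero
differences give p = 1 by convention (no evidence), constant non-zero
differences give p = 0. An unpaired (Welch) switch exists for
sensitivity checks but the paired test is the default and the one used
by the filter.

PCA is classical covariance PCA: column (variable) mean-centering, no
scaling to unit variance, eigen-decomposition via SVD. `factors`
(variables × components) is the orthonormal basis, `scores`
(observations × components) the centered data in that basis, so
centered data = scores·factorsᵀ exactly. Correlation-based PCA would
change the explained-variance fractions and is deliberately not offered.
Component signs are fixed so each factor column's largest-magnitude
entry is positive, making score plots reproducible. Explained-variance
fractions are computed over all min(n, p) components and sum to one;
data with no variation raise instead of returning undefined fractions.

Fold changes are ratios of condition means with no pseudo-count: a zero
denominator yields an explicit undefined signal rather than a silently
distorted value. The isoform/miRNA ratio is the ratio of condition
means, accompanied by the per-patient ratio distribution and a paired
t-test between conditions. The exon-usage comparison accepts counts
normalized upstream and reports per-exon fold and paired p, flagging
fold > 1 with p < alpha.

Both PCA entry points exist — the filtered isoform set (default) and the
full table — since trimming before or after dimension reduction is a
genuine analysis choice; the default trims first.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not read-level sequencing. Expression is log-normal (strictly positive,
right-skewed, like FPKM) and repression acts multiplicatively, i.e.
linearly in log space. For a planted triplet, with G ~ N(0,1) the
standardized log-abundance of the miRNA:

    log Z = μ_Z + s·G
    log X = μ_X − γ·G + σ·N₁
    log Y = μ_Y − γ·G + σ·N₂

All three pairwise Pearson correlations then have closed forms from
bivariate log-normal moments, corr(e^U, e^V) = (e^cov −
1)/√((e^varU − 1)(e^varV − 1)), exposed by
`expected_triplet_correlations` and verified empirically at n = 10⁵
within 0.01 in the test suite.

Defaults and why:

* **n_patients = 72** — the matched-cohort size the analysis targets.
* **γ = 0.3, σ = 0.15, s = 0.15** — chosen analytically so a planted
  triplet has population ρ_XY ≈ 0.79, ρ_XZ ≈ −0.85 and S ≈ 0.52: strong
  mediation with ~15 % multiplicative expression noise, comfortably
  detectable at n = 72 while leaving the S > 0.3 threshold doing real
  work. Confounded pairs use a latent factor with the same loading, so
  they match the planted pairs' co-expression (ρ_XY ≈ 0.79) but have
  S ≈ 0.
* **50 triplets + 50 confounded pairs + 50+50 background entities +
  10 background miRNAs** — planted pairs are ~0.4 % of the 22 500
  candidate pairs, so the 99th-percentile selection keeps all of them
  plus a tail of null pairs for the later filters to reject.
* **miRNA fold 4–8×, gene fold ~2× in cancer** — the disproportionate
  miRNA up-regulation that breaks titration; in the sponge dataset the
  repression coupling is additionally switched off in the cancer
  condition, so the miRNA-mediated network exists only in normal tissue.
* **3 planted sites per sequence**, sequences 600–1500 nt (3'UTRs,
  ≥ 500 so the length filter is exercised by configuration rather than
  by construction) and 800–2000 nt (lncRNAs); sites are planted at
  non-overlapping uniform positions; background occurrences arise by
  chance at ~1/4096 per window, giving the enrichment test a realistic
  null.
* **Titration generator**: one dominant no-site isoform (~50 % share),
  one site-bearing isoform (~15 % share, 1.3× in cancer), the rest
  low-abundance nulls; the dominant isoform absorbs whatever fold keeps
  the gene total at gene_fold. Multiplicative noise 25 % (typical
  biological variability for an abundant transcript), mean-corrected so
  sample means match planted means. A paired reference-miRNA profile is
  up-regulated by a draw from the miRNA fold range.
* **Exon generator**: gamma-Poisson counts (NB size 10), means 100–400,
  exons past the breakpoint (default 5) doubled in cancer.

An optional "super-sponge" mode plants one lncRNA sharing one miRNA
with k mRNA targets, providing ground truth for hub statistics and
rewiring comparisons; it is off by default so the standard recovery
conditions stay at exactly 50 triplets + 50 confounded pairs.

Everything is a pure function of the parameter set including the seed
(numpy SeedSequence sub-streams for expression, sequences and miRNAs),
so identical parameters give bit-identical datasets.

### What the generator does not emulate

Real FPKM data have heavier tails, condition-dependent library effects,
correlated miRNA families, shared targets across triplets, mapping
artefacts and missing values; sequences are not uniform random and seed
matches cluster in AU-rich regions. Passing the recovery tests therefore
shows the pipeline's statistical machinery is correct and well-calibrated
under its own model assumptions — it does not certify discovery
performance on patient data, where effect sizes and confounding are less
favourable.

## Problem sizes used in tests and the acceptance script

Recovery is measured over 10 simulated cohorts at the default
conditions; titration statistics over 20 cohorts; formula/oracle checks
use n = 10⁵ Gaussian samples, 1000 random scanner instances and 100
hypergeometric instances. These sizes make the whole acceptance run
finish in seconds on one CPU while keeping Monte-Carlo error well below
the asserted margins.

## Known limitations

* Only 6-mer seed matching; no target-prediction scoring.
* The enrichment universe is a package convention (see above).
* The empirical percentile on few pairs is coarse (a warning is logged
  below 100 candidate pairs).
* Correlations on raw FPKM are sensitive to outliers; no rank-based
  option is provided because the statistic is defined on Pearson
  correlations.
* The GTF reader records strand but never reverse-complements: sequences
  supplied to scanning must already be sense-strand transcript sequences.
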