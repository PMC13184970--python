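# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical conventions.

## Abundance model

A vOTU's abundance in a sample is the trimmed mean of per-position read
depth over its representative contig, divided by the sample's total
quality-trimmed bases and multiplied by 10⁹ ("per metagenome
gigabase"). The trimmed mean removes `floor(trim_fraction · L)`
positions from each tail of the sorted depth vector; the default trim
fraction is 0.05 per tail, the common default of coverage tooling, and
is exposed as a parameter. Detection requires breadth of coverage
(fraction of positions hit by ≥1 read) of at least 0.70, an inclusive
bound; records below it have their depth zeroed rather than dropped, so
the abundance matrix keeps a stable shape across samples. Read-level
identity (≥95%) and alignment (≥75%) filters are the mapper's job and
are assumed applied upstream of the coverage summary.

vOTU construction is greedy centroid clustering: contigs sorted by
length descending (ties broken lexicographically by id) each join the
first existing representative with ANI ≥ 95% and aligned fraction of
the shorter sequence ≥ 80% (both inclusive), else found a new cluster.
The representative is therefore always the longest member. The
similarity table is treated as symmetric and deduplicated by keeping
the best evidence per pair; the result is invariant to record order.

## Compositional treatment

Viral abundance tables are zero-inflated compositions. All multivariate
analysis runs on centered log-ratios, clrᵢ = ln(xᵢ+c) − mean_j ln(xⱼ+c),
with pseudo-count c = 0.001 added on the per-gigabase abundance scale
before the log. Closure (dividing each sample by its total) before or
after adding the pseudo-count does not change the CLR on strictly
positive data and is omitted. Aitchison distance is the Euclidean
distance between sample CLR vectors.

PCoA double-centers −½D², eigendecomposes the symmetrized matrix, and
keeps only axes with positive eigenvalues; percent variance is
computed over the positive eigenvalues. On exactly-Euclidean input
(which Aitchison distance is) negative eigenvalues appear only as
numerical noise, and pairwise distances of the full coordinate set
reproduce the input to ~1e-8.

Shannon diversity uses the natural logarithm: the reported scale of
diversity at richness in the thousands (H slightly above 8 when
S > 6000, below the ln S ≈ 8.7 ceiling) is only consistent with
natural-log units.

## Permutation statistics

All permutation p-values use the add-one convention (b+1)/(m+1), so the
smallest attainable p at 999 permutations is 0.001.

**PERMANOVA** partitions the total sum of squared distances
(Σ_{i<j} d²ᵢⱼ / n) into within- and between-group parts and forms
pseudo-F with (g−1, n−g) degrees of freedom; r² = SS_between/SS_total.
The null permutes group labels. Exceedances are counted strictly
(F* > F + tol): with small balanced groups a uniform label permutation
re-draws the observed partition (identically or with groups swapped)
with probability 2/C(n, n_a) per draw, and such re-draws are copies of
the observed grouping, not more-extreme outcomes; the observed grouping
itself enters the null distribution once through the add-one terms.
envfit and Mantel keep the conventional ≥ counting, where the collision
probability is ~1/n! and the convention is conservative.

**envfit** regresses each centered environmental variable on the first
two ordination axes (the plane on which arrows are displayed); r² is
the coefficient of determination, the arrow the unit-normalized
coefficient vector, and the null permutes the variable across samples.
Constant variables are excluded with a flag; samples with missing
values are dropped per variable with a warning. k-means cluster
selection runs on all positive-eigenvalue axes by default (preserving
the full Aitchison geometry; restriction to leading axes is an option),
with 100 restarts per k over k = 2…min(8, n−1), and returns the
smallest k attaining the maximal mean silhouette width.

**Friedman** uses vOTUs as blocks and timepoints as treatments
(df = k−1 = 13 for a 14-point series), mid-ranks within blocks, and the
standard tie correction of the χ² denominator; rows with all-tied
values carry no information and a fully tied table yields χ² = 0.
Kendall's W = χ²/(n(k−1)). Post-hoc consecutive-timepoint contrasts are
paired signed-rank tests across vOTUs with BH correction over the k−1
pairs. All-zero rows are retained (the matching of W's scale to
block counts in the tens of thousands indicates whole-inventory use).

**Rank tests** use exact enumeration for tie-free samples up to n = 25
and the tie- and continuity-corrected normal approximation above; the
two paths agree to <0.01 at n = 30. The exact test is discrete: its
true size at nominal 0.05 is the largest attainable level below 0.05
(≈0.038 at n = 7 vs 7), which the calibration tests account for.

**Mantel** correlates upper triangles (Spearman by default — rank-based,
matching the ρ notation used throughout; Pearson optional) and jointly
permutes rows/columns of the second matrix; the test is two-sided.

## Temporal dynamics

Distance decay uses Bray–Curtis on log(x+1) abundances,
d = Σ|uᵢ−vᵢ| / Σ(uᵢ+vᵢ), partitioned after Baselga with
A = Σ min(u,v), B, C the group-specific excesses:
d_balanced = min(B,C)/(A+min(B,C)), d_gradient = d − d_balanced. The
partition is applied on the same log scale as the dissimilarity it
decomposes, and the identity d_balanced + d_gradient = d_bray holds to
1e-12. Time lags are whole calendar months.

Occupancy classes use strict/closed boundaries — sporadic 0 < f < 0.25,
intermittent 0.25 ≤ f ≤ 0.75, persistent f > 0.75 — the unique
convention that reproduces the integer bins 1–3 / 4–10 / 11–14 at
T = 14. Never-detected vOTUs are excluded.

## Annotation contrasts

Lifestyle and AVG labels are propagated from contigs to vOTUs on the
population assumption: any temperate member makes the vOTU temperate,
AVG category sets are unions over members, host taxonomy follows the
representative. Temperate calls accept a recombinase hit with bit
score ≥ 50, or a lifestyle probability ≥ 0.95 on complete/high-quality
genomes; AVG retention requires annotation bit score ≥ 60, auxiliary
score ≤ 3 and no V flag. All thresholds are inclusive, following their
≥/≤ phrasing.

Per-sample category percentages default to the "assigned" denominator
(detected vOTUs carrying any annotation of the same type), so the
large unannotated pool does not dilute percentages; "all" is available
as an option. Effect size is the difference of group medians of
per-sample percentages (lagoon − open sea), in percentage points on
the 0–100 scale; zeros are kept as data points. Categories are retained
when at least one group has ≥5 vOTUs in the category and |effect| ≥ 0.1
percentage points; BH correction runs over the retained categories
only, and excluded categories are reported with their reason. Because
lifestyle and AVG annotations derive from contigs pooled across groups,
those contrasts optionally exclude group-shared vOTUs first; host
contrasts do not by default.

## Synthetic data

The generators emulate the statistical skeleton of the study design,
not its sequences. Nonzero abundances are lognormal (μ = 0, σ = 1.5)
over Bernoulli detection (p = 0.7), matching the zero-inflated shape
the pseudo-count exists for; the lognormal is a modeling convenience,
not a claim about real abundance distributions. Defaults plant the
study-scale contrasts at desk scale: a 300-vOTU lagoon pool vs a
150-vOTU sea pool, 5% of the sea pool shared, a 4.8-fold lagoon
abundance excess, 7 samples per group, a 14-point monthly series
(first-of-month dates, so month arithmetic is exact) with disturbances
at indices 0 and 8 mirroring the two deoxygenation events of a 3-year
lagoon series, and an occupancy mixture (0.42, 0.46, 0.12) within the
observed sporadic/intermittent/persistent ranges.

In the time series each vOTU receives a Gaussian temporal activity
profile; its detected timepoints are the profile's top-n points, so
communities turn over smoothly and time-lagged dissimilarity rises
monotonically in expectation — that is what makes Mantel recovery
plannable. Disturbances inject a cohort (15% of the pool) of
single-timepoint vOTUs. The planted environmental driver is the
standardized first PCoA axis plus Gaussian noise with variance
(1−r²)/r², giving an expected regression r² at the configured level
(0.5 by default); decoy variables are independent noise. With
env_signal_r2 = 0 the driver is itself pure noise.

What passing tests show is therefore that the machinery recovers
planted lognormal/Bernoulli structure of this shape — not that real
viral communities satisfy the model: real data carry taxonomic
correlation structure, sequencing-depth artefacts, and detection error
that the generators deliberately omit (no reads, contigs or sequence
content are simulated).

All draws flow from one `numpy.random.default_rng(seed)` per generator
call; regeneration with the same configuration is bit-identical, and
no global random state is touched.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the statistics at desk
scale: pools of 60–800 vOTUs, 7 samples per group, 14 timepoints,
199–999 permutations, 200-simulation null calibrations, and 50-seed
recovery ensembles — sizes at which every planted effect is
comfortably detectable and the suite completes in about a minute.
Tolerances: CLR column sums to 0 within 1e-9; Aitchison equals
Euclidean∘CLR within 1e-10; the Baselga identity holds within 1e-12;
distance matrices must be symmetric within 1e-12. Silhouette ties are
broken toward smaller k; clustering ties by contig length break
lexicographically; duplicate similarity records keep the best pair
evidence. Degenerate inputs are flagged rather than silently handled:
all-zero difference vectors give p = 1 with a flag, constant variables
are excluded from envfit and Spearman correlations, samples with no
assigned detected vOTUs yield missing percentages with a warning.

## Known limitations

- One-factor PERMANOVA only; no strata/blocked permutation designs.
- envfit fits linear gradients on two axes; surface fitting and
  higher-axis fits are out of scope.
- The greedy centroid clustering depends on input lengths being
  correct; no sequence-level verification is possible here.
- The synthetic annotation model draws categories independently per
  vOTU; real AVG co-occurrence is more structured.
- Exact rank tests are used only for tie-free small samples;
  mid-p or permutation variants are not implemented.
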