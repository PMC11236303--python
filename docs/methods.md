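# Methods

## The spatial model

Spots live on the even-parity offset hexagonal lattice used by
spaceranger-style position tables: a spot at array coordinates (r, c)
satisfies (r + c) mod 2 = 0, and its ring-1 neighbors are
{(r, c±2), (r±1, c±1)}. The synthetic grid places spots at unit pitch —
pixel x = c/2, pixel y = r·√3/2 — so all six neighbors of an interior spot
sit at distance exactly 1. This makes the two adjacency constructions
(array offsets; pixel distance below 1.3 × the median nearest-neighbor
distance) provably identical on undistorted grids, which the tests exploit
as an oracle equivalence. On real, possibly distorted coordinates the
pixel-distance mode is the fallback; the mode and its parameter are stamped
into every output manifest.

"Proximity" for the nearby classification is ring-1 adjacency by default.
Nothing in the biology fixes the radius; ring-k (k-fold closure of the
ring-1 graph) is exposed for sensitivity analyses. Tumor spots labeled
`other` (necrotic) confer no nearby status and are excluded from all group
statistics; `nearby_none` is kept as a real category rather than dropped.

## Annotation

Region labels are an input (from the generator or a user TSV) — automatic
malignancy scoring, clustering and image evidence are deliberately out of
scope. Marker positivity is raw count ≥ 1 UMI by default: spot-level UMI
data makes "detected at all" the natural contrast, and the threshold is
configurable and recorded. Manual overrides are all-or-nothing (validated
before any field changes), repair the cross-field invariants (a spot moved
out of the tumor region loses its tumor group and re-enters the
to-be-classified pool), and return an audit trail. Promoting a spot *to*
tumor requires the override to state the tumor group; guessing one would
silently fabricate data. Before `classify_nearby` runs, non-tumor spots
carry the sentinel `unclassified`; strict validation (used when exporting)
rejects it.

## Normalization and HVGs

LogNormalize: value = ln(1 + count · s / total) with s = 10,000 counts per
spot, natural log. Spots with zero total are dropped with a log entry.
HVG selection computes mean and unbiased (n−1) variance on the normalized
matrix, keeps genes with mean in [0.125, 3], and then requires variance
strictly above the 0.5 quantile of the candidate variances. The quantile is
type-7 (linear interpolation between order statistics), "exceeding" is
read as strict, and both bounds and the quantile are parameters. Whether
variance should be computed on standardized values instead is genuinely
open; plain variance of log-normalized values is used and documented.

## ssGSEA

Per spot, genes are ranked by expression descending with average ranks on
ties (UMI data is tie-heavy, mostly at zero; the ordering among ties is
fixed by gene symbol so scores are deterministic). Walking the ranked list,
the in-set ECDF increments by |rᵢ|^α / Σ_set |rⱼ|^α and the out-of-set ECDF
by 1/(N − n_set); the enrichment score is Σ (ECDF_in − ECDF_out) over all
positions. α = 0.75 and division of the whole score matrix by
(max − min) of raw scores are the dominant conventions and both are
parameters. A signature that shares no gene with the matrix, or covers
every gene, is a hard error (the statistic is undefined). Differential
enrichment between spot groups is the ratio of group medians; when either
median is non-positive the ratio is meaningless, so the row is flagged and
the median difference is reported instead — both medians are always
emitted.

## Module scores and trajectory curves

The per-cell resistance/sensitivity scores use the binned-control module
score: genes are cut into 24 bins by average expression, and the score is
the mean expression of the set minus the mean of 100 control genes sampled
(seeded, with replacement) from each set gene's bin. This is the standard
per-cell scoring family; ssGSEA is also available so users can switch.
Curves along pseudotime are sliding-window means (window = 10% of cells,
centered, symmetric so reversing pseudotime mirrors the mean curve
exactly) with 2.5/97.5 percentile bands from 200 bootstrap resamples of
each window's cells. The bootstrap streams from one seeded generator in
window order; band values are therefore reproducible but not
mirror-symmetric under pseudotime reversal (the means are).

## Diversity

D = 1.4826 × MAD of the upper-triangle pairwise Pearson correlations among
HVGs across the tumor spots of a sample; 1.4826 is the usual consistency
constant (applied exactly once) making the MAD estimate the standard
deviation under normality. Genes with zero variance across tumor spots are
dropped and counted rather than propagating undefined correlations. Both D
and 1/D are emitted (the inverse is only defined for D > 0). Correlations
are computed over all tumor spots of the sample; per-subregion diversity
would be a different, finer statistic.

## Differential expression

Per gene, a two-sided Wilcoxon rank-sum on normalized values; scipy's
`method="auto"` gives the exact distribution for small tie-free groups and
the tie-corrected normal approximation otherwise. Genes with identical
values everywhere get p = 1. Fold change is log2 of the ratio of
expm1-backtransformed normalized means with a 1e-9 pseudocount; Δpct uses
raw counts at the shared positivity threshold. FDR is Benjamini–Hochberg
across all tested genes. The choice of test and fold-change base is a
package decision — spot-level DE conventions vary — and both intermediate
means and percentages are reported so other definitions can be derived.

## ceRNA filtering

Candidate triplets are the join of lncRNA–miRNA and miRNA–mRNA edge lists
(interaction edges are an input file; no database is bundled). Filters, in
a fixed order that also names each rejection: lncRNA log2FC > 1 and
adjusted p < 0.05; miRNA log2FC < −1 and adjusted p < 0.05; mRNA in the
target list (when given) and passing the same screen when it has a DE
entry; paired expression present; Pearson r > 0; correlation p < 0.05.
The positivity requirement on r is a deliberate reading of the sponge
logic — an lncRNA that de-represses its target should co-express with it —
where significance alone would also admit strong negative correlations.
Retained triplets are ranked by r descending, ties lexicographic; an
independent validator pass re-checks every retained triplet.

## The synthetic generator

The generator is the package's study condition, not a tuning dial. A
connected tumor blob is grown by seeded breadth-first accretion on the hex
graph (fraction 0.35 of a 10 × 20 = 200-spot tissue), a necrotic blob
(0.05) is carved from the tumor interior (stray tumor fragments created by
the carve are folded into necrotic so tumor connectivity is an invariant),
and a connected marker-positive sub-blob (0.4 of tumor) is grown from the
tumor boundary so that marker-adjacent non-tumor spots exist. Counts are
negative binomial (mean 1, shape 2 — var = m + m²/θ) with a lognormal
per-gene mean factor (σ = 0.5). The marker draws 1 + NB(m − 1), m = 20, on
planted-positive spots and exactly 0 elsewhere, then Bernoulli dropout
(default 0.1) thins positives to zero; the shift guarantees a positive
spot has ≥ 1 molecule before dropout, so noiseless positivity calling
recovers the planted truth exactly and sensitivity under dropout q is
1 − q in expectation. Two planted programs (an SPP1⁺-TAM-like signature
elevated 4× in non-tumor spots adjacent to the marker blob; a T-cell
signature elevated 4× in normal tissue) give the niche contrast a
detectable but not overwhelming effect at this tissue size. Trajectory
cells get uniform pseudotime and linear set trends (slopes +2/−2 on the
log scale, Gaussian noise σ = 0.5, clipped at 0). The ceRNA fixture plants
one passing triplet and seven decoys, each failing exactly one filter;
decoy lncRNA–mRNA sample correlations are constructed exactly (Gram–
Schmidt) at their planted values, so which filter fails is deterministic
for every seed rather than merely likely.

What the generator does **not** emulate: spatial autocorrelation beyond
the region structure, segmentation noise at region borders, cell-type
mixtures within a spot, batch effects, sequencing-depth gradients, or
realistic gene–gene correlation networks. Passing tests therefore
demonstrate that the statistics recover structure of the assumed form at
realistic noise levels — not that they are robust to everything real
tissue does.

## Numerical and determinism choices

Floats in TSV outputs are written with 6 significant digits and round-trip
at that precision. All randomness flows from one seed; the CLI derives a
per-stage seed as (seed · 1000003 + crc32(stage)) mod 2³¹ so stages are
independently reproducible and two runs of one config are byte-identical.
Ties are always broken by symbol or id, never by memory order. Problem
sizes in the test suite and acceptance script (200-spot tissues, 500-cell
trajectories, 1000-gene null DE, 5000-spot diversity convergence, 40 × 40
adjacency grids) were chosen as the smallest sizes at which each planted
effect or convergence property is comfortably detectable.

## Known limitations

Dense matrices are used internally after I/O, which caps practical sizes
around 10⁴–10⁵ spots; the nearby classification considers ring adjacency
only, not geodesic distance along tissue; the module score's control
sampling differs in detail from other implementations (per-set-gene
sampling with replacement), so absolute score values are not comparable
across tools, only contrasts; and the ceRNA stage tests association, not
mechanism — a retained triplet is a filtered hypothesis.
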