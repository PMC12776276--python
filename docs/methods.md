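# Methods

## Positional scoring

Counts are Seurat-style log-normalized: `norm = log(1 + s·c/T)` with per-cell
total `T` and scale `s = 10,000` (the field convention; recorded in output
metadata). A module score for gene set *S* in cell *c* is

    score(c) = mean_{g∈S} norm[c,g] − mean_{g∈ctrl(S)} norm[c,g]

where the control pool is built by ranking all genes by mean normalized
expression (ties by column order), cutting the ranks into `n_bins = 24`
equal-frequency bins, and drawing `n_ctrl = 100` control genes from each set
gene's bin (excluding the gene itself; without replacement unless the bin is
smaller than `n_ctrl`). Draws use `numpy.random.default_rng(seed)` in set-gene
order and the pools are concatenated with multiplicity. This is deterministic
given the seed and is documented precisely so an independent oracle can mirror
it (the test suite does). DV.Score and NT.Score are the dorsal−ventral and
nasal−temporal score differences, exactly.

Scores are computed on the full dataset rather than per library: score
distributions were reported to be insensitive to that choice, and a single
pass keeps control pools well populated.

## Grid reconstruction

Equal-width bins span the observed min–max of each score (half-open intervals,
final bin closed, so max-score cells are assigned). Scores have no canonical
units, so no fixed or symmetric range is imposed. A bin is valid when it holds
at least `min_cells` cells *and* `min_counts` total raw transcripts summed
over all genes of its member cells ("gene counts per grid cell" is read as
total transcripts; a plausible alternative — detected genes — would change
only the sparsest bins). Presets: chicken (51, 3, 20), human (40, 3, 15),
mouse (51, 5, 30), all with σ = 1.0 and clip percentile 94 (midpoint of the
93–95 range used across species).

Smoothing is normalized convolution, `K∗(values·valid) / K∗(valid)`, with an
isotropic Gaussian of SD σ in grid units truncated at radius ⌈4σ⌉ (mass loss
< 1e−6 at σ = 1). Smoothing after masking (rather than masking after
smoothing) was chosen so invalid bins contribute neither signal nor zeros.
Display clipping sets values above the chosen percentile (linear-interpolation
definition) of the defined smoothed values to that percentile.

## Spatially variable genes

Moran's I uses binary queen (8-neighbor) contiguity restricted to valid bins —
the weights are not specified by the source analysis; queen contiguity is the
lattice standard, and a rook mode exists for analytic checks (the 2×2
checkerboard gives exactly −1). Significance is a one-sided permutation test,
`p = (1 + #{I_perm ≥ I_obs}) / (1 + n_perm)`, values shuffled across valid
bins with a per-gene child seed; genes pass at BH q < 0.01 (the SVG threshold,
distinct from the q < 0.05 used for differential expression).

Two deliberate choices:

- **The scan tests raw binned values, not smoothed maps.** Gaussian smoothing
  correlates neighboring bins by construction, so a permutation test on
  smoothed maps rejects every gene, patterned or not. Raw bin means of an
  unpatterned gene are (approximately) exchangeable, which is what the
  permutation null requires. Moran's I for *ranking* and cosine similarity for
  anchor redundancy use the smoothed maps.
- **Permutation resolution vs BH.** With `n_perm = 999` the smallest possible
  p is 1e−3; if only k of m genes are truly patterned, their best attainable
  q is m·10⁻³/k, which exceeds 0.01 whenever patterned genes are fewer than
  ~10% of the panel. The end-to-end pipeline therefore uses `n_perm = 4999`
  when the gene panel is small; calibration checks keep 999.

Known limitation: on pipeline-produced maps, even spatially flat genes show
mildly inflated raw rejection rates (≈3–4% at α = 0.01 in the 20,000-cell
benchmark). The cause is real, not a bug: the grid axes are module scores
computed from the same counts, and log-normalized expression couples to
per-cell sequencing depth, so depth gradients in score space induce weak
spatial structure in every gene. The test itself is exactly calibrated on
exchangeable nulls (verified on iid lattice fields); BH at q < 0.01 absorbs
the inflation in practice. A green SVG-calibration test therefore establishes
calibration of the statistic, not the absence of normalization artifacts in
real data.

## Anchors

Greedy selection scans significant genes by decreasing Moran's I (ties by
input order); a gene becomes an anchor iff its cosine similarity to every
current anchor is below τ = 0.9, stopping at 20 anchors. Every significant
gene is assigned to its most-similar anchor. An anchor "forms a cluster" when
at least 2 other genes are assigned to it at similarity ≥ τ; cluster-forming
anchors that are each other's most-similar anchor merge (transitively). The
source describes this algorithm only in outline; priority-by-I with a cosine
redundancy filter is the reading that satisfies both the "maximizes spatial
autocorrelation" and "maximize divergence of patterns" descriptions, and both
thresholds are parameters so alternatives can be swapped in.

Note that cosine similarity on non-negative expression maps is inflated by the
shared baseline; τ = 0.9 accounts for this. Pearson similarity (with the
r > 0.9, p < 0.001 convention) is available independently.

## Region differential expression

Regions are bins whose smoothed marker value reaches a quantile (default
0.95) over valid bins; explicit bin lists are accepted for manually drawn
regions. Pseudobulks sum raw counts per (embryo, in/out); rows with ≤100
cells are excluded. Each gene is fit with an NB2 GLM (log link, design
intercept + group, offset log total counts): IRLS for the coefficients
alternating with a bounded 1-D ML step for the dispersion, using a
method-of-moments initializer, a floor of 1e−8, and the Cox–Reid ½·logdet
adjustment. The Wald statistic for the group coefficient is referred to a t
distribution with n−p degrees of freedom. Without the Cox–Reid and t
corrections the raw type-I error on a 2000-gene 6+6 null was 10.4% at the 5%
level; with them 4.6%. No dispersion shrinkage across genes is applied (a
deliberate simplification relative to shrinkage-based reference tools; with
very few pseudobulks per group, per-gene dispersions are noisier and power is
somewhat lower). Significance: |log2FC| > 1 and BH q < 0.05.

## FISH quantification

Blocks tile from the image's top-left; edge blocks are partial, and block
means are taken over foreground (mask) pixels only — zero-filling background
would bias edge blocks downward. Zero-foreground blocks are missing. Min–max
normalization to [0,1] is global; axis normalization rescales each column (or
row) independently, skipping (and flagging) lines with fewer than two distinct
defined values. Strips collect blocks whose centers lie within ±width/2
(default 500 μm → 1539 px) of the origin line; per-position mean and SD are
taken over the strip's defined blocks, positions with less than 80% defined
coverage are dropped as background-dominated, and positions are reported in μm
relative to the origin. Strip statistics operate on blocks, not raw pixels
(consistent with profiling the binned matrices). FIJI-style pre-filters
(bright-outlier removal, Gaussian blur, mean-background subtraction) are
provided but off by default: quantification is defined on raw images.

Replicate profiles are linearly interpolated onto a common axis (default step
= one block = 25 px × 0.3248 μm/px = 8.12 μm — no resolution is invented
beyond the data's) with no extrapolation; aggregation reports per-position
mean, SEM or SD, and sample count (SEM missing where n = 1).

## Profile clustering

Gene×position matrices are correlated pairwise over jointly observed
positions (entries with <3 joint positions, or zero variance, are missing;
missing entries are imputed as correlation 0 with a warning before
clustering). Average-linkage clustering runs on distance 1 − r. Leaf ordering
uses an exact dynamic program over all 2^(n−1) subtree flips (minimizing the
sum of adjacent-leaf distances): the installed scipy's optimal leaf ordering
was found to return non-optimal orders on ~30% of random instances, so the
exact algorithm is implemented in-package and verified against exhaustive
search.

Cross-modal comparison rescales each profile to [0,1] in value and position
and interpolates the denser profile onto the sparser axis before computing
Pearson r. This is meaningful for patterns with a well-defined origin (spots);
a stripe's intensity peak is an arbitrary point on its ridge, so cross-modal r
for stripes through a peak-derived origin is not informative.

## Synthetic benchmark (what it does and does not establish)

Cells receive latent positions uniform on the unit disk (u = NT, v = DV; the
optic fissure landmark is not modeled — the pipeline consumes only
axis-monotone structure). Gene g in cell c has NB mean
`baseline_g·(1 + A·P_g(u,v))·s_c` with archetype P ∈ [0,1] (axis gradients,
central spot, equatorial/oblique stripe, flat), variance μ + φμ², φ = 0.3,
and lognormal size factors (0, 0.35). Defaults: 20,000 cells, 30 embryos
(the scale of the real chicken resource), baseline 0.5 UMI, amplitude A = 20 —
markers rise from ~0.5 to ~10 expected UMI across their axis, the dynamic
range of spatially restricted developmental genes, which are near-off outside
their domain. Flat "decoy" genes get lognormal (σ = 1) baseline spread so the
control-gene pools span the markers' expression range. The benchmark ships
the chicken marker sets patterned on their axes, two held-out test genes
(FGF8SIM: nasal-central spot at (0.40, 0); CYP1B1SIM: oblique stripe at 30°),
500 decoys, and matched synthetic FISH renders of the held-out archetypes.

The generator does **not** emulate: realistic transcriptome-wide library
composition (518 genes vs ~15,000 expressed — normalization couplings are
proportionally stronger here), batch or technology structure, cell-type
mixture, ambient RNA, or tissue-shape asymmetries. Green tests establish that
the pipeline recovers known spatial structure from counts with realistic
noise — not that marker sets of this size suffice in any particular real
tissue.
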