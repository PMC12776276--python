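# retinotopo

Spatial reconstruction of gene expression in the developing retina from
dissociated single-cell RNA-seq, with matched quantification of multiplexed
RNA-FISH flat-mount images.

Dissociation destroys spatial information, but the embryonic retina is
patterned by well-characterized marker genes along its two anatomical axes:
dorso-ventral (DV) and naso-temporal (NT). `retinotopo` exploits this to put
cells back on the tissue plane:

1. **Positional scoring.** Each cell receives four module scores — mean
   log-normalized expression of a dorsal, ventral, nasal, or temporal marker
   set minus that of expression-matched control genes. The composites

       DV.Score = Dorsal − Ventral        NT.Score = Nasal − Temporal

   serve as continuous positional coordinates. The shipped chicken sets are
   {Tbx5, Tbx2, Tbx3, Aldh1a1, EfnB2, EfnB1} (dorsal), {Vax1, Chrdl1, Aldh1a3}
   (ventral), {FoxG1, SOHo-1, Hmx1, EfnA5, EfnA2} (nasal) and {FoxD1, EphA3}
   (temporal).
2. **Topographic maps.** Cells are binned on a G×G grid over
   (NT.Score, DV.Score) — species presets: chicken 51×51 (≥3 cells, ≥20
   transcripts per bin), human 40×40 (≥3, ≥15), mouse 51×51 (≥5, ≥30) — and
   each gene's per-bin mean expression is smoothed with a mask-aware Gaussian
   (σ = 1 bin) and display-clipped at a high percentile (default 94th).
3. **Spatially variable genes and anchors.** Spatial structure is scored with
   Moran's I on the bin lattice (queen contiguity), tested by seeded
   permutation and filtered at Benjamini–Hochberg q < 0.01. A greedy pass in
   decreasing Moran's I picks up to 20 mutually non-redundant "anchor"
   patterns (cosine similarity < 0.9 to all earlier anchors); every
   significant gene is assigned to its most-similar anchor, and
   mutual-nearest-neighbor anchors merge into pattern groups.
4. **Region differential expression.** Grid regions (e.g. the high-acuity
   area, marked by a nasal-central Fgf8-like spot) are defined by quantile
   thresholding a marker's map; raw counts are summed per (embryo, in/out)
   pseudobulk (rows with ≤100 cells excluded) and tested per gene with a
   negative-binomial GLM (log link, log-total offset, Cox–Reid adjusted ML
   dispersion, Wald t test); significance at |log2FC| > 1 and q < 0.05.
5. **RNA-FISH quantification.** Masked grayscale flat-mount images
   (1 px = 0.3248 μm) are reduced to 25×25-px block means, min–max normalized,
   optionally row/column normalized, and profiled along DV/NT in a 500 μm
   strip through a user-set origin (positions with <80% signal coverage are
   dropped). Aligned profiles from replicates are interpolated onto a common
   axis and averaged; profile panels are clustered with average linkage on
   1 − Pearson r with exact optimal leaf ordering, enabling direct
   FISH ↔ scRNA comparison.

A fully seeded synthetic-data module generates benchmark retinas (latent
positions on the unit disk, negative-binomial counts, lognormal library
sizes) and matching synthetic FISH renders, so the whole pipeline is testable
offline with known ground truth.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import retinotopo as rt

bundle = rt.make_benchmark_suite(seed=0, n_cells=5000, n_decoys=100)
scores = rt.compute_axis_scores(bundle.dataset, bundle.gene_sets, seed=0)
print("Spearman(DV.Score, true v) =",
      round(spearmanr(scores.dv, bundle.truth["v"]).statistic, 3))

grid = rt.build_grid(scores, bundle.dataset, rt.get_preset("chicken"))
print("grid:", grid.G, "x", grid.G, "| valid bins:", int(grid.valid.sum()))

gm = rt.reconstruct_gene(grid, bundle.dataset, "FGF8SIM")  # held-out spot gene
truth = rt.archetype_map_on_grid(grid, bundle.truth, bundle.patterns["FGF8SIM"])
m = np.isfinite(gm.smoothed) & np.isfinite(truth) & grid.valid
cos = float(gm.smoothed[m] @ truth[m]
            / np.linalg.norm(gm.smoothed[m]) / np.linalg.norm(truth[m]))
print("held-out spot: cosine to noiseless truth =", round(cos, 3))

w = rt.build_weights(grid)
stat = rt.morans_test(rt.topo_grid.gene_map(grid, bundle.dataset, "FGF8SIM"),
                      w, n_perm=999, seed=0)
print(f"Moran's I = {stat.I:.3f}, permutation p = {stat.p_value:.3f}")
```

Output:

```
Spearman(DV.Score, true v) = 0.814
grid: 51 x 51 | valid bins: 578
held-out spot: cosine to noiseless truth = 0.825
Moran's I = 0.453, permutation p = 0.001
```

Reading: the marker-based DV coordinate ranks cells by their true latent
dorso-ventral position (ρ = 0.81); `FGF8SIM` — a test gene *excluded* from the
scoring sets — is reconstructed as a nasal-central spot closely matching the
noiseless generative pattern (cosine 0.83); its map is strongly spatially
autocorrelated (Moran's I = 0.45) at the smallest p attainable with 999
permutations.

## Command line

```bash
retinotopo simulate --seed 0 --out synth_data        # benchmark dataset + truth
retinotopo score --data-dir synth_data --out scores.tsv
retinotopo run --config run.yaml                     # full pipeline
retinotopo presets                                   # species grid parameters
```

`run.yaml` holds paths, the species preset, seeds and thresholds (defaults are
the published parameters); unknown keys are rejected and every run writes a
`run_log.json` with a version/config stamp.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the benchmark from scratch at the given seed and runs the complete
pipeline — scoring, grid construction, held-out spot/stripe reconstruction,
the Moran's I scan with anchor selection, FISH block quantification with
cross-modal profile comparison, and the pseudobulk NB-GLM with a spiked
region-enriched gene — printing each stage's summary statistics and writing
the JSON result file.

See `docs/methods.md` for the statistical model, parameter choices, and known
limitations.
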