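"""2D topographic reconstruction: score-space binning, smoothing, clipping.

Cells are discretized on a regular G×G grid over (NT.Score, DV.Score); each
grid cell holds the mean normalized expression of the cells falling in it.
Bins with too few cells or too few total transcripts are masked invalid.
Maps are denoised by mask-aware (normalized-convolution) Gaussian smoothing
and display-clipped at a high percentile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .axis_scoring import AxisScores
from .io_core import CellDataset, SpeciesPreset

__all__ = ["TopoGrid", "GeneMap", "build_grid", "gene_map", "smooth_map",
           "clip_map", "grid_sensitivity", "reconstruct_gene"]


@dataclass
class TopoGrid:
    """Discretization of cells onto a G×G grid in score space.

    Row index i follows DV.Score (y), column index j follows NT.Score (x).
    """

    G: int
    x_edges: np.ndarray  # G+1, NT.Score
    y_edges: np.ndarray  # G+1, DV.Score
    cell_assignment: np.ndarray  # (n_cells, 2) int: (i, j)
    n_cells: np.ndarray  # G×G int
    total_counts: np.ndarray  # G×G int (raw transcripts of member cells)
    valid: np.ndarray  # G×G bool
    preset: SpeciesPreset

    @property
    def n_bins(self) -> int:
        return self.G * self.G


@dataclass
class GeneMap:
    """Per-gene G×G expression map (mean per valid bin; NaN elsewhere)."""

    gene: str
    values: np.ndarray  # raw binned means, NaN off the valid mask
    smoothed: np.ndarray | None = None
    sigma: float | None = None
    clip_percentile: float | None = None
    clipped_max: float | None = None
    meta: dict = field(default_factory=dict)

    def best(self) -> np.ndarray:
        """Most-processed layer available (smoothed if present, else raw)."""
        return self.values if self.smoothed is None else self.smoothed


def _bin_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins [e_i, e_{i+1}); the final bin is closed."""
    idx = np.searchsorted(edges, x, side="right") - 1
    # cells exactly at the top edge belong to the last bin
    idx[x == edges[-1]] = len(edges) - 2
    return np.clip(idx, 0, len(edges) - 2)


def build_grid(
    scores: AxisScores, ds: CellDataset, preset: SpeciesPreset
) -> TopoGrid:
    """Assign every cell to a grid bin and compute the validity mask."""
    if len(scores.table) != ds.n_cells:
        raise ValueError("scores and dataset disagree on the number of cells")
    G = preset.grid_size
    nt, dv = scores.nt, scores.dv
    for name, v in (("NT.Score", nt), ("DV.Score", dv)):
        if v.max() == v.min():
            raise ValueError(f"degenerate axis: {name} has zero range")
    x_edges = np.linspace(nt.min(), nt.max(), G + 1)
    y_edges = np.linspace(dv.min(), dv.max(), G + 1)
    j = _bin_index(nt, x_edges)
    i = _bin_index(dv, y_edges)
    flat = i * G + j
    n_cells = np.bincount(flat, minlength=G * G).reshape(G, G)
    cell_totals = np.asarray(ds.counts.sum(axis=1)).ravel()
    total_counts = np.bincount(flat, weights=cell_totals, minlength=G * G)
    total_counts = total_counts.reshape(G, G).astype(np.int64)
    valid = (n_cells >= preset.min_cells) & (total_counts >= preset.min_counts)
    return TopoGrid(
        G=G,
        x_edges=x_edges,
        y_edges=y_edges,
        cell_assignment=np.column_stack([i, j]),
        n_cells=n_cells,
        total_counts=total_counts,
        valid=valid,
        preset=preset,
    )


def gene_map(grid: TopoGrid, ds: CellDataset, gene: str) -> GeneMap:
    """Mean normalized expression of ``gene`` per valid bin."""
    g = ds.gene_idx(gene)
    norm = ds.norm_matrix()
    expr = np.asarray(norm[:, g].todense()).ravel()
    G = grid.G
    flat = grid.cell_assignment[:, 0] * G + grid.cell_assignment[:, 1]
    sums = np.bincount(flat, weights=expr, minlength=G * G).reshape(G, G)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / grid.n_cells
    values = np.where(grid.valid, means, np.nan)
    return GeneMap(gene=gene, values=values)


def smooth_map(gmap: GeneMap, grid: TopoGrid, sigma: float | None = None) -> GeneMap:
    """Mask-aware Gaussian smoothing by normalized convolution.

    smoothed = K∗(values·valid) / K∗(valid), isotropic kernel of SD ``sigma``
    grid units truncated at radius ⌈4σ⌉; bins where the denominator is zero
    stay missing.
    """
    if sigma is None:
        sigma = grid.preset.sigma
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = math.ceil(4 * sigma)
    defined = np.isfinite(gmap.values)
    num = gaussian_filter(
        np.where(defined, gmap.values, 0.0), sigma, mode="constant", radius=radius
    )
    den = gaussian_filter(
        defined.astype(float), sigma, mode="constant", radius=radius
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(den > 1e-12, num / den, np.nan)
    return replace(gmap, smoothed=smoothed, sigma=float(sigma))


def clip_map(gmap: GeneMap, percentile: float | None = None,
             grid: TopoGrid | None = None) -> GeneMap:
    """Clip the smoothed map at a high percentile to tame outlier bins.

    ``clipped_max`` is the linear-interpolation percentile of the defined
    smoothed values; values above it are set to it.
    """
    if percentile is None:
        if grid is None:
            raise ValueError("pass a percentile or a grid with a preset")
        percentile = grid.preset.clip_percentile
    if not (0 < percentile <= 100):
        raise ValueError("percentile must be in (0, 100]")
    layer = gmap.best()
    defined = np.isfinite(layer)
    if not defined.any():
        raise ValueError("map has no defined bins to clip")
    cmax = float(np.percentile(layer[defined], percentile))
    clipped = np.where(defined & (layer > cmax), cmax, layer)
    out = replace(gmap, clip_percentile=float(percentile), clipped_max=cmax)
    if gmap.smoothed is None:
        out.values = clipped
    else:
        out.smoothed = clipped
    return out


def reconstruct_gene(
    grid: TopoGrid,
    ds: CellDataset,
    gene: str,
    *,
    sigma: float | None = None,
    clip_percentile: float | None = None,
) -> GeneMap:
    """Binned map → smoothing → percentile clipping, with preset defaults."""
    gm = gene_map(grid, ds, gene)
    gm = smooth_map(gm, grid, sigma)
    pct = clip_percentile if clip_percentile is not None else grid.preset.clip_percentile
    return clip_map(gm, pct)


def grid_sensitivity(
    scores: AxisScores,
    ds: CellDataset,
    gene: str,
    sizes: list[int],
    preset: SpeciesPreset,
) -> list[GeneMap]:
    """Reconstruct one gene at several grid resolutions (shared score range)."""
    maps = []
    for G in sizes:
        if G < 2:
            raise ValueError("grid sizes must be ≥ 2")
        p = SpeciesPreset(
            name=f"{preset.name}-G{G}",
            grid_size=G,
            min_cells=preset.min_cells,
            min_counts=preset.min_counts,
            sigma=preset.sigma,
            clip_percentile=preset.clip_percentile,
        )
        grid = build_grid(scores, ds, p)
        gm = reconstruct_gene(grid, ds, gene)
        gm.meta["grid_size"] = G
        maps.append(gm)
    return maps


def write_gene_map(gmap: GeneMap, grid: TopoGrid, out_prefix: str | Path) -> None:
    """Export a map as a delimited G×G matrix plus a JSON sidecar."""
    prefix = Path(out_prefix)
    np.savetxt(f"{prefix}.tsv", gmap.best(), delimiter="\t")
    sidecar = {
        "gene": gmap.gene,
        "grid_size": grid.G,
        "x_edges": grid.x_edges.tolist(),
        "y_edges": grid.y_edges.tolist(),
        "sigma": gmap.sigma,
        "clip_percentile": gmap.clip_percentile,
        "clipped_max": gmap.clipped_max,
        "preset": grid.preset.name,
    }
    Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))
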