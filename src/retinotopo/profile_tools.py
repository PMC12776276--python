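"""1D axis profiles, common-axis interpolation, and correlation clustering.

A :class:`Profile1D` is a gene's mean expression (or FISH intensity) along one
anatomical axis, with per-position dispersion and coverage.  Profiles from
different samples or modalities are linearly interpolated onto a common axis
(never extrapolated), correlated pairwise over jointly observed positions, and
clustered with average linkage on distance = 1 − correlation, with exact
optimal leaf ordering of the dendrogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .axis_scoring import AxisScores
from .io_core import CellDataset

__all__ = [
    "Profile1D",
    "ProfileMatrix",
    "axis_profile_from_cells",
    "profile_from_gene_map",
    "interpolate_to_common_axis",
    "profile_correlation_matrix",
    "cluster_profiles",
    "cross_modal_compare",
]


@dataclass
class Profile1D:
    """Mean ± spread along one axis with per-position coverage."""

    positions: np.ndarray  # strictly increasing (μm or score units)
    mean: np.ndarray
    spread: np.ndarray  # SD or SEM, see spread_type
    coverage: np.ndarray  # contributing cells/pixels/samples per position
    spread_type: str = "sd"
    origin_index: int | None = None
    low_confidence: np.ndarray | None = None
    label: str = ""
    axis: str = ""

    def __post_init__(self) -> None:
        n = len(self.positions)
        if not (len(self.mean) == len(self.spread) == len(self.coverage) == n):
            raise ValueError("profile fields must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.coverage < 0):
            raise ValueError("coverage must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": self.positions,
                "mean": self.mean,
                self.spread_type: self.spread,
                "coverage": self.coverage,
            }
        )
        if self.low_confidence is not None:
            df["low_confidence"] = self.low_confidence
        return df


@dataclass
class ProfileMatrix:
    """Gene×position matrix on one interpolated axis (NaN = unobserved)."""

    genes: list[str]
    positions: np.ndarray
    values: np.ndarray  # (n_genes, n_positions)
    meta: dict = field(default_factory=dict)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.genes.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.positions)


def axis_profile_from_cells(
    scores: AxisScores,
    ds: CellDataset,
    gene: str,
    axis: str,
    n_bins: int = 50,
    min_cells: int = 50,
) -> Profile1D:
    """Binned mean expression of a gene along DV.Score or NT.Score.

    Bins with coverage ≤ ``min_cells`` are flagged low-confidence (plotted
    dashed in the conventional display), not dropped.
    """
    if axis not in ("DV", "NT"):
        raise ValueError("axis must be 'DV' or 'NT'")
    if n_bins < 2:
        raise ValueError("n_bins must be ≥ 2")
    coord = scores.dv if axis == "DV" else scores.nt
    g = ds.gene_idx(gene)
    expr = np.asarray(ds.norm_matrix()[:, g].todense()).ravel()
    edges = np.linspace(coord.min(), coord.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, coord, side="right") - 1, 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    s1 = np.bincount(idx, weights=expr, minlength=n_bins)
    s2 = np.bincount(idx, weights=expr**2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, s1 / np.maximum(count, 1), np.nan)
        var = np.where(count > 1, (s2 - s1**2 / np.maximum(count, 1)) / np.maximum(count - 1, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile1D(
        positions=centers,
        mean=mean,
        spread=np.sqrt(np.maximum(var, 0)),
        coverage=count,
        spread_type="sd",
        low_confidence=count <= min_cells,
        label=gene,
        axis=axis,
    )


def profile_from_gene_map(gmap, grid, axis: str) -> Profile1D:
    """Collapse a 2D gene map to a 1D profile by averaging across the other axis."""
    layer = gmap.best()
    if axis == "DV":
        vals, centers = layer, 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
        mean = np.nanmean(np.where(np.isfinite(layer), layer, np.nan), axis=1)
        cov = np.isfinite(layer).sum(axis=1)
        sd = np.nanstd(np.where(np.isfinite(layer), layer, np.nan), axis=1)
    elif axis == "NT":
        centers = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        mean = np.nanmean(np.where(np.isfinite(layer), layer, np.nan), axis=0)
        cov = np.isfinite(layer).sum(axis=0)
        sd = np.nanstd(np.where(np.isfinite(layer), layer, np.nan), axis=0)
    else:
        raise ValueError("axis must be 'DV' or 'NT'")
    return Profile1D(
        positions=centers, mean=mean, spread=sd, coverage=cov,
        spread_type="sd", label=gmap.gene, axis=axis,
    )


def interpolate_to_common_axis(
    profiles: list[Profile1D], step: float
) -> ProfileMatrix:
    """Linear interpolation of ≥2 profiles onto one shared axis.

    The common axis spans the union of the profiles' ranges at the given step;
    positions outside a profile's observed range stay missing (no
    extrapolation).
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if step <= 0:
        raise ValueError("step must be positive")
    lo = min(p.positions[0] for p in profiles)
    hi = max(p.positions[-1] for p in profiles)
    axis = np.arange(lo, hi + step / 2, step)
    values = np.full((len(profiles), axis.size), np.nan)
    for k, p in enumerate(profiles):
        ok = np.isfinite(p.mean)
        if ok.sum() < 2:
            raise ValueError(f"profile {p.label!r} has fewer than 2 observed positions")
        xs, ys = p.positions[ok], p.mean[ok]
        inside = (axis >= xs[0]) & (axis <= xs[-1])
        values[k, inside] = np.interp(axis[inside], xs, ys)
    return ProfileMatrix(
        genes=[p.label or f"profile_{k}" for k, p in enumerate(profiles)],
        positions=axis,
        values=values,
        meta={"step": step},
    )


def masked_pearson(a: np.ndarray, b: np.ndarray, min_joint: int = 3) -> float:
    """Pearson r over jointly finite positions; NaN when undefined."""
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < min_joint:
        return np.nan
    x, y = a[mask], b[mask]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("zero variance over the joint support", stacklevel=2)
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def profile_correlation_matrix(pm: ProfileMatrix) -> pd.DataFrame:
    """Pairwise masked Pearson correlation of all profile rows."""
    n = len(pm.genes)
    if n < 2:
        raise ValueError("need ≥2 profiles to correlate")
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            corr[i, j] = corr[j, i] = masked_pearson(pm.values[i], pm.values[j])
    return pd.DataFrame(corr, index=pm.genes, columns=pm.genes)


def optimal_leaf_order(Z: np.ndarray, dist: np.ndarray) -> list[int]:
    """Exact optimal leaf ordering of a dendrogram (Bar-Joseph dynamic program).

    Finds, among all 2^(n−1) subtree flips of the linkage ``Z``, the leaf
    sequence minimizing the sum of distances between adjacent leaves.
    M(v, i, j) — the best cost of arranging v's subtree with outer leaves i
    and j — is built bottom-up; the crossing edge between the two child blocks
    is minimized over their inner endpoints.
    """
    n = dist.shape[0]
    leaves: dict[int, np.ndarray] = {k: np.array([k]) for k in range(n)}
    M: dict[int, np.ndarray] = {k: np.zeros((1, 1)) for k in range(n)}
    split: dict[int, int] = {}
    argk: dict[int, np.ndarray] = {}
    argm: dict[int, np.ndarray] = {}
    for row in range(n - 1):
        node = n + row
        a, b = int(Z[row, 0]), int(Z[row, 1])
        La, Lb = leaves[a], leaves[b]
        Ma, Mb = M[a], M[b]
        D = dist[np.ix_(La, Lb)]
        na, nb = len(La), len(Lb)
        # T[i, m] = min_k Ma[i, k] + D[k, m]  (k = inner leaf on the a side)
        T = np.empty((na, nb))
        ak = np.empty((na, nb), dtype=np.intp)
        for i in range(na):
            cand = Ma[i][:, None] + D
            ak[i] = np.argmin(cand, axis=0)
            T[i] = cand[ak[i], np.arange(nb)]
        # M1[i, j] = min_m T[i, m] + Mb[m, j]  (m = inner leaf on the b side)
        M1 = np.empty((na, nb))
        am = np.empty((na, nb), dtype=np.intp)
        for j in range(nb):
            cand = T + Mb[:, j][None, :]
            am[:, j] = np.argmin(cand, axis=1)
            M1[:, j] = cand[np.arange(na), am[:, j]]
        full = np.full((na + nb, na + nb), np.inf)
        full[:na, na:] = M1
        full[na:, :na] = M1.T  # a reversed ordering has identical cost
        leaves[node] = np.concatenate([La, Lb])
        M[node] = full
        split[node] = na
        argk[node] = ak
        argm[node] = am

    def reconstruct(node: int, i: int, j: int) -> list[int]:
        if node < n:
            return [node]
        na = split[node]
        if i >= na:  # outer-left endpoint on the b side → mirror
            return reconstruct(node, j, i)[::-1]
        jb = j - na
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        m = int(argm[node][i, jb])
        k = int(argk[node][i, m])
        left = reconstruct(a, i, k)  # global leaf ids
        right = reconstruct(b, m, jb)
        return left + right

    root = 2 * n - 2
    flat = int(np.argmin(M[root]))
    i, j = np.unravel_index(flat, M[root].shape)
    return [int(g) for g in reconstruct(root, int(i), int(j))]


def cluster_profiles(corr: pd.DataFrame):
    """Average-linkage clustering on 1−r with exact optimal leaf ordering.

    Missing correlations are imputed as 0 (with a warning).  Returns
    ``(linkage_matrix, leaf_order)`` where leaf_order lists gene labels in the
    optimally ordered dendrogram sequence.
    """
    if len(corr) < 2:
        raise ValueError("need ≥2 leaves to cluster")
    c = corr.to_numpy(dtype=float).copy()
    if np.isnan(c).any():
        warnings.warn("missing correlations imputed as 0 before clustering", stacklevel=2)
        c = np.where(np.isnan(c), 0.0, c)
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # guard against float asymmetry
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    order = optimal_leaf_order(Z, dist)
    return Z, [corr.index[i] for i in order]


def dendrogram_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Newick string for a scipy linkage matrix."""
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

    return rec(tree) + ";"


def _rescale01(v: np.ndarray) -> np.ndarray:
    ok = np.isfinite(v)
    lo, hi = v[ok].min(), v[ok].max()
    if hi == lo:
        return np.full_like(v, np.nan)
    return (v - lo) / (hi - lo)


def cross_modal_compare(
    fish: ProfileMatrix,
    scrna: ProfileMatrix,
    gene_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson r between FISH and scRNA profiles of the same gene.

    Each profile is rescaled to [0,1] in value and its positions normalized to
    [0,1]; the longer profile is interpolated onto the shorter one's axis.
    """
    if gene_pairs is None:
        common = [g for g in fish.genes if g in scrna.genes]
        gene_pairs = [(g, g) for g in common]
    if not gene_pairs:
        raise ValueError("no shared genes between the two modalities")
    rows = []
    for gf, gs in gene_pairs:
        a, b = fish.row(gf), scrna.row(gs)
        pa = _rescale01(a)
        pb = _rescale01(b)
        if np.all(np.isnan(pa)) or np.all(np.isnan(pb)):
            warnings.warn(f"constant profile for {gf}/{gs}; correlation undefined", stacklevel=2)
            rows.append((gf, gs, np.nan))
            continue
        xa = _norm_positions(fish.positions)
        xb = _norm_positions(scrna.positions)
        # interpolate the longer onto the shorter axis
        if xa.size <= xb.size:
            ok = np.isfinite(pb)
            b_on_a = np.interp(xa, xb[ok], pb[ok], left=np.nan, right=np.nan)
            r = masked_pearson(pa, b_on_a)
        else:
            ok = np.isfinite(pa)
            a_on_b = np.interp(xb, xa[ok], pa[ok], left=np.nan, right=np.nan)
            r = masked_pearson(a_on_b, pb)
        rows.append((gf, gs, r))
    return pd.DataFrame(rows, columns=["fish_gene", "scrna_gene", "pearson_r"])


def _norm_positions(x: np.ndarray) -> np.ndarray:
    return (x - x[0]) / (x[-1] - x[0])
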