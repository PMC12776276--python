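"""Spatially variable gene detection and anchor-based pattern clustering.

Spatial autocorrelation of a gene map is measured with Moran's I on the
lattice of valid grid bins (binary queen contiguity by default):

    I = (n / W) · Σ_ij w_ij z_i z_j / Σ_i z_i²,   z = x − mean(x)

Significance is assessed by a one-sided permutation test (values shuffled
across valid bins), and p-values are Benjamini–Hochberg adjusted.  Anchor
genes — a small set of maximally autocorrelated, mutually non-redundant
patterns — are selected greedily in decreasing order of Moran's I, admitting a
gene only while its cosine similarity to every current anchor stays below a
redundancy threshold.  Each significant gene is then assigned to its
most-similar anchor, and anchors that are mutual nearest neighbors are merged
into pattern groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .topo_grid import GeneMap, TopoGrid

__all__ = [
    "SpatialWeights",
    "SpatialStat",
    "AnchorSet",
    "build_weights",
    "morans_I",
    "morans_test",
    "moran_scan",
    "bh_adjust",
    "cosine_similarity",
    "pearson_spatial",
    "select_anchors",
    "group_anchors",
]


@dataclass
class SpatialWeights:
    """Binary contiguity weights over the valid bins of a grid."""

    valid_flat: np.ndarray  # flattened grid indices of valid bins, sorted
    w: sp.csr_matrix  # n×n symmetric binary adjacency, zero diagonal
    neighborhood: str

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def W(self) -> float:
        return float(self.w.sum())


def build_weights(grid_or_valid, neighborhood: str = "queen") -> SpatialWeights:
    """Adjacency over valid bins: queen (8-neighbor) or rook (4-neighbor)."""
    valid = grid_or_valid.valid if isinstance(grid_or_valid, TopoGrid) else np.asarray(grid_or_valid)
    if valid.ndim != 2:
        raise ValueError("validity mask must be 2D")
    if neighborhood == "queen":
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    elif neighborhood == "rook":
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    nr, nc = valid.shape
    flat_idx = np.flatnonzero(valid)
    pos = {f: k for k, f in enumerate(flat_idx)}
    rows, cols = [], []
    ii, jj = np.divmod(flat_idx, nc)
    for di, dj in offsets:
        ni, nj = ii + di, jj + dj
        ok = (ni >= 0) & (ni < nr) & (nj >= 0) & (nj < nc)
        nb_flat = ni[ok] * nc + nj[ok]
        src = flat_idx[ok]
        keep = [k for k, f in enumerate(nb_flat) if f in pos]
        for k in keep:
            rows.append(pos[src[k]])
            cols.append(pos[nb_flat[k]])
    w = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(flat_idx), len(flat_idx))
    )
    return SpatialWeights(valid_flat=flat_idx, w=w, neighborhood=neighborhood)


def _map_vector(gmap: GeneMap, weights: SpatialWeights) -> np.ndarray:
    """Smoothed values of a map on the weights' valid bins."""
    x = gmap.best().ravel()[weights.valid_flat]
    if np.isnan(x).any():
        # smoothing defines values wherever the denominator > 0, which covers
        # every valid bin; NaN here means the map came from a different grid
        raise ValueError("map is undefined on some valid bins of the weights")
    return x


def morans_I(gmap: GeneMap, weights: SpatialWeights) -> float:
    """Moran's I of the (smoothed) map over the valid bins."""
    x = _map_vector(gmap, weights)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 valid bins")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError(f"zero variance: map {gmap.gene!r} is constant on valid bins")
    return float(n / weights.W * (z @ (weights.w @ z)) / denom)


@dataclass
class SpatialStat:
    """Moran's I result for one gene with permutation p and BH q."""

    gene: str
    I: float
    n: int
    p_value: float
    q_value: float = np.nan
    significant: bool = False
    alpha: float = 0.01


def morans_test(
    gmap: GeneMap,
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
) -> SpatialStat:
    """One-sided permutation test for positive spatial autocorrelation.

    p = (1 + #{I_perm ≥ I_obs}) / (1 + n_perm), values permuted across the
    valid bins with the given seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be ≥ 99")
    x = _map_vector(gmap, weights)
    obs = morans_I(gmap, weights)
    rng = np.random.default_rng(seed)
    n = x.size
    z = x - x.mean()
    denom = float(z @ z)
    # permuting z permutes x: mean and denominator are permutation-invariant
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    P = z[perm_idx]  # (n_perm, n)
    quad = np.einsum("ij,ij->i", P, P @ weights.w.T)
    I_perm = n / weights.W * quad / denom
    p = (1 + int(np.sum(I_perm >= obs))) / (1 + n_perm)
    return SpatialStat(gene=gmap.gene, I=obs, n=n, p_value=p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moran_scan(
    maps: list[GeneMap],
    weights: SpatialWeights,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.01,
    layer: str = "raw",
) -> list[SpatialStat]:
    """Moran's I permutation test for many genes + BH correction at ``alpha``.

    The test runs on the *raw* binned values by default: Gaussian smoothing
    correlates neighboring bins by construction, so permutation p-values on
    smoothed maps would flag even spatially flat genes.  Raw bin means of an
    unpatterned gene are exchangeable across bins, which is what calibrates
    the permutation null.  Pass ``layer='best'`` to test whatever layer the
    maps carry.  Each gene gets an independent child seed spawned from
    ``seed`` so p-values are mutually independent under the null.
    """
    from dataclasses import replace as _replace

    if layer == "raw":
        test_maps = [_replace(m, smoothed=None) for m in maps]
    elif layer == "best":
        test_maps = maps
    else:
        raise ValueError("layer must be 'raw' or 'best'")
    seeds = np.random.SeedSequence(seed).spawn(len(test_maps))
    stats_ = []
    for gmap, ss in zip(test_maps, seeds):
        st = morans_test(gmap, weights, n_perm=n_perm, seed=ss.generate_state(1)[0] % (2**31))
        st.alpha = alpha
        stats_.append(st)
    q = bh_adjust([s.p_value for s in stats_])
    for s, qv in zip(stats_, q):
        s.q_value = float(qv)
        s.significant = bool(qv < alpha)
    return stats_


def _joint_defined(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    mask = np.isfinite(a) & np.isfinite(b)
    if not mask.any():
        raise ValueError("maps share no defined bins")
    return mask


def cosine_similarity(map_a: GeneMap, map_b: GeneMap) -> float:
    """Cosine similarity of two maps over their jointly defined bins."""
    a, b = map_a.best().ravel(), map_b.best().ravel()
    mask = _joint_defined(a, b)
    a, b = a[mask], b[mask]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


def pearson_spatial(map_a: GeneMap, map_b: GeneMap) -> tuple[float, float]:
    """Pearson r and two-sided p over jointly defined bins.

    Patterns are conventionally called similar at r > 0.9 with p < 0.001
    (see :func:`is_pattern_similar`).
    """
    a, b = map_a.best().ravel(), map_b.best().ravel()
    mask = _joint_defined(a, b)
    if mask.sum() < 3:
        raise ValueError("need ≥3 jointly defined bins for Pearson correlation")
    a, b = a[mask], b[mask]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the maps over the joint bins")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def is_pattern_similar(r: float, p: float, r_min: float = 0.9, p_max: float = 0.001) -> bool:
    return (r > r_min) and (p < p_max)


@dataclass
class AnchorSet:
    """Greedy anchor genes, per-gene assignment, and anchor groups."""

    anchors: list[str]
    assignment: pd.DataFrame  # index gene; columns anchor, similarity
    anchor_groups: list[list[str]] = field(default_factory=list)
    member_counts: dict[str, int] = field(default_factory=dict)
    tau_redundancy: float = 0.9


def select_anchors(
    stats_: list[SpatialStat],
    maps: dict[str, GeneMap],
    A_max: int = 20,
    tau_redundancy: float = 0.9,
) -> AnchorSet:
    """Greedy anchor selection maximizing spatial autocorrelation.

    Significant genes are scanned in decreasing Moran's I (ties broken by
    input order); a gene becomes an anchor iff its cosine similarity to every
    current anchor is < ``tau_redundancy``.  Every significant gene is then
    assigned to its most-similar anchor.
    """
    if A_max < 1:
        raise ValueError("A_max must be ≥ 1")
    if not (0 < tau_redundancy < 1):
        raise ValueError("tau_redundancy must be in (0, 1)")
    sig = [s for s in stats_ if s.significant]
    if not sig:
        raise ValueError("no significant genes to select anchors from")
    order = sorted(range(len(sig)), key=lambda k: (-sig[k].I, k))
    anchors: list[str] = []
    for k in order:
        gene = sig[k].gene
        if len(anchors) >= A_max:
            break
        sims = [cosine_similarity(maps[gene], maps[a]) for a in anchors]
        if all(not np.isfinite(s) or s < tau_redundancy for s in sims):
            anchors.append(gene)
    rows = []
    for s in sig:
        sims = np.array([cosine_similarity(maps[s.gene], maps[a]) for a in anchors])
        sims = np.where(np.isfinite(sims), sims, -np.inf)
        best = int(np.argmax(sims))
        rows.append((s.gene, anchors[best], float(sims[best])))
    assignment = pd.DataFrame(rows, columns=["gene", "anchor", "similarity"]).set_index("gene")
    counts = assignment["anchor"].value_counts().to_dict()
    return AnchorSet(
        anchors=anchors,
        assignment=assignment,
        member_counts={a: int(counts.get(a, 0)) for a in anchors},
        tau_redundancy=tau_redundancy,
    )


def group_anchors(
    anchor_set: AnchorSet,
    maps: dict[str, GeneMap],
    min_members: int = 2,
) -> AnchorSet:
    """Merge cluster-forming anchors that are mutual nearest neighbors.

    An anchor forms a cluster iff ≥ ``min_members`` genes besides itself are
    assigned to it with similarity ≥ the redundancy threshold.  Two
    cluster-forming anchors merge iff each is the other's most-similar anchor;
    merging is transitive.  Non-cluster-forming anchors stay singleton groups.
    """
    anchors = anchor_set.anchors
    if not anchors:
        raise ValueError("anchor set is empty")
    tau = anchor_set.tau_redundancy
    asg = anchor_set.assignment
    forms = {}
    for a in anchors:
        members = asg[(asg["anchor"] == a) & (asg.index != a) & (asg["similarity"] >= tau)]
        forms[a] = len(members) >= min_members
    # nearest anchor of each anchor (by cosine of maps)
    nearest: dict[str, str | None] = {}
    for a in anchors:
        best, best_s = None, -np.inf
        for b in anchors:
            if b == a:
                continue
            s = cosine_similarity(maps[a], maps[b])
            if np.isfinite(s) and s > best_s:
                best, best_s = b, s
        nearest[a] = best
    # union-find over mutual-NN pairs among cluster-forming anchors
    parent = {a: a for a in anchors}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in anchors:
        b = nearest[a]
        if b is not None and forms.get(a) and forms.get(b) and nearest[b] == a:
            parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for a in anchors:
        groups.setdefault(find(a), []).append(a)
    anchor_set.anchor_groups = [groups[r] for r in sorted(groups, key=anchors.index)]
    return anchor_set


def svg_table(stats_: list[SpatialStat]) -> pd.DataFrame:
    """Spatially-variable-gene report (gene, I, n, p, q, significant)."""
    return pd.DataFrame(
        [(s.gene, s.I, s.n, s.p_value, s.q_value, s.significant) for s in stats_],
        columns=["gene", "morans_I", "n_bins", "p_value", "q_value", "significant"],
    )
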