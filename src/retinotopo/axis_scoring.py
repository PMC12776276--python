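"""Per-cell positional scoring along the retinal DV and NT axes.

Each axis identity (dorsal, ventral, nasal, temporal) is scored as a gene
*module score*: the mean log-normalized expression of the axis marker set in a
cell, minus the mean expression of expression-matched control genes.  Control
genes are drawn from equal-frequency bins of per-gene mean expression so that
the subtraction cancels depth- and expression-level effects.  The composite
positional coordinates are

    DV.Score = dorsal score − ventral score
    NT.Score = nasal score − temporal score

which place every cell on a continuous dorso-ventral × naso-temporal plane.

Sampling procedure (documented so an independent oracle can mirror it):
genes are ranked by mean normalized expression over all cells (ties broken by
column order) and cut into ``n_bins`` equal-frequency bins; for each set gene,
``n_ctrl`` control genes are drawn from that gene's bin (excluding the gene
itself) without replacement, or with replacement when the bin holds fewer than
``n_ctrl`` candidates.  Draws use ``numpy.random.default_rng(seed)`` and are
taken per set gene in the order the set lists them; the control pools are
concatenated (duplicates across set genes allowed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import CellDataset, GeneSetSpec

__all__ = [
    "AxisScores",
    "compute_module_score",
    "compute_axis_scores",
    "score_distribution_summary",
]


@dataclass
class AxisScores:
    """Per-cell axis module scores and the composite DV/NT coordinates."""

    table: pd.DataFrame  # index cell_id; dorsal/ventral/nasal/temporal/dv_score/nt_score
    rng_seed: int
    n_bins: int
    n_ctrl: int

    @property
    def dv(self) -> np.ndarray:
        return self.table["dv_score"].to_numpy()

    @property
    def nt(self) -> np.ndarray:
        return self.table["nt_score"].to_numpy()

    def write(self, path) -> None:
        self.table.rename_axis("cell_id").to_csv(path, sep="\t")


def _expression_bins(gene_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin label per gene, ranked by mean (ties by order)."""
    order = np.argsort(gene_means, kind="stable")
    n = len(gene_means)
    # equal-frequency: split the rank range into n_bins near-equal chunks
    labels = np.empty(n, dtype=np.int64)
    bounds = np.linspace(0, n, n_bins + 1).round().astype(int)
    for b in range(n_bins):
        labels[order[bounds[b] : bounds[b + 1]]] = b
    return labels


def compute_module_score(
    ds: CellDataset,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Module score per cell: mean set expression − mean control expression."""
    if n_bins < 2:
        raise ValueError("n_bins must be ≥ 2")
    if n_ctrl < 1:
        raise ValueError("n_ctrl must be ≥ 1")
    if n_bins > ds.n_genes:
        raise ValueError(
            f"n_bins ({n_bins}) exceeds the number of genes ({ds.n_genes})"
        )
    norm = ds.norm_matrix()
    set_idx, missing = ds.resolve_genes(gene_set)
    if not set_idx:
        raise ValueError(f"no gene of the set is present in the dataset: {gene_set}")
    gene_means = np.asarray(norm.mean(axis=0)).ravel()
    labels = _expression_bins(gene_means, n_bins)

    rng = np.random.default_rng(seed)
    bin_members = {b: np.where(labels == b)[0] for b in np.unique(labels)}
    ctrl_idx: list[np.ndarray] = []
    for g in set_idx:
        pool = bin_members[labels[g]]
        pool = pool[pool != g]
        if pool.size == 0:
            continue
        replace = pool.size < n_ctrl
        ctrl_idx.append(rng.choice(pool, size=n_ctrl, replace=replace))
    if not ctrl_idx:
        raise ValueError("no control genes available for any set gene")
    ctrl = np.concatenate(ctrl_idx)

    set_mean = np.asarray(norm[:, set_idx].mean(axis=1)).ravel()
    # controls keep multiplicity: mean over the concatenated pool
    ctrl_mean = np.asarray(norm[:, ctrl].mean(axis=1)).ravel()
    return set_mean - ctrl_mean


def compute_axis_scores(
    ds: CellDataset,
    sets: GeneSetSpec,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> AxisScores:
    """Score all four axes and form DV.Score / NT.Score per cell."""
    cols = {}
    for axis in ("dorsal", "ventral", "nasal", "temporal"):
        cols[f"{axis}_score"] = compute_module_score(
            ds, getattr(sets, axis), n_bins=n_bins, n_ctrl=n_ctrl, seed=seed
        )
    table = pd.DataFrame(cols, index=pd.Index(ds.cells, name="cell_id"))
    table["dv_score"] = table["dorsal_score"] - table["ventral_score"]
    table["nt_score"] = table["nasal_score"] - table["temporal_score"]
    return AxisScores(table=table, rng_seed=seed, n_bins=n_bins, n_ctrl=n_ctrl)


def score_distribution_summary(
    scores: AxisScores, ds: CellDataset, by: str
) -> pd.DataFrame:
    """Per-group mean/SD/quantiles of each score, for QC.

    ``by`` names a column of the dataset's per-cell metadata.
    """
    if by not in ds.meta.columns:
        raise KeyError(f"metadata key {by!r} not found; have {list(ds.meta.columns)}")
    groups = ds.meta[by].to_numpy()
    df = scores.table.copy()
    df["_group"] = groups
    agg = df.groupby("_group").agg(["count", "mean", "std", "median"])
    q25 = df.groupby("_group").quantile(0.25)
    q75 = df.groupby("_group").quantile(0.75)
    for col in scores.table.columns:
        agg[(col, "q25")] = q25[col]
        agg[(col, "q75")] = q75[col]
    return agg.sort_index(axis=1)
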