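"""Shared dataset model, file I/O and configuration.

The pipeline's central container is :class:`CellDataset`: a sparse cell×gene
UMI count matrix with an optional log-normalized layer and a per-cell metadata
table (embryo, library, species).  Counts are read from / written to
MatrixMarket coordinate files plus tab-delimited annotation tables, the layout
emitted by the synthetic-data generator and by common single-cell tooling.

Gene symbols are matched case-insensitively (after stripping whitespace)
throughout; original casing is preserved for output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = [
    "CellDataset",
    "GeneSetSpec",
    "OrthologTable",
    "SpeciesPreset",
    "PRESETS",
    "read_cell_dataset",
    "write_cell_dataset",
    "normalize_counts",
    "load_gene_sets",
    "default_gene_sets",
    "read_ortholog_table",
    "map_orthologs",
    "get_preset",
]


def _canon(symbol: str) -> str:
    return symbol.strip().casefold()


@dataclass
class CellDataset:
    """Sparse cell×gene counts with optional normalized layer and metadata.

    Parameters
    ----------
    counts
        Non-negative integer UMI counts, cells in rows, genes in columns.
    cells, genes
        Ordered identifiers matching the matrix dimensions.
    meta
        Per-cell table indexed like ``cells`` with at least ``embryo_id``;
        ``library_id`` and ``species`` columns are conventional.
    norm
        Log-transformed size-normalized expression (same shape/order as
        ``counts``), or ``None`` until :func:`normalize_counts` is applied.
    """

    counts: sp.csr_matrix
    cells: np.ndarray
    genes: np.ndarray
    meta: pd.DataFrame
    norm: sp.csr_matrix | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cells = np.asarray(self.cells, dtype=object)
        self.genes = np.asarray(self.genes, dtype=object)
        n_cells, n_genes = self.counts.shape
        if len(self.cells) != n_cells or len(self.genes) != n_genes:
            raise ValueError(
                f"annotation/matrix dimension mismatch: matrix is "
                f"{n_cells}×{n_genes}, got {len(self.cells)} cells and "
                f"{len(self.genes)} genes"
            )
        if len(self.meta) != n_cells:
            raise ValueError(
                f"metadata has {len(self.meta)} rows for {n_cells} cells"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")
        canon = [_canon(g) for g in self.genes]
        if len(set(canon)) != len(canon):
            dupes = pd.Series(canon).value_counts()
            raise ValueError(
                "gene symbols not unique after case-folding: "
                f"{sorted(dupes[dupes > 1].index)}"
            )
        if "embryo_id" not in self.meta.columns:
            raise ValueError("metadata must contain an 'embryo_id' column")
        if self.meta["embryo_id"].astype(str).str.len().eq(0).any():
            raise ValueError("every cell must have a non-empty embryo_id")
        self._gene_index = {c: i for i, c in enumerate(canon)}

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_idx(self, symbol: str) -> int:
        """Column index of ``symbol`` (case-insensitive); KeyError if absent."""
        try:
            return self._gene_index[_canon(symbol)]
        except KeyError:
            raise KeyError(f"gene {symbol!r} not present in dataset") from None

    def resolve_genes(
        self, symbols: Iterable[str]
    ) -> tuple[list[int], list[str]]:
        """Map symbols to column indices; returns (indices, unresolved)."""
        idx, missing = [], []
        for s in symbols:
            j = self._gene_index.get(_canon(s))
            if j is None:
                missing.append(s)
            else:
                idx.append(j)
        return idx, missing

    def norm_matrix(self) -> sp.csr_matrix:
        if self.norm is None:
            raise ValueError(
                "dataset has no normalized layer; run normalize_counts first"
            )
        return self.norm


def read_cell_dataset(
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
    meta_path: str | Path,
    *,
    orientation: str = "cells_by_genes",
) -> CellDataset:
    """Load a dataset from MatrixMarket counts + delimited annotation tables.

    ``orientation`` declares the on-disk matrix layout (``cells_by_genes`` or
    ``genes_by_cells``); internally the matrix is always cells×genes.
    """
    mat = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    if orientation == "genes_by_cells":
        mat = sp.csr_matrix(mat.T)
    elif orientation != "cells_by_genes":
        raise ValueError(f"unknown orientation {orientation!r}")
    genes = pd.read_csv(genes_path, sep="\t")["gene"].to_numpy(dtype=object)
    cells = pd.read_csv(cells_path, sep="\t")["cell_id"].to_numpy(dtype=object)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"embryo_id": str})
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    if len(cells) != mat.shape[0] or len(genes) != mat.shape[1]:
        raise ValueError(
            f"annotation/matrix dimension mismatch: matrix is "
            f"{mat.shape[0]}×{mat.shape[1]} ({orientation}), annotations give "
            f"{len(cells)} cells and {len(genes)} genes"
        )
    meta = meta.reindex(cells)
    if meta["embryo_id"].isna().any():
        raise ValueError("metadata missing rows for some cells")
    return CellDataset(counts=mat, cells=cells, genes=genes, meta=meta)


def write_cell_dataset(ds: CellDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the counts + annotations layout read by :func:`read_cell_dataset`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "counts.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
        "meta": out / "meta.tsv",
    }
    scipy.io.mmwrite(
        str(paths["matrix"]), sp.coo_matrix(ds.counts), field="integer"
    )
    pd.DataFrame({"gene": ds.genes}).to_csv(paths["genes"], sep="\t", index=False)
    pd.DataFrame({"cell_id": ds.cells}).to_csv(paths["cells"], sep="\t", index=False)
    ds.meta.rename_axis("cell_id").reset_index().to_csv(
        paths["meta"], sep="\t", index=False
    )
    return paths


def normalize_counts(ds: CellDataset, scale: float = 10_000.0) -> CellDataset:
    """Seurat-style log-normalization: ``log(1 + scale·count/cell_total)``.

    Returns the same dataset with the ``norm`` layer populated; raw counts are
    untouched.  Cells with zero total counts are a hard error.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = np.asarray(ds.counts.sum(axis=1)).ravel()
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(
            f"cells with zero total counts cannot be normalized: "
            f"{list(ds.cells[zero[:20]])}"
        )
    norm = ds.counts.astype(np.float64).tocsr(copy=True)
    inv = scale / totals
    norm.data *= np.repeat(inv, np.diff(norm.indptr))
    np.log1p(norm.data, out=norm.data)
    ds.norm = norm
    ds.attrs["normalize_scale"] = float(scale)
    return ds


# ---------------------------------------------------------------------------
# Gene sets


@dataclass
class GeneSetSpec:
    """Dorsal/ventral/nasal/temporal axis marker sets for one species."""

    dorsal: list[str]
    ventral: list[str]
    nasal: list[str]
    temporal: list[str]
    species: str = ""

    def __post_init__(self) -> None:
        sets = {
            "dorsal": self.dorsal,
            "ventral": self.ventral,
            "nasal": self.nasal,
            "temporal": self.temporal,
        }
        for name, genes in sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        canon_sets = {k: {_canon(g) for g in v} for k, v in sets.items()}
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                shared = canon_sets[a] & canon_sets[b]
                if shared:
                    raise ValueError(
                        f"gene sets {a!r} and {b!r} overlap: {sorted(shared)}"
                    )

    def as_dict(self) -> dict[str, list[str]]:
        return {
            "dorsal": list(self.dorsal),
            "ventral": list(self.ventral),
            "nasal": list(self.nasal),
            "temporal": list(self.temporal),
        }

    def all_genes(self) -> list[str]:
        return self.dorsal + self.ventral + self.nasal + self.temporal

    def resolve(self, ds: CellDataset) -> dict[str, list[str]]:
        """Report unresolvable symbols per axis (empty dict = all resolve)."""
        report: dict[str, list[str]] = {}
        for axis, genes in self.as_dict().items():
            _, missing = ds.resolve_genes(genes)
            if missing:
                report[axis] = missing
        return report


def load_gene_sets(path: str | Path) -> GeneSetSpec:
    """Load a YAML mapping with dorsal/ventral/nasal/temporal lists."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    missing = [k for k in ("dorsal", "ventral", "nasal", "temporal") if k not in raw]
    if missing:
        raise ValueError(f"gene-set config missing keys: {missing}")
    return GeneSetSpec(
        dorsal=list(raw["dorsal"]),
        ventral=list(raw["ventral"]),
        nasal=list(raw["nasal"]),
        temporal=list(raw["temporal"]),
        species=raw.get("species", ""),
    )


def default_gene_sets(species: str = "chicken") -> GeneSetSpec:
    """Shipped axis marker sets (chicken symbols; human = uppercased)."""
    from importlib.resources import files

    path = files("retinotopo.data") / f"gene_sets_{species}.yaml"
    if not path.is_file():
        raise ValueError(f"no shipped gene sets for species {species!r}")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return GeneSetSpec(
        dorsal=list(raw["dorsal"]),
        ventral=list(raw["ventral"]),
        nasal=list(raw["nasal"]),
        temporal=list(raw["temporal"]),
        species=raw.get("species", species),
    )


# ---------------------------------------------------------------------------
# Orthology


@dataclass
class OrthologTable:
    """Offline ortholog lookup with primary-then-fallback source precedence."""

    rows: pd.DataFrame  # source_species, source_symbol, target_species, target_symbol, source_db

    COLUMNS = (
        "source_species",
        "source_symbol",
        "target_species",
        "target_symbol",
        "source_db",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"ortholog table missing columns: {missing}")
        key = ["source_species", "source_symbol", "target_species", "source_db"]
        dup = self.rows[self.rows.duplicated(key, keep=False)]
        if len(dup):
            conflicts = dup.groupby(key)["target_symbol"].nunique()
            conflicts = conflicts[conflicts > 1]
            if len(conflicts):
                raise ValueError(
                    "conflicting duplicate ortholog rows within one source_db: "
                    f"{list(conflicts.index)}"
                )
            self.rows = self.rows.drop_duplicates(key)


def read_ortholog_table(path: str | Path) -> OrthologTable:
    rows = pd.read_csv(path, sep="\t")
    return OrthologTable(rows=rows)


def map_orthologs(
    table: OrthologTable,
    genes: Sequence[str],
    source: str,
    target: str,
    *,
    primary_db: str = "primary",
    fallback_db: str = "fallback",
) -> tuple[dict[str, str], list[str]]:
    """Map symbols between species; returns (mapping, unmapped symbols).

    For each query symbol the primary-db mapping wins; the fallback db is
    consulted only where the primary has no row.  Lookup is case-insensitive.
    """
    if source == target:
        raise ValueError("source and target species must differ")
    sub = table.rows[
        (table.rows["source_species"] == source)
        & (table.rows["target_species"] == target)
    ]
    lut: dict[str, dict[str, str]] = {}
    for db in (primary_db, fallback_db):
        rows = sub[sub["source_db"] == db]
        lut[db] = {_canon(s): t for s, t in zip(rows["source_symbol"], rows["target_symbol"])}
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for g in genes:
        c = _canon(g)
        if c in lut[primary_db]:
            mapping[g] = lut[primary_db][c]
        elif c in lut[fallback_db]:
            mapping[g] = lut[fallback_db][c]
        else:
            unmapped.append(g)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} symbols had no ortholog: {unmapped[:10]}",
            stacklevel=2,
        )
    return mapping, unmapped


# ---------------------------------------------------------------------------
# Species presets


@dataclass(frozen=True)
class SpeciesPreset:
    """Grid reconstruction parameters for one species.

    ``grid_size`` bins per score axis, per-bin validity thresholds
    (``min_cells`` cells and ``min_counts`` total raw transcripts), Gaussian
    smoothing SD ``sigma`` in grid units, and the display clip percentile.
    """

    name: str
    grid_size: int
    min_cells: int
    min_counts: int
    sigma: float = 1.0
    clip_percentile: float = 94.0

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be ≥ 2")
        if self.min_cells < 1:
            raise ValueError("min_cells must be ≥ 1")
        if self.min_counts < 0:
            raise ValueError("min_counts must be ≥ 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 < self.clip_percentile <= 100):
            raise ValueError("clip_percentile must be in (0, 100]")


PRESETS: Mapping[str, SpeciesPreset] = {
    "chicken": SpeciesPreset("chicken", grid_size=51, min_cells=3, min_counts=20),
    "human": SpeciesPreset("human", grid_size=40, min_cells=3, min_counts=15),
    "mouse": SpeciesPreset("mouse", grid_size=51, min_cells=5, min_counts=30),
}


def get_preset(name: str) -> SpeciesPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown species preset {name!r}; valid presets: {sorted(PRESETS)}"
        ) from None
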