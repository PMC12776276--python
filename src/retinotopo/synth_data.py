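"""Synthetic retina datasets and FISH images with known spatial ground truth.

Cells carry latent positions (u, v) uniform on the unit disk — u is the
naso-temporal coordinate (nasal positive) and v the dorso-ventral coordinate
(dorsal positive).  Each gene follows a spatial archetype P(u, v) ∈ [0, 1]
scaled into a negative-binomial mean

    μ_g(c) = baseline_g · (1 + amplitude · P_g(u_c, v_c)) · s_c

with lognormal cell size factors s_c and NB dispersion φ (var = μ + φμ²).
The standard benchmark bundle emulates the chicken embryonic retina: the
shipped axis marker genes patterned along their axes, two held-out test genes
("FGF8SIM", a nasal-central spot; "CYP1B1SIM", an oblique stripe), 500
spatially flat decoy genes, and matched synthetic FISH renders of the held-out
archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .fish_quant import DEFAULT_PIXEL_SIZE_UM, FISHImage
from .io_core import CellDataset, GeneSetSpec, default_gene_sets, normalize_counts
from .topo_grid import TopoGrid

__all__ = [
    "Archetype",
    "SynthConfig",
    "BenchmarkBundle",
    "simulate_cells",
    "render_fish_image",
    "make_benchmark_suite",
    "archetype_field",
    "archetype_map_on_grid",
]


# --------------------------------------------------------------------------
# Archetype pattern functions, all mapping (u, v) in the unit disk to [0, 1]


def _spot(u, v, center=(0.40, 0.0), width=0.25):
    d2 = (u - center[0]) ** 2 + (v - center[1]) ** 2
    return np.exp(-d2 / (2 * width**2))


def _oblique(u, v, angle_deg=30.0, offset=0.0, width=0.25):
    t = np.deg2rad(angle_deg)
    d = u * np.sin(t) + v * np.cos(t) - offset
    return np.exp(-(d**2) / (2 * width**2))


_ARCHETYPES: dict[str, Callable] = {
    "dorsal_gradient": lambda u, v, **k: (v + 1) / 2,
    "ventral_gradient": lambda u, v, **k: (1 - v) / 2,
    "nasal_gradient": lambda u, v, **k: (u + 1) / 2,
    "temporal_gradient": lambda u, v, **k: (1 - u) / 2,
    "central_spot": _spot,
    "equatorial_stripe": lambda u, v, width=0.15, **k: np.exp(-(v**2) / (2 * width**2)),
    "oblique_stripe": _oblique,
    "flat": lambda u, v, **k: np.zeros_like(np.asarray(u, dtype=float)),
}

_AXIS_OF = {
    "dorsal": "dorsal_gradient",
    "ventral": "ventral_gradient",
    "nasal": "nasal_gradient",
    "temporal": "temporal_gradient",
}


@dataclass(frozen=True)
class Archetype:
    """A named spatial pattern with optional parameters."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _ARCHETYPES:
            raise ValueError(
                f"unknown archetype {self.name!r}; valid: {sorted(_ARCHETYPES)}"
            )

    def __call__(self, u, v):
        return _ARCHETYPES[self.name](u, v, **self.params)


def archetype_field(archetype: str | Archetype, u, v) -> np.ndarray:
    """Evaluate an archetype's noiseless pattern at positions (u, v)."""
    if isinstance(archetype, str):
        archetype = Archetype(archetype)
    return np.asarray(archetype(np.asarray(u), np.asarray(v)), dtype=float)


@dataclass
class SynthConfig:
    """Stated world of the simulator.

    Defaults emulate the chicken benchmark: 20,000 progenitor cells from 30
    embryos; baseline 0.5 UMI per gene per cell with lognormal per-gene spread
    for unpatterned genes; pattern amplitude 20, i.e. marker genes rise from
    ~0.5 to ~10 expected UMI across their axis (spatially restricted
    developmental genes are near-off outside their domain); NB dispersion 0.3
    and lognormal library size factors (0, 0.35).
    """

    n_cells: int = 20_000
    n_embryos: int = 30
    patterns: dict[str, str | Archetype] = field(default_factory=dict)
    baseline_mean: float = 0.5
    baseline_sigma: float = 1.0  # lognormal spread of flat-gene baselines
    amplitude: float = 20.0
    dispersion: float = 0.3
    libsize_lognorm: tuple[float, float] = (0.0, 0.35)
    seed: int = 0
    species: str = "chicken"

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be ≥ 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be ≥ 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for gene, arch in self.patterns.items():
            if isinstance(arch, str) and arch not in _ARCHETYPES:
                raise ValueError(f"gene {gene!r} has unknown archetype {arch!r}")


def simulate_cells(cfg: SynthConfig) -> tuple[CellDataset, pd.DataFrame]:
    """Simulate a CellDataset plus a truth table of latent (u, v) positions.

    Positions are uniform on the unit disk; embryo labels round-robin; counts
    gamma-Poisson with dispersion φ (var = μ + φμ²); fully seeded.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    r = np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    u, v = r * np.cos(theta), r * np.sin(theta)
    size = rng.lognormal(*cfg.libsize_lognorm, size=n)
    genes = list(cfg.patterns)
    arches = [
        a if isinstance(a, Archetype) else Archetype(a) for a in cfg.patterns.values()
    ]
    # flat genes get lognormal baseline variation so their mean expression
    # spans the markers' range (realistic control-gene pool for scoring)
    baselines = np.full(len(genes), cfg.baseline_mean)
    flat = np.array([a.name == "flat" for a in arches])
    baselines[flat] = cfg.baseline_mean * rng.lognormal(
        0.0, cfg.baseline_sigma, size=int(flat.sum())
    )
    counts = np.empty((n, len(genes)), dtype=np.int32)
    inv_phi = 1.0 / cfg.dispersion
    for k, arch in enumerate(arches):
        P = archetype_field(arch, u, v)
        mu = baselines[k] * (1.0 + cfg.amplitude * P) * size
        lam = rng.gamma(shape=inv_phi, scale=mu * cfg.dispersion)
        counts[:, k] = rng.poisson(lam)
    cells = np.array([f"cell_{i:05d}" for i in range(n)], dtype=object)
    embryos = np.array([f"embryo_{i % cfg.n_embryos:02d}" for i in range(n)])
    meta = pd.DataFrame(
        {
            "embryo_id": embryos,
            "library_id": [f"lib_{i % 4}" for i in range(n)],
            "species": cfg.species,
        },
        index=pd.Index(cells, name="cell_id"),
    )
    ds = CellDataset(
        counts=sp.csr_matrix(counts),
        cells=cells,
        genes=np.array(genes, dtype=object),
        meta=meta,
    )
    ds.attrs["synth_seed"] = cfg.seed
    truth = pd.DataFrame(
        {"u": u, "v": v, "embryo_id": embryos}, index=pd.Index(cells, name="cell_id")
    )
    return ds, truth


def render_fish_image(
    archetype: str | Archetype,
    shape_px: tuple[int, int] = (400, 400),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[FISHImage, np.ndarray]:
    """Render an archetype on a disk-masked image plus Gaussian noise.

    Returns ``(image, truth)`` where ``truth`` is the noiseless field (NaN off
    the disk).  Orientation matches the flat-mount convention: nasal (u+) to
    the right, dorsal (v+) at the top.
    """
    h, w = shape_px
    if h < 2 or w < 2:
        raise ValueError("image dimensions must be ≥ 2")
    rows, cols = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    radius = 0.48 * min(h, w)
    uu = (cols - cx) / radius
    vv = (cy - rows) / radius  # rows increase downward; dorsal is up
    mask = uu**2 + vv**2 <= 1.0
    field_ = archetype_field(archetype, uu, vv)
    rng = np.random.default_rng(seed)
    noisy = np.clip(field_ + rng.normal(0, noise_sd, size=field_.shape), 0, None)
    intensity = np.where(mask, noisy, 0.0)
    truth = np.where(mask, field_, np.nan)
    img = FISHImage(intensity=intensity, mask=mask, pixel_size_um=pixel_size_um)
    return img, truth


@dataclass
class BenchmarkBundle:
    """Standard synthetic benchmark used by the acceptance suites."""

    dataset: CellDataset
    truth: pd.DataFrame
    gene_sets: GeneSetSpec
    patterns: dict[str, Archetype]
    fish: dict[str, tuple[FISHImage, np.ndarray]]
    config: SynthConfig


FGF8SIM_SPOT = Archetype("central_spot", {"center": (0.40, 0.0), "width": 0.25})
CYP1B1SIM_STRIPE = Archetype("oblique_stripe", {"angle_deg": 30.0, "offset": 0.0, "width": 0.25})


def make_benchmark_suite(
    seed: int = 0, n_cells: int = 20_000, n_decoys: int = 500
) -> BenchmarkBundle:
    """Chicken-like benchmark: patterned markers, held-out test genes, decoys.

    The two held-out genes are excluded from every scoring set; their spatial
    structure must be recovered by the reconstruction alone, mirroring the
    held-out validation a limited marker panel is expected to pass.
    """
    sets = default_gene_sets("chicken")
    patterns: dict[str, Archetype] = {}
    for axis in ("dorsal", "ventral", "nasal", "temporal"):
        for g in getattr(sets, axis):
            patterns[g] = Archetype(_AXIS_OF[axis])
    patterns["FGF8SIM"] = FGF8SIM_SPOT
    patterns["CYP1B1SIM"] = CYP1B1SIM_STRIPE
    for k in range(n_decoys):
        patterns[f"DECOY{k:03d}"] = Archetype("flat")
    cfg = SynthConfig(n_cells=n_cells, patterns=patterns, seed=seed)
    ds, truth = simulate_cells(cfg)
    normalize_counts(ds)
    fish = {
        gene: render_fish_image(patterns[gene], seed=seed + 1 + k)
        for k, gene in enumerate(("FGF8SIM", "CYP1B1SIM"))
    }
    return BenchmarkBundle(
        dataset=ds,
        truth=truth,
        gene_sets=sets,
        patterns=patterns,
        fish=fish,
        config=cfg,
    )


def archetype_map_on_grid(
    grid: TopoGrid, truth: pd.DataFrame, archetype: str | Archetype
) -> np.ndarray:
    """Noiseless archetype rendered on a grid: per-bin mean of P(u, v).

    Averages the archetype over the cells assigned to each bin, giving the
    ground-truth map a perfect reconstruction would recover (NaN off the valid
    mask).
    """
    P = archetype_field(archetype, truth["u"].to_numpy(), truth["v"].to_numpy())
    G = grid.G
    flat = grid.cell_assignment[:, 0] * G + grid.cell_assignment[:, 1]
    sums = np.bincount(flat, weights=P, minlength=G * G).reshape(G, G)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / grid.n_cells
    return np.where(grid.valid, means, np.nan)
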