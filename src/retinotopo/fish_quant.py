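"""Quantification of RNA-FISH flat-mount images.

A masked grayscale image is divided into square blocks (25×25 px by default,
1 px = 0.3248 μm); the mean intensity over foreground pixels of each block
gives a block map, which is min–max normalized to [0, 1], optionally
re-normalized per row/column to emphasize one axis, and profiled along the DV
or NT axis in a 500 μm-wide strip anchored at a user-set origin (conventionally
the high-acuity area).  Profiles from aligned samples are interpolated onto a
common spatial axis and averaged.

Orientation convention: nasal to the right, ventral at the bottom, so image
columns run temporal→nasal and rows run dorsal→ventral.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .profile_tools import Profile1D

__all__ = [
    "FISHImage",
    "BlockMap",
    "read_fish_image",
    "prefilter_image",
    "block_quantify",
    "normalize01",
    "axis_normalize",
    "set_origin",
    "extract_strip_profile",
    "aggregate_profiles",
]

DEFAULT_PIXEL_SIZE_UM = 0.3248
DEFAULT_BLOCK_PX = 25


def strip_width_px(
    strip_width_um: float = 500.0, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
) -> int:
    """Strip width in pixels: round(width_um / pixel_size_um); 1539 at defaults."""
    return round(strip_width_um / pixel_size_um)


@dataclass
class FISHImage:
    """Single-channel intensity image with a tissue foreground mask."""

    intensity: np.ndarray
    mask: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    orientation: str = "nasal-right,ventral-bottom"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.intensity.shape != self.mask.shape:
            raise ValueError(
                f"intensity {self.intensity.shape} and mask {self.mask.shape} "
                "shapes differ"
            )
        if self.intensity.ndim != 2:
            raise ValueError("image must be 2D grayscale")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


def read_fish_image(
    image_path: str | Path,
    mask_path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> FISHImage:
    """Load a grayscale TIFF and its binary mask TIFF/PNG."""
    img = tifffile.imread(str(image_path)).astype(np.float64)
    mask = tifffile.imread(str(mask_path))
    return FISHImage(intensity=img, mask=np.asarray(mask) > 0, pixel_size_um=pixel_size_um)


def prefilter_image(
    img: FISHImage,
    remove_outliers: bool = False,
    outlier_radius_px: int = 2,
    outlier_threshold: float = 50.0,
    gaussian_blur: bool = False,
    blur_sigma_px: float = 5.0,
    subtract_background: bool = False,
) -> FISHImage:
    """Optional FIJI-style pre-filters (off by default; quantification runs on
    raw images).

    - remove_outliers: replace pixels brighter than the local median by more
      than ``outlier_threshold`` with that median (bright-outlier removal).
    - gaussian_blur: Gaussian filter of SD ``blur_sigma_px``.
    - subtract_background: subtract the mean intensity outside the mask,
      clipping at zero.
    """
    out = img.intensity.copy()
    if remove_outliers:
        size = 2 * outlier_radius_px + 1
        med = ndimage.median_filter(out, size=size)
        bright = out - med > outlier_threshold
        out[bright] = med[bright]
    if gaussian_blur:
        out = ndimage.gaussian_filter(out, blur_sigma_px)
    if subtract_background:
        bg = out[~img.mask]
        if bg.size:
            out = np.clip(out - bg.mean(), 0, None)
    return replace(img, intensity=out)


@dataclass
class BlockMap:
    """Per-block mean intensities of a masked image.

    ``values`` is NaN on blocks with no foreground pixel.  The origin (block
    coordinates) anchors downstream profile positions at 0 μm.
    """

    values: np.ndarray
    block_size_px: int
    pixel_size_um: float
    origin: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def block_size_um(self) -> float:
        return self.block_size_px * self.pixel_size_um

    def write(self, out_prefix: str | Path) -> None:
        prefix = Path(out_prefix)
        np.savetxt(f"{prefix}.tsv", self.values, delimiter="\t")
        sidecar = {
            "block_size_px": self.block_size_px,
            "pixel_size_um": self.pixel_size_um,
            "origin": list(self.origin) if self.origin else None,
            **self.meta,
        }
        Path(f"{prefix}.json").write_text(json.dumps(sidecar, indent=1))


def block_quantify(img: FISHImage, block_size_px: int = DEFAULT_BLOCK_PX) -> BlockMap:
    """Mean foreground intensity per block; blocks tile from the top-left.

    Edge blocks are partial (mean over the available pixels); blocks without
    any foreground pixel are missing.
    """
    if block_size_px < 1:
        raise ValueError("block_size_px must be ≥ 1")
    if not img.mask.any():
        raise ValueError("mask has no foreground pixels")
    h, w = img.intensity.shape
    nbr = -(-h // block_size_px)
    nbc = -(-w // block_size_px)
    row_idx = np.arange(0, h, block_size_px)
    col_idx = np.arange(0, w, block_size_px)
    masked = np.where(img.mask, img.intensity, 0.0)
    sums = np.add.reduceat(np.add.reduceat(masked, row_idx, axis=0), col_idx, axis=1)
    npix = np.add.reduceat(
        np.add.reduceat(img.mask.astype(np.float64), row_idx, axis=0), col_idx, axis=1
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(npix > 0, sums / npix, np.nan)
    assert values.shape == (nbr, nbc)
    return BlockMap(
        values=values, block_size_px=block_size_px, pixel_size_um=img.pixel_size_um
    )


def normalize01(bm: BlockMap) -> BlockMap:
    """Min–max rescale defined blocks to [0, 1]."""
    vals = bm.values[bm.valid]
    if vals.size < 2 or vals.max() == vals.min():
        raise ValueError("normalization needs ≥2 defined blocks with distinct values")
    out = (bm.values - vals.min()) / (vals.max() - vals.min())
    return replace(bm, values=out, meta={**bm.meta, "normalized": "01"})


def axis_normalize(bm: BlockMap, axis: str) -> BlockMap:
    """Per-column ('column') or per-row ('row') min–max rescaling.

    Lines with fewer than two distinct defined values cannot be rescaled: they
    are left missing and their indices recorded in ``meta['skipped_lines']``.
    """
    if axis not in ("column", "row"):
        raise ValueError("axis must be 'column' or 'row'")
    v = bm.values.copy()
    if axis == "row":
        v = v.T
    out = np.full_like(v, np.nan)
    skipped = []
    for k in range(v.shape[1]):
        line = v[:, k]
        ok = np.isfinite(line)
        if ok.sum() < 2 or np.nanmax(line) == np.nanmin(line):
            if ok.any():
                skipped.append(k)
            continue
        lo, hi = np.nanmin(line), np.nanmax(line)
        out[ok, k] = (line[ok] - lo) / (hi - lo)
    if skipped:
        warnings.warn(
            f"{len(skipped)} {axis}s had <2 distinct defined blocks and were skipped",
            stacklevel=2,
        )
    if axis == "row":
        out = out.T
    return replace(
        bm, values=out, meta={**bm.meta, "normalized": axis, "skipped_lines": skipped}
    )


def set_origin(bm: BlockMap, row: int, col: int) -> BlockMap:
    """Record the (0, 0) reference block (typically the high-acuity area)."""
    nbr, nbc = bm.values.shape
    if not (0 <= row < nbr and 0 <= col < nbc):
        raise ValueError(f"origin ({row}, {col}) outside map of shape {bm.values.shape}")
    return replace(bm, origin=(row, col))


def extract_strip_profile(
    bm: BlockMap,
    axis: str,
    strip_width_um: float = 500.0,
    signal_fraction: float = 0.8,
) -> Profile1D:
    """Mean ± SD intensity along one axis within a strip through the origin.

    The strip is ``strip_width_um`` wide (in pixels: round(width/pixel_size),
    1539 px at defaults) centered on the origin line; it collects the blocks
    whose centers fall inside.  For the NT profile positions run along image
    columns (μm relative to the origin, nasal positive); for DV along rows
    (ventral positive, matching the bottom-ventral orientation).  Positions
    where fewer than ``signal_fraction`` of the strip's blocks are defined are
    dropped as background-dominated edge positions.
    """
    if bm.origin is None:
        raise ValueError("origin must be set before extracting profiles")
    if strip_width_um <= 0:
        raise ValueError("strip_width_um must be positive")
    if not (0 < signal_fraction <= 1):
        raise ValueError("signal_fraction must be in (0, 1]")
    if axis not in ("DV", "NT"):
        raise ValueError("axis must be 'DV' or 'NT'")
    width_px = strip_width_px(strip_width_um, bm.pixel_size_um)
    half_px = width_px / 2
    o_row, o_col = bm.origin
    nbr, nbc = bm.values.shape
    block_px = bm.block_size_px
    row_centers = (np.arange(nbr) + 0.5) * block_px
    col_centers = (np.arange(nbc) + 0.5) * block_px
    if axis == "NT":
        in_strip = np.abs(row_centers - (o_row + 0.5) * block_px) <= half_px
        strip = bm.values[in_strip, :]  # rows within the strip; profile over cols
        positions = (col_centers - (o_col + 0.5) * block_px) * bm.pixel_size_um
    else:
        in_strip = np.abs(col_centers - (o_col + 0.5) * block_px) <= half_px
        strip = bm.values[:, in_strip].T  # cols within strip; profile over rows
        positions = (row_centers - (o_row + 0.5) * block_px) * bm.pixel_size_um
    n_strip = strip.shape[0]
    if n_strip == 0:
        raise ValueError("strip contains no blocks; check origin and width")
    defined = np.isfinite(strip)
    frac = defined.sum(axis=0) / n_strip
    keep = frac >= signal_fraction
    if not keep.any():
        raise ValueError("no profile position passes the signal fraction filter")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(strip, axis=0)
        sd = np.nanstd(strip, axis=0, ddof=0)
    pos = positions[keep]
    origin_index = int(np.argmin(np.abs(pos))) if keep.any() else None
    return Profile1D(
        positions=pos,
        mean=mean[keep],
        spread=sd[keep],
        coverage=defined.sum(axis=0)[keep],
        spread_type="sd",
        origin_index=origin_index,
        axis=axis,
    )


def aggregate_profiles(
    profiles: list[Profile1D], step_um: float | None = None, spread: str = "sem"
) -> Profile1D:
    """Average origin-aligned profiles on a common interpolated axis.

    Per position: mean over samples with defined values, SEM (or SD) and the
    contributing sample count; SEM is missing where only one sample covers the
    position.
    """
    if len(profiles) < 2:
        raise ValueError("need ≥2 profiles to aggregate")
    if spread not in ("sem", "sd"):
        raise ValueError("spread must be 'sem' or 'sd'")
    if step_um is None:
        step_um = DEFAULT_BLOCK_PX * DEFAULT_PIXEL_SIZE_UM
    lo = min(p.positions[0] for p in profiles)
    hi = max(p.positions[-1] for p in profiles)
    axis = np.arange(lo, hi + step_um / 2, step_um)
    stack = np.full((len(profiles), axis.size), np.nan)
    for k, p in enumerate(profiles):
        ok = np.isfinite(p.mean)
        inside = (axis >= p.positions[ok][0]) & (axis <= p.positions[ok][-1])
        stack[k, inside] = np.interp(axis[inside], p.positions[ok], p.mean[ok])
    n = np.isfinite(stack).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    disp = sd / np.sqrt(n) if spread == "sem" else sd
    disp = np.where(n > 1, disp, np.nan)
    covered = n > 0
    pos = axis[covered]
    return Profile1D(
        positions=pos,
        mean=mean[covered],
        spread=disp[covered],
        coverage=n[covered],
        spread_type=spread,
        origin_index=int(np.argmin(np.abs(pos))),
        axis=profiles[0].axis,
    )


def profile_table(p: Profile1D) -> pd.DataFrame:
    """Distance (μm) / intensity / dispersion table, the exported profile format."""
    return pd.DataFrame(
        {
            "distance_um": p.positions,
            "mean_intensity": p.mean,
            p.spread_type: p.spread,
            "n": p.coverage,
        }
    )
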