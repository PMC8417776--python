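"""Likelihood-map construction, thresholding, and lesion-burden ratio.

Patch probabilities are accumulated into a per-pixel map and normalized by
coverage (each pixel's value is the mean probability of the patches covering
it), which keeps every value in [0, 1] by construction.  Thresholding the
map at θ (default 0.9, inclusive) inside the tissue mask gives the lesion
mask, whose pixel count A_lesion over the tissue count A_tissue is the
reported lesion-burden ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from . import defaults
from .patches import PatchGrid
from .tissue import TissueMask

__all__ = [
    "LikelihoodMap",
    "LesionMask",
    "QuantResult",
    "NoTissueError",
    "accumulate_map",
    "threshold_map",
    "quantify",
    "count_components",
    "dice",
]


class NoTissueError(RuntimeError):
    """Raised when A_tissue = 0 and the ratio is undefined."""


@dataclass(frozen=True)
class LikelihoodMap:
    """Per-pixel lesion likelihood in [0, 1] plus patch-coverage counts.

    ``values`` is 0 wherever ``coverage`` is 0.
    """

    values: np.ndarray  # float64, in [0, 1]
    coverage: np.ndarray  # int64, >= 0


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion raster; ``area_px`` is its true-pixel count (A_lesion)."""

    mask: np.ndarray
    area_px: int

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "LesionMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, area_px=int(mask.sum()))


@dataclass(frozen=True)
class QuantResult:
    """Per-slide quantification: areas, burden ratio, lesion count."""

    slide_id: str
    a_tissue_px: int
    a_lesion_px: int
    ratio: float
    n_lesion_components: int
    theta: float


def accumulate_map(
    image_dims: tuple[int, int],
    grid: PatchGrid,
    probs: np.ndarray,
    normalize: str = "coverage",
) -> LikelihoodMap:
    """Accumulate patch probabilities into a per-pixel likelihood map.

    ``normalize="coverage"`` (default) divides the accumulated sum by the
    number of covering patches, a per-pixel mean that is structurally
    bounded in [0, 1].  ``normalize="minmax"`` instead rescales the raw
    accumulation to [0, 1] by its own extremes; it is retained for
    comparison but makes the threshold depend on the slide's own range, so
    it is not the default.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if len(probs) != len(grid):
        raise ValueError(f"{len(probs)} probabilities for {len(grid)} grid origins")
    if len(probs) and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    h, w = image_dims
    p = grid.patch_size
    acc = np.zeros((h, w), dtype=np.float64)
    cov = np.zeros((h, w), dtype=np.int64)
    for (r, c), pr in zip(grid.origins, probs):
        acc[r : r + p, c : c + p] += pr
        cov[r : r + p, c : c + p] += 1
    covered = cov > 0
    values = np.zeros_like(acc)
    if normalize == "coverage":
        values[covered] = acc[covered] / cov[covered]
    elif normalize == "minmax":
        if covered.any():
            lo, hi = acc[covered].min(), acc[covered].max()
            if hi > lo:
                values[covered] = (acc[covered] - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return LikelihoodMap(values=values, coverage=cov)


def threshold_map(
    lmap: LikelihoodMap,
    tissue: TissueMask | np.ndarray,
    theta: float = defaults.THRESHOLD,
) -> LesionMask:
    """Lesion mask = (likelihood >= θ) ∧ tissue ∧ covered."""
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    mask = tissue.mask if isinstance(tissue, TissueMask) else np.asarray(tissue, dtype=bool)
    if mask.shape != lmap.values.shape:
        raise ValueError("tissue mask and likelihood map dimensions differ")
    lesion = (lmap.values >= theta) & mask & (lmap.coverage > 0)
    return LesionMask.from_mask(lesion)


def count_components(
    mask: LesionMask | np.ndarray,
    connectivity: int = defaults.COMPONENT_CONNECTIVITY,
    min_area_px: int = 0,
) -> int:
    """Number of connected components of area >= ``min_area_px``."""
    arr = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels, n = measure.label(arr, connectivity=1 if connectivity == 4 else 2, return_num=True)
    if min_area_px <= 1:
        return int(n)
    areas = np.bincount(labels.ravel())[1:]
    return int((areas >= min_area_px).sum())


def quantify(
    tissue: TissueMask,
    lesion: LesionMask,
    slide_id: str = "",
    theta: float = defaults.THRESHOLD,
    connectivity: int = defaults.COMPONENT_CONNECTIVITY,
    min_component_area_px: int = defaults.MIN_COMPONENT_AREA_PX,
) -> QuantResult:
    """ratio = A_lesion / A_tissue, plus a filtered lesion-component count.

    Raises :class:`NoTissueError` when A_tissue = 0 (the ratio is undefined
    and is reported as missing upstream, never as 0/0).
    """
    if np.any(lesion.mask & ~tissue.mask):
        raise ValueError("lesion mask must be a subset of the tissue mask")
    if tissue.area_px == 0:
        raise NoTissueError(f"slide {slide_id or '<unnamed>'}: no tissue detected")
    return QuantResult(
        slide_id=slide_id,
        a_tissue_px=tissue.area_px,
        a_lesion_px=lesion.area_px,
        ratio=lesion.area_px / tissue.area_px,
        n_lesion_components=count_components(
            lesion, connectivity=connectivity, min_area_px=min_component_area_px
        ),
        theta=theta,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
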