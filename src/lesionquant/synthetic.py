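"""Synthetic H&E-like slides with planted ground truth.

Real whole-slide scans of chemically induced liver lesions are not publicly
deposited, so every downstream stage of the pipeline is exercised on
synthetic slides instead: a bright near-white slide background, one smooth
darker "tissue" blob with a pink parenchyma-like texture, and bluish
higher-texture lesion blobs grown inside the tissue until they occupy a
requested fraction of the tissue area.  The generator returns the exact
tissue and lesion masks it painted, so recovery of the lesion-burden ratio
A_lesion / A_tissue can be scored against a known truth.

The texture model is deliberately minimal (two separable color/texture
classes plus scattered dark nuclei); it makes no attempt at photorealistic
staining.  See docs/methods.md for what it does and does not emulate.
"""

from __future__ import annotations

import dataclasses
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from . import defaults

__all__ = [
    "SyntheticSlideSpec",
    "GroundTruth",
    "LabeledPatchSet",
    "ArmSpec",
    "CohortSlide",
    "FractionDistribution",
    "PointMass",
    "ScaledBeta",
    "UnachievableFractionError",
    "StarvedClassError",
    "CohortGenerationError",
    "generate_slide",
    "eligible_patch_origins",
    "sample_patches",
    "generate_cohort",
    "write_cohort",
]


class UnachievableFractionError(RuntimeError):
    """Raised when lesion growth cannot reach the requested tissue fraction."""


class StarvedClassError(RuntimeError):
    """Raised when too few patch positions satisfy the purity rule for a class."""


class CohortGenerationError(RuntimeError):
    """A per-animal slide failed to generate; carries the animal identity."""


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic slide.

    ``target_lesion_fraction`` is the requested |lesion| / |tissue| pixel
    ratio; the grower hits it to within ``fraction_tolerance`` or raises.
    ``noise_sd`` is broad-band per-channel Gaussian speckle over the whole
    slide; ``lesion_speckle_sd`` adds extra high-frequency texture inside
    lesions so that lesion and normal parenchyma differ in texture energy as
    well as in hue.  ``nucleus_density`` is dark dots per 1000 px^2 of tissue.
    """

    width_px: int = 512
    height_px: int = 512
    background_intensity: int = 244
    tissue_color: tuple[int, int, int] = (228, 168, 188)
    lesion_color: tuple[int, int, int] = (158, 130, 196)
    noise_sd: float = 7.0
    lesion_speckle_sd: float = 22.0
    nucleus_density: float = 1.2
    target_lesion_fraction: float = 0.0
    n_lesion_blobs: int = 2
    fraction_tolerance: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        min_dim = 4 * defaults.PATCH_SIZE
        if self.width_px < min_dim or self.height_px < min_dim:
            raise ValueError(
                f"slide must be at least {min_dim} px per side "
                f"(4x the default patch size)"
            )
        if not 0 <= self.background_intensity <= 255:
            raise ValueError("background_intensity must be in [0, 255]")
        if self.noise_sd < 0 or self.lesion_speckle_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be nonnegative")
        if not 0 <= self.target_lesion_fraction < 1:
            raise ValueError("target_lesion_fraction must be in [0, 1)")
        if self.fraction_tolerance <= 0:
            raise ValueError("fraction_tolerance must be positive")
        if self.target_lesion_fraction + self.fraction_tolerance >= 1:
            raise ValueError("target fraction + tolerance must be < 1")
        if self.n_lesion_blobs < 0:
            raise ValueError("n_lesion_blobs must be nonnegative")
        if self.target_lesion_fraction > 0 and self.n_lesion_blobs == 0:
            raise ValueError("positive lesion fraction requires >= 1 blob")


@dataclass(frozen=True)
class GroundTruth:
    """True tissue/lesion masks of a generated slide.

    ``planted_fraction`` is |lesion_mask| / |tissue_mask| (0 when the slide
    has no tissue).  Invariant: lesion_mask is a pixel-wise subset of
    tissue_mask.
    """

    tissue_mask: np.ndarray
    lesion_mask: np.ndarray
    planted_fraction: float

    @classmethod
    def from_masks(cls, tissue_mask: np.ndarray, lesion_mask: np.ndarray) -> "GroundTruth":
        tissue_mask = np.asarray(tissue_mask, dtype=bool)
        lesion_mask = np.asarray(lesion_mask, dtype=bool)
        if tissue_mask.shape != lesion_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(lesion_mask & ~tissue_mask):
            raise ValueError("lesion_mask must be a subset of tissue_mask")
        n_tissue = int(tissue_mask.sum())
        frac = float(lesion_mask.sum()) / n_tissue if n_tissue else 0.0
        return cls(tissue_mask=tissue_mask, lesion_mask=lesion_mask, planted_fraction=frac)


@dataclass(frozen=True)
class LabeledPatchSet:
    """Training patches with binary labels (0 = normal tissue, 1 = lesion).

    ``origins`` (optional) records the (row, col) top-left corner each patch
    was cut from, for traceability back to the ground-truth masks.
    """

    patches: np.ndarray  # (N, P, P, 3) uint8
    labels: np.ndarray  # (N,) int, values in {0, 1}
    purity: float
    origins: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.patches) != len(self.labels):
            raise ValueError("patches and labels must have equal length")
        if not 0.5 < self.purity <= 1.0:
            raise ValueError("purity must be in (0.5, 1]")


# --------------------------------------------------------------------------
# fraction distributions for cohort simulation
# --------------------------------------------------------------------------


class FractionDistribution(ABC):
    """Parametric law over [0, 1) for per-animal target lesion fractions."""

    @abstractmethod
    def sample(self, rng: np.random.Generator) -> float: ...

    @property
    @abstractmethod
    def mean(self) -> float: ...

    @property
    @abstractmethod
    def sd(self) -> float: ...


@dataclass(frozen=True)
class PointMass(FractionDistribution):
    value: float = 0.0

    def sample(self, rng: np.random.Generator) -> float:
        return self.value

    @property
    def mean(self) -> float:
        return self.value

    @property
    def sd(self) -> float:
        return 0.0


@dataclass(frozen=True)
class ScaledBeta(FractionDistribution):
    """Beta(mean*conc, (1-mean)*conc) scaled by ``upper``.

    ``concentration`` controls spread: the default 50 gives an SD of about
    0.056 at mean 0.2, a realistic animal-to-animal spread of lesion burden.
    """

    mean_fraction: float = 0.2
    concentration: float = 50.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.mean_fraction < 1:
            raise ValueError("mean_fraction must be in (0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    @property
    def _ab(self) -> tuple[float, float]:
        return (
            self.mean_fraction * self.concentration,
            (1.0 - self.mean_fraction) * self.concentration,
        )

    def sample(self, rng: np.random.Generator) -> float:
        a, b = self._ab
        return float(self.upper * rng.beta(a, b))

    @property
    def mean(self) -> float:
        return self.upper * self.mean_fraction

    @property
    def sd(self) -> float:
        m = self.mean_fraction
        var = m * (1.0 - m) / (self.concentration + 1.0)
        return self.upper * float(np.sqrt(var))


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm of a simulated cohort."""

    name: str
    n_animals: int
    fraction_distribution: FractionDistribution
    base_spec: SyntheticSlideSpec = field(default_factory=SyntheticSlideSpec)


@dataclass(frozen=True)
class CohortSlide:
    arm_name: str
    animal_id: str
    image: np.ndarray
    ground_truth: GroundTruth
    spec: SyntheticSlideSpec


# --------------------------------------------------------------------------
# slide generation
# --------------------------------------------------------------------------


def _tissue_blob(spec: SyntheticSlideSpec, rng: np.random.Generator) -> np.ndarray:
    """One smooth ellipse-like blob with a low-frequency radial perturbation."""
    h, w = spec.height_px, spec.width_px
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    ry = 0.44 * h * rng.uniform(0.92, 1.0)
    rx = 0.44 * w * rng.uniform(0.92, 1.0)
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - cy) / ry
    dx = (xx - cx) / rx
    theta = np.arctan2(dy, dx)
    pert = np.zeros_like(theta)
    for k in range(2, 6):
        pert += rng.normal(0.0, 0.035) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    return dx * dx + dy * dy <= (1.0 + pert) ** 2


_STRUCT8 = np.ones((3, 3), dtype=bool)


def _grow_blob(
    allowed: np.ndarray,
    seed_rc: tuple[int, int],
    target_px: int,
    rng: np.random.Generator,
    accept: float = 0.85,
) -> np.ndarray:
    """Grow one connected blob from ``seed_rc`` toward ``target_px`` pixels.

    Growth is frontier dilation with random acceptance, restricted to
    ``allowed``; the last step takes exactly the shortfall, so the final
    area is exact unless the frontier is exhausted, in which case the
    partial blob is returned and the caller's tolerance check decides.
    Work is confined to a bounding window that expands with the blob.
    """
    h, w = allowed.shape
    blob = np.zeros_like(allowed)
    r, c = seed_rc
    blob[r, c] = True
    area = 1
    r0, r1, c0, c1 = r, r + 1, c, c + 1
    while area < target_px:
        # window with a 1-px halo for the dilation
        wr0, wr1 = max(r0 - 1, 0), min(r1 + 1, h)
        wc0, wc1 = max(c0 - 1, 0), min(c1 + 1, w)
        sub = blob[wr0:wr1, wc0:wc1]
        frontier = ndi.binary_dilation(sub, structure=_STRUCT8) & allowed[wr0:wr1, wc0:wc1] & ~sub
        fr, fc = np.nonzero(frontier)
        if fr.size == 0:
            return blob  # frontier exhausted; short of target
        keep = rng.random(fr.size) < accept
        if not keep.any():
            continue
        fr, fc = fr[keep], fc[keep]
        need = target_px - area
        if fr.size > need:
            pick = rng.choice(fr.size, size=need, replace=False)
            fr, fc = fr[pick], fc[pick]
        blob[wr0 + fr, wc0 + fc] = True
        area += fr.size
        r0 = min(r0, wr0 + fr.min())
        r1 = max(r1, wr0 + fr.max() + 1)
        c0 = min(c0, wc0 + fc.min())
        c1 = max(c1, wc0 + fc.max() + 1)
    return blob


def _plant_lesions(
    tissue: np.ndarray, spec: SyntheticSlideSpec, rng: np.random.Generator
) -> np.ndarray:
    lesion = np.zeros_like(tissue)
    if spec.target_lesion_fraction == 0:
        return lesion
    n_tissue = int(tissue.sum())
    target_total = int(round(spec.target_lesion_fraction * n_tissue))
    if target_total == 0:
        return lesion
    # keep lesions strictly interior to the tissue blob
    interior = ndi.binary_erosion(tissue, structure=_STRUCT8, iterations=3)
    max_attempts = 8
    for attempt in range(max_attempts):
        lesion[:] = False
        remaining = target_total
        for b in range(spec.n_lesion_blobs):
            blobs_left = spec.n_lesion_blobs - b
            target_b = int(round(remaining / blobs_left))
            if target_b <= 0:
                continue
            # gap of 2 px so distinct blobs stay disconnected (8-connectivity)
            occupied = ndi.binary_dilation(lesion, structure=_STRUCT8, iterations=2)
            allowed = interior & ~occupied
            cand_r, cand_c = np.nonzero(allowed)
            if cand_r.size == 0:
                break
            i = int(rng.integers(cand_r.size))
            blob = _grow_blob(allowed, (int(cand_r[i]), int(cand_c[i])), target_b, rng)
            lesion |= blob
            remaining -= int(blob.sum())
        if abs(lesion.sum() / n_tissue - spec.target_lesion_fraction) <= spec.fraction_tolerance:
            return lesion
    raise UnachievableFractionError(
        f"could not plant lesion fraction {spec.target_lesion_fraction:.3f} "
        f"(±{spec.fraction_tolerance}) in {n_tissue} tissue px "
        f"after {max_attempts} attempts"
    )


def _render(
    tissue: np.ndarray, lesion: np.ndarray, spec: SyntheticSlideSpec, rng: np.random.Generator
) -> np.ndarray:
    h, w = tissue.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = float(spec.background_intensity)
    normal = tissue & ~lesion
    for ch in range(3):
        img[..., ch][normal] = spec.tissue_color[ch]
        img[..., ch][lesion] = spec.lesion_color[ch]
    # low-frequency mottling over the tissue (shared across channels)
    mottle = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=8.0)
    mottle *= 6.0 / max(mottle.std(), 1e-12)
    img[tissue] += mottle[tissue, None]
    # extra high-frequency speckle inside lesions: texture-energy contrast
    if lesion.any() and spec.lesion_speckle_sd > 0:
        speckle = rng.normal(0.0, spec.lesion_speckle_sd, size=(h, w, 3))
        img[lesion] += speckle[lesion]
    # scattered dark nuclei over all tissue
    if spec.nucleus_density > 0 and tissue.any():
        n_nuclei = int(round(spec.nucleus_density * tissue.sum() / 1000.0))
        if n_nuclei:
            tr, tc = np.nonzero(tissue)
            pick = rng.choice(tr.size, size=min(n_nuclei, tr.size), replace=False)
            dots = np.zeros((h, w), dtype=bool)
            dots[tr[pick], tc[pick]] = True
            dots = ndi.binary_dilation(dots, structure=_STRUCT8) & tissue
            img[dots] = np.array([92.0, 62.0, 118.0])
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_slide(spec: SyntheticSlideSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate one synthetic slide and its ground truth.

    Deterministic for a fixed ``spec`` (including its seed).  Raises
    :class:`UnachievableFractionError` when the requested lesion fraction
    cannot be planted inside the tissue blob.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_blob(spec, rng)
    lesion = _plant_lesions(tissue, spec, rng)
    image = _render(tissue, lesion, spec, rng)
    return image, GroundTruth.from_masks(tissue, lesion)


# --------------------------------------------------------------------------
# labeled patch sampling
# --------------------------------------------------------------------------


def _window_sums(mask: np.ndarray, p: int) -> np.ndarray:
    """Sum of ``mask`` over every p x p window (valid positions only)."""
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
    return ii[p:, p:] - ii[:-p, p:] - ii[p:, :-p] + ii[:-p, :-p]


def eligible_patch_origins(
    gt: GroundTruth, patch_size: int, purity: float, label: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-left corners of patches eligible for ``label`` under ``purity``.

    Label 1 requires ground-truth lesion coverage >= purity; label 0
    requires lesion coverage <= 1 - purity and tissue coverage >= purity.
    """
    if not 0.5 < purity <= 1.0:
        raise ValueError("purity must be in (0.5, 1]")
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    p = patch_size
    denom = float(p * p)
    eps = 1e-9
    les_frac = _window_sums(gt.lesion_mask, p) / denom
    if label == 1:
        return np.nonzero(les_frac >= purity - eps)
    tis_frac = _window_sums(gt.tissue_mask, p) / denom
    return np.nonzero((les_frac <= 1.0 - purity + eps) & (tis_frac >= purity - eps))


def sample_patches(
    image: np.ndarray,
    gt: GroundTruth,
    patch_size: int = defaults.PATCH_SIZE,
    n_per_class: int = 200,
    purity: float = 0.9,
    seed: int = 0,
) -> LabeledPatchSet:
    """Sample ``n_per_class`` training patches per label without replacement.

    A patch is eligible for label 1 when its ground-truth lesion coverage is
    at least ``purity``, and for label 0 when its lesion coverage is at most
    ``1 - purity`` and its tissue coverage at least ``purity``.
    """
    p = patch_size
    if p > min(image.shape[:2]):
        raise ValueError("patch_size larger than image")
    elig = {
        1: eligible_patch_origins(gt, p, purity, 1),
        0: eligible_patch_origins(gt, p, purity, 0),
    }
    rng = np.random.default_rng(seed)
    patches, labels, origins = [], [], []
    for label in (0, 1):
        rr, cc = elig[label]
        if rr.size < n_per_class:
            raise StarvedClassError(
                f"class {label}: only {rr.size} eligible patch positions "
                f"for {n_per_class} requested (purity {purity})"
            )
        pick = rng.choice(rr.size, size=n_per_class, replace=False)
        for i in pick:
            r, c = int(rr[i]), int(cc[i])
            patches.append(image[r : r + p, c : c + p].copy())
            labels.append(label)
            origins.append((r, c))
    return LabeledPatchSet(
        patches=np.stack(patches),
        labels=np.asarray(labels, dtype=np.int64),
        purity=purity,
        origins=np.asarray(origins, dtype=np.int64),
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


def generate_cohort(arm_specs: Sequence[ArmSpec], seed: int = 0) -> list[CohortSlide]:
    """One slide per animal; per-animal fractions drawn i.i.d. per arm.

    Fully reproducible from ``seed``; per-slide seeds are derived from the
    cohort generator so arms do not share randomness.
    """
    rng = np.random.default_rng(seed)
    slides: list[CohortSlide] = []
    for arm in arm_specs:
        for i in range(arm.n_animals):
            animal_id = f"{arm.name}-{i + 1:02d}"
            frac = float(arm.fraction_distribution.sample(rng))
            frac = min(max(frac, 0.0), 1.0 - arm.base_spec.fraction_tolerance - 1e-6)
            slide_seed = int(rng.integers(2**31))
            spec = dataclasses.replace(
                arm.base_spec, target_lesion_fraction=frac, seed=slide_seed
            )
            try:
                image, gt = generate_slide(spec)
            except UnachievableFractionError as e:
                raise CohortGenerationError(f"animal {animal_id}: {e}") from e
            slides.append(CohortSlide(arm.name, animal_id, image, gt, spec))
    return slides


def write_cohort(cohort: Sequence[CohortSlide], outdir: str | Path) -> pd.DataFrame:
    """Write slide/mask PNGs plus a manifest CSV; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        stem = s.animal_id
        image_path = outdir / f"{stem}.png"
        tmask_path = outdir / f"{stem}_tissue.png"
        lmask_path = outdir / f"{stem}_lesion.png"
        iio.imwrite(image_path, s.image)
        iio.imwrite(tmask_path, (s.ground_truth.tissue_mask * np.uint8(255)))
        iio.imwrite(lmask_path, (s.ground_truth.lesion_mask * np.uint8(255)))
        rows.append(
            {
                "arm": s.arm_name,
                "animal_id": s.animal_id,
                "image_path": image_path.name,
                "tissue_mask_path": tmask_path.name,
                "lesion_mask_path": lmask_path.name,
                "planted_fraction": s.ground_truth.planted_fraction,
                "seed": s.spec.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
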