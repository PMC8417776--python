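"""Sliding-window patch grid and the reference lesion-probability classifier.

The slide's tissue region is tiled by a sliding window (stride may be
smaller than the patch for overlap; a flush position is appended per axis so
the window reaches the image edge).  Each retained patch is mapped to a
12-number texture summary — per channel: mean, standard deviation, and
horizontal/vertical gradient energy — and a standardized L2-regularized
logistic model converts the summary to a lesion probability.

The classifier is a deterministic, seconds-to-train stand-in for a
convolutional network; anything exposing ``predict_prob`` over patches can
be dropped in via the same contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize

from . import defaults
from .synthetic import LabeledPatchSet
from .tissue import TissueMask

__all__ = [
    "PatchGrid",
    "PatchClassifier",
    "NotFittedError",
    "SingleClassError",
    "build_grid",
    "extract_features",
    "features_for_patches",
    "features_for_grid",
    "fit_classifier",
    "predict_probs",
]

N_FEATURES = 12


class NotFittedError(RuntimeError):
    pass


class SingleClassError(ValueError):
    pass


@dataclass(frozen=True)
class PatchGrid:
    """Retained sliding-window origins (row-major sorted, top-left corners)."""

    patch_size: int
    stride: int
    origins: np.ndarray  # (N, 2) int64 (row, col)
    tissue_fraction: np.ndarray  # (N,) float64

    def __len__(self) -> int:
        return len(self.origins)


def _axis_positions(dim: int, p: int, s: int) -> np.ndarray:
    pos = list(range(0, dim - p + 1, s))
    if pos[-1] != dim - p:
        pos.append(dim - p)  # flush position so the window reaches the edge
    return np.asarray(pos, dtype=np.int64)


def _integral(mask: np.ndarray) -> np.ndarray:
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(mask, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def build_grid(
    image_dims: tuple[int, int],
    tissue: TissueMask | np.ndarray,
    patch_size: int = defaults.PATCH_SIZE,
    stride: int = defaults.STRIDE,
    min_tissue_frac: float = defaults.MIN_TISSUE_FRAC,
) -> PatchGrid:
    """Candidate origins on the stride lattice (+ flush), kept when the
    patch's tissue fraction is at least ``min_tissue_frac``."""
    h, w = image_dims
    p, s = patch_size, stride
    if p > min(h, w):
        raise ValueError("patch_size larger than image")
    if s < 1:
        raise ValueError("stride must be >= 1")
    if not 0 <= min_tissue_frac <= 1:
        raise ValueError("min_tissue_frac must be in [0, 1]")
    mask = tissue.mask if isinstance(tissue, TissueMask) else np.asarray(tissue, dtype=bool)
    if mask.shape != (h, w):
        raise ValueError("tissue mask shape differs from image_dims")
    rows = _axis_positions(h, p, s)
    cols = _axis_positions(w, p, s)
    ii = _integral(mask)
    win = ii[rows[:, None] + p, cols[None, :] + p]
    win = win - ii[rows[:, None], cols[None, :] + p]
    win = win - ii[rows[:, None] + p, cols[None, :]]
    win = win + ii[rows[:, None], cols[None, :]]
    frac = win / float(p * p)
    keep = frac >= min_tissue_frac
    rr, cc = np.nonzero(keep)
    origins = np.stack([rows[rr], cols[cc]], axis=1)
    return PatchGrid(
        patch_size=p, stride=s, origins=origins, tissue_fraction=frac[rr, cc]
    )


# --------------------------------------------------------------------------
# features
# --------------------------------------------------------------------------


def extract_features(patch: np.ndarray) -> np.ndarray:
    """12 texture numbers for one P x P RGB patch.

    Per channel, in order: mean, population SD, horizontal gradient energy
    (mean |difference| of horizontally adjacent pixels), vertical gradient
    energy.  Reference single-patch implementation; ``features_for_patches``
    is the vectorized equivalent.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 3 or patch.shape[-1] != 3 or patch.shape[0] != patch.shape[1]:
        raise ValueError("expected a square P x P x 3 patch")
    out = np.empty(N_FEATURES)
    for ch in range(3):
        x = patch[..., ch]
        out[4 * ch + 0] = x.mean()
        out[4 * ch + 1] = x.std()
        out[4 * ch + 2] = np.abs(np.diff(x, axis=1)).mean()
        out[4 * ch + 3] = np.abs(np.diff(x, axis=0)).mean()
    return out


def features_for_patches(patches: np.ndarray) -> np.ndarray:
    """Vectorized :func:`extract_features` over an (N, P, P, 3) stack."""
    x = np.asarray(patches, dtype=np.float64)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError("expected an (N, P, P, 3) array")
    feats = np.empty((x.shape[0], N_FEATURES))
    feats[:, 0::4] = x.mean(axis=(1, 2))
    feats[:, 1::4] = x.std(axis=(1, 2))
    feats[:, 2::4] = np.abs(np.diff(x, axis=2)).mean(axis=(1, 2))
    feats[:, 3::4] = np.abs(np.diff(x, axis=1)).mean(axis=(1, 2))
    return feats


def features_for_grid(image: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Features for every grid patch, via per-channel integral images.

    Equivalent to slicing each patch and calling :func:`extract_features`,
    but O(image + patches) instead of O(patches * P^2).
    """
    img = np.asarray(image, dtype=np.float64)
    p = grid.patch_size
    n = len(grid)
    feats = np.empty((n, N_FEATURES))
    if n == 0:
        return feats
    r = grid.origins[:, 0]
    c = grid.origins[:, 1]

    def winsum(arr: np.ndarray, rr: np.ndarray, cc: np.ndarray, hh: int, ww: int) -> np.ndarray:
        ii = _integral(arr)
        return ii[rr + hh, cc + ww] - ii[rr, cc + ww] - ii[rr + hh, cc] + ii[rr, cc]

    area = float(p * p)
    for ch in range(3):
        x = img[..., ch]
        s1 = winsum(x, r, c, p, p)
        s2 = winsum(x * x, r, c, p, p)
        mean = s1 / area
        var = np.maximum(s2 / area - mean * mean, 0.0)
        dh = np.abs(np.diff(x, axis=1))
        dv = np.abs(np.diff(x, axis=0))
        gh = winsum(dh, r, c, p, p - 1) / (p * (p - 1))
        gv = winsum(dv, r, c, p - 1, p) / (p * (p - 1))
        feats[:, 4 * ch + 0] = mean
        feats[:, 4 * ch + 1] = np.sqrt(var)
        feats[:, 4 * ch + 2] = gh
        feats[:, 4 * ch + 3] = gv
    return feats


# --------------------------------------------------------------------------
# classifier
# --------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class PatchClassifier:
    """Standardized L2-regularized logistic model over patch texture features.

    The objective is mean log-loss + (reg_strength/2)·||w||² (intercept not
    penalized), minimized by full-batch L-BFGS to gradient tolerance 1e-8 —
    deterministic given the data, and invariant to duplicating the training
    set (the loss is a per-sample mean).
    """

    patch_size: int = defaults.PATCH_SIZE
    reg_strength: float = defaults.REG_STRENGTH
    weights: np.ndarray | None = None
    intercept: float = 0.0
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    train_accuracy: float | None = None

    @property
    def is_fitted(self) -> bool:
        return self.weights is not None

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.feature_mean) / self.feature_sd

    def predict_prob(self, patches: np.ndarray) -> np.ndarray:
        """Lesion probability for an (N, P, P, 3) patch stack."""
        if not self.is_fitted:
            raise NotFittedError("classifier has not been fitted")
        z = self._standardize(features_for_patches(patches))
        return _sigmoid(z @ self.weights + self.intercept)

    def predict_prob_features(self, feats: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise NotFittedError("classifier has not been fitted")
        z = self._standardize(feats)
        return _sigmoid(z @ self.weights + self.intercept)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        if not self.is_fitted:
            raise NotFittedError("cannot serialize an unfitted classifier")
        doc = {
            "format": "lesionquant-patch-classifier-v1",
            "patch_size": self.patch_size,
            "reg_strength": self.reg_strength,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "train_accuracy": self.train_accuracy,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PatchClassifier":
        doc = json.loads(text)
        return cls(
            patch_size=int(doc["patch_size"]),
            reg_strength=float(doc["reg_strength"]),
            weights=np.asarray(doc["weights"], dtype=np.float64),
            intercept=float(doc["intercept"]),
            feature_mean=np.asarray(doc["feature_mean"], dtype=np.float64),
            feature_sd=np.asarray(doc["feature_sd"], dtype=np.float64),
            train_accuracy=doc.get("train_accuracy"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PatchClassifier":
        return cls.from_json(Path(path).read_text())


def fit_classifier(
    train: LabeledPatchSet,
    reg_strength: float = defaults.REG_STRENGTH,
    seed: int = 0,
) -> PatchClassifier:
    """Fit the reference logistic classifier on a labeled patch set.

    ``seed`` is accepted for interface symmetry; the optimization is
    full-batch from a zero start and uses no randomness.
    """
    y = np.asarray(train.labels, dtype=np.float64)
    if np.unique(y).size < 2:
        raise SingleClassError("training set contains a single class")
    if reg_strength < 0:
        raise ValueError("reg_strength must be nonnegative")
    feats = features_for_patches(train.patches)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    x = (feats - mu) / sd
    n = x.shape[0]

    def loss_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = theta[:-1], theta[-1]
        z = x @ w + b
        # stable mean log-loss: log(1+e^z) - y z
        ll = np.logaddexp(0.0, z) - y * z
        p = _sigmoid(z)
        resid = p - y
        grad_w = x.T @ resid / n + reg_strength * w
        grad_b = resid.mean()
        val = ll.mean() + 0.5 * reg_strength * (w @ w)
        return val, np.concatenate([grad_w, [grad_b]])

    theta0 = np.zeros(x.shape[1] + 1)
    res = optimize.minimize(
        loss_grad, theta0, jac=True, method="L-BFGS-B",
        options={"maxiter": 2000, "gtol": 1e-8, "ftol": 1e-14},
    )
    w, b = res.x[:-1], float(res.x[-1])
    pred = _sigmoid(x @ w + b) >= 0.5
    clf = PatchClassifier(
        patch_size=int(train.patches.shape[1]),
        reg_strength=reg_strength,
        weights=w,
        intercept=b,
        feature_mean=mu,
        feature_sd=sd,
        train_accuracy=float((pred == (y == 1)).mean()),
    )
    return clf


def predict_probs(
    grid: PatchGrid, image: np.ndarray, clf: PatchClassifier
) -> np.ndarray:
    """One lesion probability per retained grid origin (in [0, 1])."""
    if not clf.is_fitted:
        raise NotFittedError("classifier has not been fitted")
    if grid.patch_size != clf.patch_size:
        raise ValueError(
            f"grid patch size {grid.patch_size} != classifier patch size {clf.patch_size}"
        )
    feats = features_for_grid(image, grid)
    if len(feats) == 0:
        return np.empty(0)
    return clf.predict_prob_features(feats)
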