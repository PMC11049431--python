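"""Initial color characterization of fruit photographs.

Pipeline: segment the fruit from its near-white backdrop, convert sRGB to
CIELAB (D65, 2 degree observer), optionally apply a colorimeter-style
calibration correction, summarize each image as a 5-color k-means palette,
and aggregate many palettes into a cohort-level 6-color predominance
palette ordered by pixel-weight.

The calibration model maps device-derived Lab values onto reference Lab
values (as measured by a colorimeter on calibration patches) via an affine
or quadratic-polynomial least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as skcolor
from skimage import measure
from sklearn.cluster import KMeans

__all__ = [
    "LabColor",
    "Palette",
    "CalibrationModel",
    "segment_foreground",
    "fit_color_calibration",
    "extract_palette",
    "aggregate_palettes",
    "palette_table",
    "swatch_image",
]


@dataclass(frozen=True)
class LabColor:
    L_star: float
    a_star: float
    b_star: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("weight must lie in [0, 1]")

    @property
    def lab(self) -> np.ndarray:
        return np.array([self.L_star, self.a_star, self.b_star])


@dataclass(frozen=True)
class Palette:
    """Colors ordered by descending pixel weight, with a companion sRGB rendering."""

    colors: tuple[LabColor, ...]

    def __post_init__(self) -> None:
        w = self.weights
        if np.any(np.diff(w) > 1e-9):
            raise ValueError("palette colors must be ordered by nonincreasing weight")
        if w.sum() > 1.0 + 1e-6:
            raise ValueError("palette weights must sum to <= 1")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.colors])

    @property
    def lab(self) -> np.ndarray:
        return np.array([c.lab for c in self.colors])

    @property
    def srgb(self) -> np.ndarray:
        """Companion sRGB (0..1) rendering of the Lab entries."""
        return np.clip(skcolor.lab2rgb(self.lab.reshape(1, -1, 3)).reshape(-1, 3), 0, 1)

    def __len__(self) -> int:
        return len(self.colors)


def segment_foreground(image: np.ndarray) -> np.ndarray:
    """Binary fruit mask on a near-white backdrop.

    Luminance/chroma thresholding (backdrop is bright and neutral), then
    largest connected component and hole filling.  An image with no
    foreground yields an all-False mask rather than an error.
    """
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    lab = skcolor.rgb2lab(img)
    L, a, b = lab[..., 0], lab[..., 1], lab[..., 2]
    chroma = np.hypot(a, b)
    cand = (L < 90.0) | (chroma > 12.0)
    if not cand.any():
        return np.zeros(img.shape[:2], dtype=bool)
    labels = measure.label(cand)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    return ndimage.binary_fill_holes(mask)


@dataclass(frozen=True)
class CalibrationModel:
    """Least-squares map from device Lab to reference Lab."""

    coef: np.ndarray            # (n_features, 3)
    degree: int                 # 1 (affine) or 2 (quadratic polynomial)
    residual_rms: float         # RMS Lab residual on the fit patches

    def _features(self, lab: np.ndarray) -> np.ndarray:
        lab = np.atleast_2d(np.asarray(lab, dtype=float))
        cols = [np.ones(len(lab)), lab[:, 0], lab[:, 1], lab[:, 2]]
        if self.degree == 2:
            for i in range(3):
                for j in range(i, 3):
                    cols.append(lab[:, i] * lab[:, j])
        return np.column_stack(cols)

    def apply(self, lab: np.ndarray) -> np.ndarray:
        lab = np.asarray(lab, dtype=float)
        out = self._features(lab) @ self.coef
        return out.reshape(lab.shape)


def fit_color_calibration(device_patches, reference_patches,
                          degree: int = 1) -> CalibrationModel:
    """Fit the device-to-reference Lab correction on calibration patches.

    ``degree`` 1 fits an affine map (4 parameters per channel), 2 adds the
    six Lab quadratic cross terms.  Raises when the system is
    underdetermined (fewer patches than parameters).
    """
    dev = np.atleast_2d(np.asarray(device_patches, dtype=float))
    ref = np.atleast_2d(np.asarray(reference_patches, dtype=float))
    if dev.shape != ref.shape or dev.shape[1] != 3:
        raise ValueError("device and reference patch arrays must both be (n, 3)")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    n_params = 4 if degree == 1 else 10
    if len(dev) < n_params:
        raise ValueError(f"underdetermined fit: {len(dev)} patches for {n_params} parameters")
    probe = CalibrationModel(coef=np.zeros((n_params, 3)), degree=degree, residual_rms=0.0)
    X = probe._features(dev)
    coef, *_ = np.linalg.lstsq(X, ref, rcond=None)
    resid = X @ coef - ref
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return CalibrationModel(coef=coef, degree=degree, residual_rms=rms)


def _order_palette(lab: np.ndarray, weights: np.ndarray) -> Palette:
    order = np.argsort(-weights, kind="stable")
    return Palette(tuple(LabColor(*lab[i], weight=float(weights[i])) for i in order))


def extract_palette(image: np.ndarray, mask: np.ndarray, k: int = 5,
                    seed: int = 0, calibration: CalibrationModel | None = None) -> Palette:
    """5-color k-means palette of calibrated Lab pixels under the mask.

    Cluster means become palette entries weighted by their pixel fraction
    (weights sum to 1 over the mask).  Fewer distinct colors than ``k``
    returns just the distinct colors with merged weights.
    """
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    if not np.any(mask):
        raise ValueError("mask is empty")
    lab = skcolor.rgb2lab(img)[mask]
    if calibration is not None:
        lab = calibration.apply(lab)
    uniq = np.unique(lab, axis=0)
    k_eff = min(k, len(uniq))
    if k_eff == 1:
        return Palette((LabColor(*uniq[0], weight=1.0),))
    km = KMeans(n_clusters=k_eff, n_init=4, random_state=seed).fit(lab)
    weights = np.bincount(km.labels_, minlength=k_eff) / len(lab)
    return _order_palette(km.cluster_centers_, weights)


def aggregate_palettes(palettes, m: int = 6, seed: int = 0) -> Palette:
    """Cohort-level predominance palette from many per-image palettes.

    All palette entries are pooled and clustered into ``m`` groups by
    k-means weighted by the entries' pixel fractions; output colors are the
    weighted cluster means ordered by total (renormalized) weight.
    """
    palettes = list(palettes)
    if not palettes:
        raise ValueError("palette list is empty")
    lab = np.vstack([p.lab for p in palettes])
    w = np.concatenate([p.weights for p in palettes])
    uniq = np.unique(lab, axis=0)
    if m > len(uniq):
        raise ValueError(f"m={m} exceeds the {len(uniq)} distinct palette entries")
    km = KMeans(n_clusters=m, n_init=4, random_state=seed).fit(lab, sample_weight=w)
    weights = np.array([w[km.labels_ == i].sum() for i in range(m)])
    weights = weights / weights.sum()
    return _order_palette(km.cluster_centers_, weights)


def palette_table(palette: Palette) -> pd.DataFrame:
    """Palette as a table: rank, L*, a*, b*, R, G, B (0..255), weight."""
    srgb = (palette.srgb * 255.0 + 0.5).astype(int)
    rows = [{"rank": i + 1, "L_star": c.L_star, "a_star": c.a_star, "b_star": c.b_star,
             "R": srgb[i, 0], "G": srgb[i, 1], "B": srgb[i, 2], "weight": c.weight}
            for i, c in enumerate(palette.colors)]
    return pd.DataFrame(rows)


def swatch_image(palette: Palette, height: int = 40, block: int = 40) -> np.ndarray:
    """Horizontal swatch strip (uint8) with one block per color, left = most predominant."""
    srgb = (palette.srgb * 255.0 + 0.5).astype(np.uint8)
    return np.repeat(np.repeat(srgb[None, :, :], height, axis=0), block, axis=1)
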