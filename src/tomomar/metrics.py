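"""Quantitative artifact metrics for reconstructed tomosynthesis slices.

* Artifact index (AI): per artifact ROI n, AI_n = sqrt(|rsd_n - rsd_bg|)
  where rsd is the relative standard deviation of the ROI pixels
  (coefficient of variation, SD/mean, by default; a plain-SD mode is
  switchable because the convention is not universal). Reported as the ten
  per-ROI values plus mean +/- standard error.
* MSE: plain mean squared difference between two congruent slices.
* Artifact spread function (ASF): per-slice ratio of feature-minus-
  background mean contrast to the same contrast in the in-focus slice.
* GLCM texture: intensities are clipped to [mean - SD, mean + SD],
  linearly quantized to 16 gray levels, accumulated into a symmetric
  co-occurrence matrix at a single pixel offset, and summarized by inverse
  difference moment (homogeneity), contrast (dissimilarity) and correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROISpec",
    "AIResult",
    "GLCMFeatures",
    "artifact_index",
    "image_mse",
    "asf_curve",
    "glcm_features",
]


@dataclass(frozen=True)
class ROISpec:
    """Rectangular ROI: 0-based (row, col) origin, height x width pixels."""

    row: int
    col: int
    height: int = 4
    width: int = 14
    role: str = "artifact"  # "artifact" | "background" | "feature"
    slice_index: int | None = None

    def __post_init__(self):
        if self.row < 0 or self.col < 0 or self.height <= 0 or self.width <= 0:
            raise ValueError("ROI origin must be non-negative and size positive")

    def extract(self, image: np.ndarray) -> np.ndarray:
        if self.row + self.height > image.shape[0] or self.col + self.width > image.shape[1]:
            raise ValueError(
                f"ROI {self} exceeds image of shape {image.shape}"
            )
        return image[self.row : self.row + self.height, self.col : self.col + self.width]

    def to_dict(self) -> dict:
        return {
            "row": self.row,
            "col": self.col,
            "height": self.height,
            "width": self.width,
            "role": self.role,
            "slice_index": self.slice_index,
        }


@dataclass
class AIResult:
    values: np.ndarray  # per artifact ROI
    mean: float
    stderr: float


def _roi_dispersion(pixels: np.ndarray, mode: str) -> float:
    sd = float(np.std(pixels))
    if mode == "sd":
        return sd
    if mode != "cv":
        raise ValueError("dispersion mode must be 'cv' or 'sd'")
    mean = float(np.mean(pixels))
    if abs(mean) < 1e-30:
        raise ValueError("ROI mean is zero; relative SD undefined (use mode='sd')")
    return sd / abs(mean)


def artifact_index(
    image: np.ndarray,
    artifact_rois,
    bg_roi: ROISpec,
    mode: str = "cv",
) -> AIResult:
    """Artifact index over a set of artifact ROIs against one background ROI.

    AI_n = sqrt(|rsd(artifact ROI n) - rsd(background ROI)|); the summary is
    the mean and the standard error (sample SD / sqrt(n)) over the ROIs.
    """
    image = np.asarray(image)
    rsd_bg = _roi_dispersion(bg_roi.extract(image), mode)
    values = np.array(
        [math.sqrt(abs(_roi_dispersion(r.extract(image), mode) - rsd_bg)) for r in artifact_rois]
    )
    n = len(values)
    stderr = float(values.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return AIResult(values=values, mean=float(values.mean()), stderr=stderr)


def image_mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared elementwise difference of two congruent images."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def asf_curve(
    volume: np.ndarray,
    feature_roi: ROISpec,
    bg_roi: ROISpec,
    z0: int,
) -> np.ndarray:
    """Artifact spread function across slices.

    ASF(z) = [mean(feature ROI, z) - mean(bg ROI, z)] /
             [mean(feature ROI, z0) - mean(bg ROI, z0)]
    with the ROIs fixed in (row, col) across slices. ASF(z0) is exactly 1.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must be (n_slices, H, W)")
    if not (0 <= z0 < volume.shape[0]):
        raise ValueError("in-focus slice index out of range")
    contrasts = np.array(
        [
            float(np.mean(feature_roi.extract(sl))) - float(np.mean(bg_roi.extract(sl)))
            for sl in volume
        ]
    )
    denom = contrasts[z0]
    if abs(denom) < 1e-30:
        raise ValueError("degenerate in-focus contrast: ASF denominator is zero")
    asf = contrasts / denom
    asf[z0] = 1.0
    return asf


@dataclass
class GLCMFeatures:
    inverse_difference_moment: float
    contrast: float
    correlation: float | None  # None when the image is constant
    matrix: np.ndarray = field(repr=False, default=None)


def _quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Clip to [mean - SD, mean + SD] and linearly quantize to ``levels``."""
    image = np.asarray(image, dtype=np.float64)
    m = image.mean()
    s = image.std()
    if s == 0:
        return np.zeros(image.shape, dtype=np.uint8)
    lo, hi = m - s, m + s
    clipped = np.clip(image, lo, hi)
    q = np.floor((clipped - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_features(
    image: np.ndarray,
    levels: int = 16,
    offset: tuple = (0, 1),
) -> GLCMFeatures:
    """Gray-level co-occurrence texture features at a single pixel offset.

    The co-occurrence matrix is accumulated symmetrically (both pixel
    orders), normalized to sum 1; with symmetric counting p = p^T so the
    marginal means and SDs coincide. Correlation is undefined (None) for a
    constant image; homogeneity and contrast are still returned.
    """
    image = np.asarray(image, dtype=np.float64)
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ValueError("offset must be nonzero")
    if image.shape[0] <= abs(dr) or image.shape[1] <= abs(dc):
        raise ValueError("image too small along the offset direction")

    q = _quantize(image, levels).astype(np.int64)
    # pair each pixel with its neighbor at (dr, dc); accumulate symmetrically
    h, w = q.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    if a.size == 0:
        raise ValueError("no pixel pairs at the requested offset")
    P = np.zeros((levels, levels))
    np.add.at(P, (a, b), 1.0)
    np.add.at(P, (b, a), 1.0)
    P /= P.sum()

    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    idm = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    contrast = float(np.sum((ii - jj) ** 2 * P))
    mu_i = float(np.sum(ii * P))
    mu_j = float(np.sum(jj * P))
    var_i = float(np.sum((ii - mu_i) ** 2 * P))
    var_j = float(np.sum((jj - mu_j) ** 2 * P))
    if var_i <= 0 or var_j <= 0:
        corr = None
    else:
        corr = float(np.sum((ii - mu_i) * (jj - mu_j) * P) / math.sqrt(var_i * var_j))
    return GLCMFeatures(
        inverse_difference_moment=idm, contrast=contrast, correlation=corr, matrix=P
    )
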