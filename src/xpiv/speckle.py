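"""Speckle quality metrics: contrast, autocovariance speckle size, and SR.

Projection images of microbubble tracers are speckle patterns, and classical
SNR is ill-defined for them (individual particles cannot be segmented).
Image quality is therefore quantified by

* speckle contrast ``C = sigma(I) / mean(I)`` over a region of interest,
* speckle size: the FWHM of the central lobe of the ensemble-averaged
  normalized intensity autocovariance (Wiener–Khinchin, computed by FFT),
* ``SR = P_c * C``, the measurement-accuracy surrogate combining the
  cross-correlation peak height with the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

from .stack import ImageStack

__all__ = [
    "SpeckleReport",
    "speckle_contrast",
    "autocovariance",
    "speckle_size",
    "sr_value",
    "measure_speckle",
]


@dataclass
class SpeckleReport:
    """Speckle quality over one ROI of an image ensemble."""

    contrast: float
    size_x_px: float
    size_y_px: float
    size_x_um: float | None
    size_y_um: float | None
    n_frames: int
    roi: tuple[int, int, int, int] | None  # (row0, col0, height, width)

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "speckle_size_px": [self.size_x_px, self.size_y_px],
            "speckle_size_um": (
                None if self.size_x_um is None else [self.size_x_um, self.size_y_um]
            ),
            "n_frames": self.n_frames,
            "roi": None if self.roi is None else list(self.roi),
        }


def speckle_contrast(roi: np.ndarray, min_size: int = 16) -> float:
    """Speckle contrast C = std / mean of the intensity over the ROI.

    The ROI must be at least ``min_size`` pixels along each axis and have a
    positive mean (the ratio is undefined otherwise).
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or min(roi.shape) < min_size:
        raise ValueError(f"ROI must be 2D and at least {min_size} px on each side")
    mean = roi.mean()
    if mean <= 0:
        raise ValueError("speckle contrast undefined for non-positive mean intensity")
    return float(roi.std() / mean)


def autocovariance(frames: np.ndarray | ImageStack, roi=None) -> np.ndarray:
    """Ensemble-averaged normalized autocovariance of the intensity field.

    Per frame the mean is subtracted and the (circular) autocovariance is
    computed as ``IFT(|FT(I - mean)|^2)``; the per-frame maps are ensemble
    averaged, normalized so the zero-lag value is exactly 1, and returned
    centred (zero lag at ``(h//2, w//2)``).
    """
    if isinstance(frames, ImageStack):
        frames = frames.frames
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("expected a 2D frame or an (n, h, w) ensemble")
    if roi is not None:
        r0, c0, h, w = roi
        frames = frames[:, r0 : r0 + h, c0 : c0 + w]
    centered = frames - frames.mean(axis=(1, 2), keepdims=True)
    spec = np.abs(spfft.fft2(centered, axes=(1, 2))) ** 2
    cov = spfft.ifft2(spec, axes=(1, 2)).real.mean(axis=0)
    peak = cov[0, 0]
    if peak <= 0:
        raise ValueError("zero-variance ROI: autocovariance normalization undefined")
    return np.fft.fftshift(cov / peak)


def speckle_size(
    cov_map: np.ndarray, pixel_pitch: float | None = None
) -> tuple[float, float] | tuple[float, float, float, float]:
    """FWHM of the central autocovariance lobe along each image axis.

    The half-maximum crossings are located on the centre row/column with
    linear interpolation between bracketing samples. Returns ``(size_x,
    size_y)`` in pixels, plus the same in micrometres when ``pixel_pitch``
    is given. Raises if the lobe never falls below half maximum inside the
    map (speckle larger than the ROI).
    """
    cov_map = np.asarray(cov_map, dtype=float)
    cy, cx = cov_map.shape[0] // 2, cov_map.shape[1] // 2
    size_x = _fwhm_1d(cov_map[cy, :], cx)
    size_y = _fwhm_1d(cov_map[:, cx], cy)
    if pixel_pitch is None:
        return size_x, size_y
    return size_x, size_y, size_x * pixel_pitch, size_y * pixel_pitch


def _fwhm_1d(profile: np.ndarray, center: int) -> float:
    peak = profile[center]
    half = peak / 2.0
    width = 0.0
    for direction in (1, -1):
        i = center
        crossed = False
        while 0 <= i + direction < profile.size:
            j = i + direction
            if profile[j] < half:
                # linear interpolation between samples i and j
                frac = (profile[i] - half) / (profile[i] - profile[j])
                width += abs(i - center) + frac
                crossed = True
                break
            i = j
        if not crossed:
            raise ValueError("speckle larger than ROI: lobe never falls below half max")
    return width


def sr_value(p_c: float, contrast: float) -> float:
    """Accuracy surrogate SR = P_c * C (correlation peak height times contrast)."""
    if not 0.0 <= p_c <= 1.0:
        raise ValueError(f"P_c must be in [0, 1], got {p_c}")
    if contrast < 0:
        raise ValueError("contrast must be >= 0")
    return float(p_c * contrast)


def measure_speckle(
    stack: ImageStack,
    roi: tuple[int, int, int, int] | None = None,
    n_frames: int = 100,
) -> SpeckleReport:
    """Contrast and speckle size for a stack, ensemble-averaged over frames.

    Contrast is computed on the per-frame ROI and averaged; size comes from
    the ensemble-averaged autocovariance. Default ensemble is 100 frames.
    """
    frames = stack.frames[:n_frames].astype(float)
    if roi is not None:
        r0, c0, h, w = roi
        view = frames[:, r0 : r0 + h, c0 : c0 + w]
    else:
        view = frames
    if min(view.shape[1:]) < 16:
        raise ValueError("ROI must be at least 16 px on each side")
    means = view.mean(axis=(1, 2))
    if np.any(means <= 0):
        raise ValueError("speckle contrast undefined for non-positive mean intensity")
    contrast = float(np.mean(view.std(axis=(1, 2)) / means))
    cov = autocovariance(view)
    sx, sy, sx_um, sy_um = speckle_size(cov, stack.pixel_pitch)
    return SpeckleReport(contrast, sx, sy, sx_um, sy_um, len(view), roi)
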