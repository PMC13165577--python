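"""ROI photometry and coflow-interface extraction.

Computes background-subtracted ROI intensities for the main and
aggregation-sensing chambers and locates the blood/reference interface in
the viscosity-sensing channel by Otsu binarization.  Coordinates are
0-based and row-major with the origin at the top-left; ROIs are half-open
rectangles; the cross-channel ("vertical") direction maps to image rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chip_model import Roi


class DegenerateHistogramError(ValueError):
    """The image has fewer than two distinct grey levels."""


@dataclass(frozen=True)
class IntensityRecord:
    """Per-trigger chamber intensities; delta_i is always Imc - Iac."""

    t_s: float
    i_mc: float
    i_ac: float

    @property
    def delta_i(self) -> float:
        return self.i_mc - self.i_ac


@dataclass(frozen=True)
class InterfaceRecord:
    """Per-trigger blood-filled width and normalized interface position."""

    t_s: float
    wb_mm: float
    alpha_b: float
    dispersion_mm: float
    no_blood: bool = False


def subtract_background(frame: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Signed difference frame - background in a widened integer range."""
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError(
            f"shape mismatch: frame {frame.shape} vs background {background.shape}")
    return frame.astype(np.int32) - background.astype(np.int32)


def roi_mean_intensity(frame: np.ndarray, roi: Roi) -> float:
    """Arithmetic mean grey level over the ROI."""
    if not roi.within(frame.shape[:2]):
        raise ValueError(f"ROI {roi} outside frame of shape {frame.shape}")
    patch = roi.crop(frame)
    if patch.size == 0:
        raise ValueError("empty ROI")
    return float(patch.mean())


def otsu_threshold(pixels: np.ndarray) -> int:
    """Otsu threshold over the 256-bin histogram of an 8-bit image.

    Returns the integer t maximizing the between-class variance of the
    split {v <= t} / {v > t}; ties break toward the lower threshold.
    """
    flat = np.asarray(pixels).ravel()
    if flat.size == 0:
        raise DegenerateHistogramError("empty input")
    values = np.clip(np.rint(flat), 0, 255).astype(np.int64)
    hist = np.bincount(values, minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("constant image: no threshold exists")
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]          # class {<= t}, t = 0..254
    w1 = total - w0
    cum_moment = np.cumsum(hist * np.arange(256))[:-1]
    total_moment = (hist * np.arange(256)).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = cum_moment / w0
        mu1 = (total_moment - cum_moment) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -1.0
    return int(np.argmax(var_between))  # argmax takes the first (lowest) tie


def classify_blood(pixels: np.ndarray, threshold: int) -> np.ndarray:
    """Boolean blood mask: the lower-mean class of the thresholded image."""
    arr = np.asarray(pixels, dtype=np.float64)
    low = arr <= threshold
    # blood is darker, i.e. the class with the lower mean intensity
    mean_low = arr[low].mean() if low.any() else np.inf
    mean_high = arr[~low].mean() if (~low).any() else np.inf
    return low if mean_low <= mean_high else ~low


def blood_filled_width(blood_mask: np.ndarray, pixel_scale_um: float,
                       channel_width_mm: float = 1.0,
                       t_s: float = 0.0) -> InterfaceRecord:
    """Blood-filled width from a binarized ROI.

    Counts blood pixels per column along the cross-channel (row) axis,
    converts to mm, and averages over columns: wb = mean, alpha_b = wb / w.
    A ROI with no blood pixels yields wb = 0 with a warning flag.
    """
    mask = np.asarray(blood_mask, dtype=bool)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("blood mask must be a non-empty 2-D array")
    px_mm = pixel_scale_um / 1000.0
    widths_mm = mask.sum(axis=0) * px_mm
    wb = float(widths_mm.mean())
    no_blood = not mask.any()
    if no_blood:
        warnings.warn("no blood pixels in ROI; wb = 0", RuntimeWarning,
                      stacklevel=2)
    return InterfaceRecord(t_s=t_s, wb_mm=wb,
                           alpha_b=wb / channel_width_mm,
                           dispersion_mm=float(widths_mm.std()),
                           no_blood=no_blood)


def interface_position(frame: np.ndarray, roi_vc: Roi, pixel_scale_um: float,
                       channel_width_mm: float = 1.0,
                       t_s: float = 0.0) -> InterfaceRecord:
    """Otsu-binarize the vc ROI of a raw frame and measure the interface.

    The threshold is computed on the vc ROI only, so chamber content cannot
    shift it; the blood class is assigned by mean intensity (blood darker),
    not by spatial side.
    """
    patch = roi_vc.crop(np.asarray(frame))
    thr = otsu_threshold(patch)
    mask = classify_blood(patch, thr)
    return blood_filled_width(mask, pixel_scale_um, channel_width_mm, t_s)
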