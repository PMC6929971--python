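"""Iodine calibration: attenuation excess → concentration (mg I/mL).

Scanned standards of known iodine concentration give a set of
(concentration, mean attenuation) points; an ordinary least-squares line
through them yields the attenuation rate — the change in attenuation per
unit change in iodine concentration.  The intercept is fitted rather than
forced through a background value, since only the slope carries meaning.
A weighted fit (by ROI voxel count) is exposed but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError, SegmentationError
from .volume_io import AttenuationVolume, TumorMask

__all__ = [
    "CalibrationSample",
    "CalibrationCurve",
    "measure_roi_mean",
    "fit_attenuation_rate",
]


@dataclass(frozen=True)
class CalibrationSample:
    """One scanned standard: known concentration, measured mean attenuation."""

    concentration: float
    mean_attenuation: float
    roi_voxels: int

    def __post_init__(self):
        if self.concentration < 0:
            raise InputError("calibration concentration must be >= 0")
        if self.roi_voxels < 1:
            raise InputError("roi_voxels must be >= 1")


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line: attenuation = intercept + attenuation_rate × concentration."""

    attenuation_rate: float
    intercept: float
    r_squared: float
    residual_sd: float

    def concentration_from_excess(self, attenuation_excess: float) -> float:
        """Convert an attenuation excess to mg I/mL via the slope."""
        return attenuation_excess / self.attenuation_rate


def measure_roi_mean(
    volume: AttenuationVolume,
    roi: TumorMask,
    concentration: float = math.nan,
) -> CalibrationSample:
    """Arithmetic mean attenuation over a 3D region of interest.

    Returns a :class:`CalibrationSample`; pass ``concentration`` to complete
    it, otherwise that field is NaN and must be filled before fitting.
    """
    if roi.values.shape != volume.values.shape:
        raise SegmentationError(
            f"ROI shape {roi.values.shape} != volume shape {volume.values.shape}"
        )
    n = roi.n_voxels
    if n == 0:
        raise SegmentationError("ROI is empty")
    mean = float(volume.values[roi.values].mean())
    return CalibrationSample(
        concentration=float(concentration), mean_attenuation=mean, roi_voxels=n
    )


def fit_attenuation_rate(
    samples: list[CalibrationSample], weighted: bool = False
) -> CalibrationCurve:
    """Least-squares line of mean attenuation on concentration.

    The slope is the attenuation rate (attenuation units per mg I/mL).
    With ``weighted=True`` samples are weighted by their ROI voxel count;
    the default is a plain unweighted fit.
    """
    if len(samples) < 2:
        raise InputError(f"need at least 2 calibration samples, got {len(samples)}")
    c = np.array([s.concentration for s in samples], dtype=float)
    a = np.array([s.mean_attenuation for s in samples], dtype=float)
    if np.isnan(c).any():
        raise InputError("calibration samples with unset concentration")
    if np.ptp(c) == 0:
        raise InputError(
            "all calibration concentrations identical; slope is undetermined"
        )
    w = (
        np.array([s.roi_voxels for s in samples], dtype=float)
        if weighted
        else np.ones_like(c)
    )
    wsum = w.sum()
    cbar = (w * c).sum() / wsum
    abar = (w * a).sum() / wsum
    sxx = (w * (c - cbar) ** 2).sum()
    sxy = (w * (c - cbar) * (a - abar)).sum()
    slope = sxy / sxx
    intercept = abar - slope * cbar

    resid = a - (intercept + slope * c)
    ss_res = float((w * resid**2).sum())
    ss_tot = float((w * (a - abar) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    # guard against negative epsilon from cancellation
    r_squared = min(max(r_squared, 0.0), 1.0)
    n = len(samples)
    residual_sd = math.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
    return CalibrationCurve(
        attenuation_rate=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        residual_sd=float(residual_sd),
    )
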