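"""Attenuation-histogram background deconvolution and dose estimation.

This is the core of the pipeline.  Because the contrast agent is
liposome-encapsulated it does not distribute homogeneously: large parts of
the tumor contain no agent, so the lower portion of the within-tumor
attenuation histogram samples liposome-free tissue.  A Gaussian
``A·exp(-(a-µ₀)²/2σ₀²)`` is fitted to the histogram counts over a
percentile window of the voxel values — 5th–95th percentile for
intravenous (IV) administration, 10th–50th for intratumoral (ITu), where
the lowest percentiles are discarded as partial-volume/motion artifacts.
Subtracting the fitted curve from the observed counts gives the
*differential histogram*; its (clipped, non-negative) excess counts are the
voxel population attributable to liposomes.

Integration limits are route-dependent.  The upper limit is always the
maximum attenuation measured in the tumor.  The lower limit is:

* IV — the center of the first bin at or above the 99th percentile of the
  voxel values whose excess is positive (scanning upward from the bin
  containing that percentile); if no bin qualifies the limit is undefined
  and all integrals are zero.
* ITu — the fitted background mean µ₀.

Summing excess counts over the limits and multiplying by the voxel volume
gives the volume of distribution; weighting each bin's excess by its
attenuation difference from µ₀ divided by the calibration slope gives the
iodine mass, from which the percent injected dose follows.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .calibration import CalibrationCurve
from .errors import (
    AlignmentError,
    DegenerateFitError,
    FitError,
    HistogramError,
    InputError,
)
from .volume_io import AttenuationVolume, TumorMask, VolumeMetadata

__all__ = [
    "Route",
    "DEFAULT_WINDOWS",
    "AttenuationHistogram",
    "GaussianBackground",
    "DifferentialHistogram",
    "DoseEstimate",
    "build_histogram",
    "fit_background",
    "differential_histogram",
    "estimate_volume_of_distribution",
    "estimate_iodine_mass",
    "percent_injected_dose",
    "classify_high_attenuation",
    "gaussian_curve",
]

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 1024


class Route(enum.Enum):
    """Administration route; each has its own fit window and lower limit."""

    IV = "IV"
    ITU = "ITu"

    @classmethod
    def parse(cls, label: str) -> "Route":
        norm = str(label).strip().lower()
        if norm == "iv":
            return cls.IV
        if norm in ("itu", "it"):
            return cls.ITU
        raise InputError(f"unknown route {label!r}; expected 'IV' or 'ITu'")


#: default percentile fit windows (lo, hi) per route
DEFAULT_WINDOWS: dict[Route, tuple[float, float]] = {
    Route.IV: (5.0, 95.0),
    Route.ITU: (10.0, 50.0),
}

#: IV lower-limit percentile for the excess scan
IV_SCAN_PERCENTILE = 99.0


def gaussian_curve(a, amplitude, mean, sd):
    """Unnormalized Gaussian in attenuation, used for the background fit."""
    return amplitude * np.exp(-((a - mean) ** 2) / (2.0 * sd**2))


@dataclass
class AttenuationHistogram:
    """Equal-width histogram of within-tumor attenuation values.

    Keeps the raw voxel values so percentiles are computed on the values
    themselves, not on binned counts.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_voxels: int
    values: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def max_value(self) -> float:
        return float(self.values.max())

    def percentile(self, q) -> float | np.ndarray:
        return np.percentile(self.values, q)


@dataclass(frozen=True)
class GaussianBackground:
    """Fitted no-liposome background model.

    ``mean`` (µ₀) is the attenuation at which no iodine is assumed present;
    ``sd`` (σ₀) its spread.  The percentile window actually used and the
    residual sum of squares of the fit are carried for auditability.
    """

    amplitude: float
    mean: float
    sd: float
    window_lo_pct: float
    window_hi_pct: float
    route: Route
    fit_rss: float


@dataclass
class DifferentialHistogram:
    """Per-bin excess counts over the fitted background, with limits.

    ``lower_limit`` may be ``None`` for IV data with no qualifying excess
    bin; all integrals are then zero.
    """

    bin_centers: np.ndarray
    excess_counts: np.ndarray
    lower_limit: float | None
    upper_limit: float


@dataclass(frozen=True)
class DoseEstimate:
    """Volume of distribution and dose summary for one tumor."""

    volume_of_distribution: float  # mm³
    iodine_mass: float  # mg
    percent_injected_dose: float  # %
    percent_injected_dose_per_cm3: float  # %/cm³
    tumor_volume: float  # mm³


def build_histogram(
    volume: AttenuationVolume,
    mask: TumorMask,
    n_bins: int = DEFAULT_N_BINS,
) -> AttenuationHistogram:
    """Histogram the within-mask attenuation values into equal-width bins.

    Bins span [min, max] of the masked values.  1024 bins by default: fine
    enough that quantization error is far below the recovery tolerances,
    coarse enough for stable per-bin counts at ~10⁶ voxels.
    """
    if n_bins < 16:
        raise HistogramError(f"n_bins must be >= 16, got {n_bins}")
    if mask.values.shape != volume.values.shape:
        raise AlignmentError(
            f"mask shape {mask.values.shape} != volume shape {volume.values.shape}"
        )
    if mask.n_voxels == 0:
        raise HistogramError("mask is empty; nothing to histogram")
    vals = volume.values[mask.values].astype(float, copy=False)
    counts, edges = np.histogram(vals, bins=n_bins)
    return AttenuationHistogram(
        bin_edges=edges,
        counts=counts.astype(np.int64),
        n_voxels=int(vals.size),
        values=vals,
    )


def fit_background(
    hist: AttenuationHistogram,
    route: Route,
    window: tuple[float, float] | None = None,
    max_iter: int = 500,
) -> GaussianBackground:
    """Fit the background Gaussian to a percentile window of the histogram.

    Unweighted least squares of ``A·exp(-(a-µ)²/2σ²)`` on the counts of
    bins whose centers lie within ``[P(lo), P(hi)]`` of the voxel-value
    distribution.  Initialization: A = max windowed count, µ = center of
    the max bin, σ = interquartile spread of the windowed values / 1.349
    (the Normal IQR factor — a robust start for the one-sided ITu window).
    """
    lo_pct, hi_pct = window if window is not None else DEFAULT_WINDOWS[route]
    if not (0 <= lo_pct < hi_pct <= 100):
        raise InputError(f"invalid percentile window ({lo_pct}, {hi_pct})")
    p_lo, p_hi = hist.percentile([lo_pct, hi_pct])
    centers = hist.bin_centers
    sel = (centers >= p_lo) & (centers <= p_hi)
    occupied = int(np.count_nonzero(hist.counts[sel] > 0))
    if occupied < 8:
        raise HistogramError(
            f"fit window [{p_lo:.6g}, {p_hi:.6g}] contains only {occupied} occupied "
            "bins (need >= 8); histogram too narrow for a Gaussian fit"
        )
    x = centers[sel]
    y = hist.counts[sel].astype(float)

    win_vals = hist.values[(hist.values >= p_lo) & (hist.values <= p_hi)]
    q25, q75 = np.percentile(win_vals, [25.0, 75.0])
    sigma0 = (q75 - q25) / 1.349
    if sigma0 <= 0:
        sigma0 = hist.bin_width
    a0 = float(y.max())
    mu0 = float(x[int(np.argmax(y))])
    try:
        popt, _ = curve_fit(
            gaussian_curve,
            x,
            y,
            p0=(a0, mu0, sigma0),
            maxfev=max_iter * 10,
            xtol=1e-10,
        )
    except RuntimeError as exc:
        raise FitError(
            f"background Gaussian fit did not converge: {exc}",
            last_params=(a0, mu0, sigma0),
        ) from exc
    amplitude, mean, sd = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    if sd < hist.bin_width:
        raise DegenerateFitError(
            f"fitted sigma {sd:.6g} collapsed below one bin width "
            f"{hist.bin_width:.6g}",
            last_params=(amplitude, mean, sd),
        )
    if amplitude <= 0:
        raise FitError("fitted amplitude is non-positive", last_params=tuple(popt))
    rss = float(((y - gaussian_curve(x, amplitude, mean, sd)) ** 2).sum())
    return GaussianBackground(
        amplitude=amplitude,
        mean=mean,
        sd=sd,
        window_lo_pct=float(lo_pct),
        window_hi_pct=float(hi_pct),
        route=route,
        fit_rss=rss,
    )


def differential_histogram(
    hist: AttenuationHistogram,
    bg: GaussianBackground,
    route: Route,
) -> DifferentialHistogram:
    """Observed minus fitted counts, clipped at zero, with route limits.

    Negative excess is clamped: excess counts represent voxel populations
    and cannot be negative.  The IV lower-limit scan starts at the bin
    containing the 99th-percentile voxel value and moves upward to the
    first bin with positive excess (lowest qualifying bin center wins).
    """
    centers = hist.bin_centers
    fitted = gaussian_curve(centers, bg.amplitude, bg.mean, bg.sd)
    excess = np.clip(hist.counts.astype(float) - fitted, 0.0, None)
    upper = hist.max_value
    if route is Route.ITU:
        lower: float | None = bg.mean
    else:
        p99 = float(hist.percentile(IV_SCAN_PERCENTILE))
        start = int(np.clip(
            np.searchsorted(hist.bin_edges, p99, side="right") - 1,
            0, len(centers) - 1,
        ))
        lower = None
        pos = np.nonzero(excess[start:] > 0)[0]
        if pos.size:
            lower = float(centers[start + pos[0]])
        else:
            logger.info(
                "IV lower-limit scan found no positive-excess bin at or above "
                "the 99th percentile; integrals will be zero"
            )
    return DifferentialHistogram(
        bin_centers=centers,
        excess_counts=excess,
        lower_limit=lower,
        upper_limit=upper,
    )


def _integration_selector(diff: DifferentialHistogram) -> np.ndarray | None:
    if diff.lower_limit is None:
        return None
    return (diff.bin_centers >= diff.lower_limit) & (
        diff.bin_centers <= diff.upper_limit
    )


def estimate_volume_of_distribution(
    diff: DifferentialHistogram, meta: VolumeMetadata
) -> float:
    """Volume (mm³) of voxels deviating above the background Gaussian."""
    sel = _integration_selector(diff)
    if sel is None:
        logger.info("volume of distribution: lower limit undefined, returning 0")
        return 0.0
    return float(diff.excess_counts[sel].sum()) * meta.voxel_volume_mm3


def estimate_iodine_mass(
    diff: DifferentialHistogram,
    bg: GaussianBackground,
    calib: CalibrationCurve,
    meta: VolumeMetadata,
) -> float:
    """Total iodine mass (mg) summed over the differential-histogram bins.

    Each bin's excess count is a voxel population at concentration
    ``(bin center − µ₀) / attenuation_rate`` (mg/mL); times the voxel
    volume in mL this is a per-bin mass, summed over the relevant range.
    """
    if calib.attenuation_rate <= 0:
        raise InputError("calibration attenuation_rate must be > 0")
    sel = _integration_selector(diff)
    if sel is None:
        logger.info("iodine mass: lower limit undefined, returning 0")
        return 0.0
    conc = (diff.bin_centers[sel] - bg.mean) / calib.attenuation_rate
    return float((diff.excess_counts[sel] * conc).sum()) * meta.voxel_volume_ml


def percent_injected_dose(
    iodine_mass: float,
    injected_mass: float,
    tumor_volume: float,
    volume_of_distribution: float = 0.0,
) -> DoseEstimate:
    """Percent injected dose, per tumor and per cm³ of tumor volume."""
    if injected_mass <= 0:
        raise InputError(f"injected mass must be > 0 mg, got {injected_mass}")
    pct = 100.0 * iodine_mass / injected_mass
    per_cm3 = pct / (tumor_volume / 1000.0) if tumor_volume > 0 else float("nan")
    return DoseEstimate(
        volume_of_distribution=float(volume_of_distribution),
        iodine_mass=float(iodine_mass),
        percent_injected_dose=float(pct),
        percent_injected_dose_per_cm3=float(per_cm3),
        tumor_volume=float(tumor_volume),
    )


def classify_high_attenuation(
    volume: AttenuationVolume,
    mask: TumorMask,
    diff: DifferentialHistogram,
) -> np.ndarray:
    """Binary liposome-voxel grid: within-mask voxels at or above the limit.

    This is the three-group voxel classification used for rendering
    (non-tumor / high-attenuation / other) reduced to its informative bit.
    Note this thresholding is not identical to the histogram-excess volume:
    the two agree only approximately (the excess subtracts the expected
    background population, a threshold does not).
    """
    if mask.values.shape != volume.values.shape:
        raise AlignmentError("mask does not match volume geometry")
    if diff.lower_limit is None:
        logger.info("classification: lower limit undefined, returning empty set")
        return np.zeros(volume.values.shape, dtype=bool)
    return mask.values & (volume.values >= diff.lower_limit)
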