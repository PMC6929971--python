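"""Histogram deconvolution: fits, limits, and dose estimators."""

import numpy as np
import pytest

from lipoct.calibration import CalibrationCurve
from lipoct.errors import AlignmentError, HistogramError, InputError
from lipoct.histogram_quant import (
    AttenuationHistogram,
    GaussianBackground,
    Route,
    build_histogram,
    classify_high_attenuation,
    differential_histogram,
    estimate_iodine_mass,
    estimate_volume_of_distribution,
    fit_background,
    gaussian_curve,
    percent_injected_dose,
)
from lipoct.phantom import HotspotSpec, PhantomSpec, generate_tumor_phantom
from lipoct.segmentation import apply_mask

from conftest import full_mask, make_volume


def flat_calib(rate):
    return CalibrationCurve(
        attenuation_rate=rate, intercept=0.0, r_squared=1.0, residual_sd=0.0
    )


# ---------------------------------------------------------------------------
# build_histogram


def test_histogram_conservation_and_percentiles(rng):
    vol = make_volume(rng.normal(100, 5, size=(100, 100, 100)))
    hist = build_histogram(vol, full_mask(vol))
    assert hist.counts.sum() == hist.n_voxels == 10**6
    # order-statistic bound on the median of 1e6 normals
    assert hist.percentile(50) == pytest.approx(100.0, abs=0.05)
    assert len(hist.bin_edges) == 1025


def test_histogram_constant_region_single_bin():
    vol = make_volume(np.full((10, 10, 10), 42.0))
    hist = build_histogram(vol, full_mask(vol))
    assert (hist.counts > 0).sum() == 1
    assert hist.counts.sum() == 1000


def test_histogram_config_errors(rng):
    vol = make_volume(rng.normal(size=(5, 5, 5)))
    with pytest.raises(HistogramError):
        build_histogram(vol, full_mask(vol), n_bins=8)
    from lipoct.volume_io import TumorMask

    empty = TumorMask(np.zeros((5, 5, 5), bool), vol.meta)
    with pytest.raises(HistogramError):
        build_histogram(vol, empty)


# ---------------------------------------------------------------------------
# fit_background


@pytest.fixture(scope="module")
def normal_hist():
    rng = np.random.default_rng(1234)
    vol = make_volume(rng.normal(100.0, 5.0, size=(100, 100, 100)))
    return build_histogram(vol, full_mask(vol))


@pytest.mark.parametrize("route", [Route.IV, Route.ITU])
def test_fit_recovers_pure_normal(normal_hist, route):
    """Both percentile windows recover µ0 and σ0 from 1e6 normal voxels."""
    bg = fit_background(normal_hist, route)
    assert bg.mean == pytest.approx(100.0, abs=0.1)
    assert bg.sd == pytest.approx(5.0, abs=0.1)
    lo, hi = (5.0, 95.0) if route is Route.IV else (10.0, 50.0)
    assert (bg.window_lo_pct, bg.window_hi_pct) == (lo, hi)
    assert bg.route is route


def test_fit_agrees_with_grid_search_oracle(normal_hist):
    """Brute-force (µ, σ) grid search lands within one bin width of the fit."""
    bg = fit_background(normal_hist, Route.ITU)
    lo, hi = np.percentile(normal_hist.values, [10, 50])
    centers = normal_hist.bin_centers
    sel = (centers >= lo) & (centers <= hi)
    x, y = centers[sel], normal_hist.counts[sel].astype(float)
    mus = np.linspace(99.0, 101.0, 401)
    sds = np.linspace(3.0, 8.0, 501)
    best = (None, None, np.inf)
    for mu in mus:
        g = np.exp(-((x[None, :] - mu) ** 2) / (2 * sds[:, None] ** 2))
        amp = (y[None, :] * g).sum(1) / (g * g).sum(1)
        sse = ((y[None, :] - amp[:, None] * g) ** 2).sum(1)
        i = int(np.argmin(sse))
        if sse[i] < best[2]:
            best = (mu, sds[i], sse[i])
    w = normal_hist.bin_width
    assert abs(bg.mean - best[0]) <= w
    assert abs(bg.sd - best[1]) <= w


def test_fit_narrow_histogram_rejected():
    vol = make_volume(np.full((12, 12, 12), 5.0))
    hist = build_histogram(vol, full_mask(vol))
    with pytest.raises(HistogramError, match="occupied"):
        fit_background(hist, Route.IV)


# ---------------------------------------------------------------------------
# differential histogram limits


def _synthetic_hist(extra_bin=None, extra_count=0):
    """Noise-free Gaussian counts over 200 bins, optional spike above P99."""
    edges = np.linspace(0.0, 100.0, 201)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.round(gaussian_curve(centers, 2000.0, 50.0, 5.0)).astype(np.int64)
    if extra_bin is not None:
        counts[extra_bin] += extra_count
    values = np.repeat(centers, counts)
    return AttenuationHistogram(
        bin_edges=edges, counts=counts, n_voxels=int(counts.sum()), values=values
    )


def test_itu_lower_limit_is_fitted_mean():
    hist = _synthetic_hist()
    bg = fit_background(hist, Route.ITU)
    diff = differential_histogram(hist, bg, Route.ITU)
    assert diff.lower_limit == bg.mean
    assert diff.upper_limit == hist.max_value


def _floor_hist(extra_bin=None, extra_count=0):
    """Counts = floor(Gaussian curve): never exceed the exact background."""
    edges = np.linspace(0.0, 100.0, 201)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.floor(gaussian_curve(centers, 2000.0, 50.0, 5.0)).astype(np.int64)
    if extra_bin is not None:
        counts[extra_bin] += extra_count
    values = np.repeat(centers, counts)
    hist = AttenuationHistogram(
        bin_edges=edges, counts=counts, n_voxels=int(counts.sum()), values=values
    )
    bg = GaussianBackground(
        amplitude=2000.0, mean=50.0, sd=5.0,
        window_lo_pct=5.0, window_hi_pct=95.0, route=Route.IV, fit_rss=0.0,
    )
    return hist, bg


def test_iv_lower_limit_first_qualifying_bin():
    """Excess only above P99 → the limit is exactly that bin's center."""
    hist, bg = _floor_hist(extra_bin=160, extra_count=50)
    diff = differential_histogram(hist, bg, Route.IV)
    assert diff.lower_limit == pytest.approx(hist.bin_centers[160])


def test_iv_no_qualifying_bin_gives_zero_integrals():
    hist, bg = _floor_hist()
    diff = differential_histogram(hist, bg, Route.IV)
    assert diff.lower_limit is None
    meta_vol = make_volume(np.zeros((2, 2, 2)))
    assert estimate_volume_of_distribution(diff, meta_vol.meta) == 0.0
    assert estimate_iodine_mass(diff, bg, flat_calib(3.0), meta_vol.meta) == 0.0


def test_excess_clipped_nonnegative(normal_hist):
    bg = fit_background(normal_hist, Route.IV)
    diff = differential_histogram(normal_hist, bg, Route.IV)
    assert (diff.excess_counts >= 0).all()


# ---------------------------------------------------------------------------
# estimators on phantoms


def run_quant(volume, mask, route, rate, window=None):
    masked = apply_mask(volume, mask)
    hist = build_histogram(masked, mask)
    bg = fit_background(hist, route, window=window)
    diff = differential_histogram(hist, bg, route)
    vd = estimate_volume_of_distribution(diff, volume.meta)
    mass = estimate_iodine_mass(diff, bg, flat_calib(rate), volume.meta)
    return masked, hist, bg, diff, vd, mass


def test_mass_doubles_with_concentration():
    """The estimator is linear: doubling hotspot concentration doubles mass."""
    masses = []
    for c in (5.0, 10.0):
        spec = PhantomSpec(
            semi_axes=(1.5, 1.3, 1.2),
            voxel_size=33.0,
            background_sd=2.0,
            noise_sd=2.0,
            psf_sigma=0.0,
            hotspots=(HotspotSpec((0.0, 0.0, 0.4), 0.5, c),),
            seed=3,
        )
        volume, truth = generate_tumor_phantom(spec)
        *_, mass = run_quant(volume, truth.tumor_mask, Route.ITU, 20.0)
        masses.append(mass)
    assert masses[1] == pytest.approx(2 * masses[0], rel=0.02)


def test_vd_bounded_by_tumor_volume(small_hotspot_phantom):
    _, volume, truth = small_hotspot_phantom
    for route in (Route.IV, Route.ITU):
        *_, vd, _ = run_quant(volume, truth.tumor_mask, route, 20.0)
        assert 0.0 <= vd <= truth.tumor_mask.volume_mm3


def test_itu_estimates_at_least_iv(small_hotspot_phantom):
    """ITu integrates from µ0, a weakly larger range than the IV limit."""
    _, volume, truth = small_hotspot_phantom
    *_, vd_iv, mass_iv = run_quant(volume, truth.tumor_mask, Route.IV, 20.0)
    *_, vd_itu, mass_itu = run_quant(volume, truth.tumor_mask, Route.ITU, 20.0)
    assert vd_itu >= vd_iv
    assert mass_itu >= mass_iv


def test_classification_dice_and_consistency():
    """Thresholded liposome voxels overlap truth and track the histogram Vd.

    Hotspot contrast 8σ0 with the hotspot just under 1% of the tumor, so the
    IV limit falls in the thin background tail between the populations.
    """
    spec = PhantomSpec(
        semi_axes=(1.35, 1.25, 1.15),
        voxel_size=33.0,
        psf_sigma=0.0,
        hotspots=(HotspotSpec((0.0, 0.0, 0.0), 0.26, 2.4),),  # 48 units = 8σ0
        seed=19,
    )
    volume, truth = generate_tumor_phantom(spec)
    masked, hist, bg, diff, vd, _ = run_quant(
        volume, truth.tumor_mask, Route.IV, spec.attenuation_rate
    )
    lipo = classify_high_attenuation(masked, truth.tumor_mask, diff)
    inter = np.count_nonzero(lipo & truth.hotspot_mask)
    dice = 2 * inter / (np.count_nonzero(lipo) + np.count_nonzero(truth.hotspot_mask))
    assert dice >= 0.9
    # consistency (not identity): classified volume vs histogram-excess volume
    classified_vol = np.count_nonzero(lipo) * volume.meta.voxel_volume_mm3
    assert classified_vol == pytest.approx(vd, rel=0.10)


def test_classify_empty_when_limit_above_maximum(small_hotspot_phantom):
    _, volume, truth = small_hotspot_phantom
    masked, hist, bg, diff, *_ = run_quant(volume, truth.tumor_mask, Route.ITU, 20.0)
    diff.lower_limit = volume.values.max() + 1.0
    lipo = classify_high_attenuation(masked, truth.tumor_mask, diff)
    assert not lipo.any()
    diff.lower_limit = None
    assert not classify_high_attenuation(masked, truth.tumor_mask, diff).any()


# ---------------------------------------------------------------------------
# percent injected dose


def test_percent_injected_dose_identities():
    d = percent_injected_dose(2.0, 2.0, 1000.0)
    assert d.percent_injected_dose == 100.0
    assert d.percent_injected_dose_per_cm3 == pytest.approx(100.0)
    z = percent_injected_dose(0.0, 1.3875, 500.0)
    assert z.percent_injected_dose == 0.0
    assert z.percent_injected_dose_per_cm3 == 0.0
    with pytest.raises(InputError):
        percent_injected_dose(1.0, 0.0, 500.0)
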