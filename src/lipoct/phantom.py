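"""Digital tumor phantoms with an exact contrast-agent ground-truth ledger.

The generator emulates the statistical model the analysis assumes: an
ellipsoidal (optionally lobulated) tumor whose liposome-free tissue draws
attenuation from a Gaussian, plus sparse spherical "hotspots" whose
attenuation is raised in proportion to their iodine concentration through
the calibration slope.  Partial-volume blurring is emulated by a Gaussian
PSF applied to the whole field, and measurement noise is added inside the
tumor afterwards — blur is a deterministic optical/geometric effect,
noise is measurement error, so blur comes first.

Every phantom carries a :class:`PhantomTruth` ledger computed by voxel
counting on the pre-blur hotspot mask, including per-shell masses computed
with the exact same shell rules as :mod:`lipoct.depth_shells` (one shared
implementation, so conventions cannot drift).

Default parameters describe a desk-scale ex vivo scan: paper-grade
16.6144 µm isotropic voxels, a ~46 mm³ ellipsoidal tumor, background noise
of 5 % of the background level, and a one-voxel PSF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .depth_shells import SHELL_IDS, compute_depth_map, partition_shells
from .errors import GeometryError, InputError
from .volume_io import AttenuationVolume, TumorMask, VolumeMetadata

__all__ = [
    "HotspotSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_tumor_phantom",
    "generate_calibration_phantoms",
    "null_phantom_spec",
    "recovery_phantom_spec",
    "spec_to_dict",
    "spec_from_dict",
    "truth_to_dict",
]


@dataclass(frozen=True)
class HotspotSpec:
    """A spherical contrast-filled subregion.

    center:
        Tumor-local center ``(z, y, x)`` in mm, relative to the tumor
        centroid.
    radius:
        Sphere radius in mm.
    iodine_concentration:
        Iodine concentration inside the sphere in mg I/mL.
    """

    center: tuple[float, float, float]
    radius: float
    iodine_concentration: float

    def __post_init__(self):
        if self.radius <= 0:
            raise InputError(f"hotspot radius must be > 0, got {self.radius}")
        if self.iodine_concentration < 0:
            raise InputError("hotspot concentration must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for a digital tumor phantom.

    semi_axes:
        Ellipsoid semi-axes ``(z, y, x)`` in mm.
    voxel_size:
        Isotropic voxel size in µm.
    background_mean, background_sd:
        Gaussian attenuation of liposome-free tissue (arbitrary units).
    attenuation_rate:
        Attenuation units per (mg I/mL); the generator's counterpart of the
        calibration slope.
    hotspots:
        Spherical contrast regions; overlaps are allowed and their
        concentrations sum.
    psf_sigma:
        Gaussian PSF sigma in mm emulating partial-volume blur (0 = none).
    noise_sd:
        Additive post-blur measurement noise inside the tumor.
    outside_value:
        Constant attenuation outside the tumor, well separated from
        ``background_mean`` so segmentation is well-posed.
    lobulation_amplitude, lobulation_order:
        Optional low-order radial modulation of the ellipsoid surface:
        the surface radius is scaled by ``1 + A·cos(order·φ)`` with φ the
        azimuth in the (y, x) plane.
    seed:
        Seed for the random draws; identical seed ⇒ bit-identical output.
    """

    semi_axes: tuple[float, float, float] = (2.5, 2.2, 2.0)
    voxel_size: float = 16.6144
    background_mean: float = 100.0
    background_sd: float = 6.0
    attenuation_rate: float = 20.0
    hotspots: tuple[HotspotSpec, ...] = ()
    psf_sigma: float = 0.0166144
    noise_sd: float = 6.0
    outside_value: float = 0.0
    lobulation_amplitude: float = 0.0
    lobulation_order: int = 0
    margin_voxels: int = 4
    seed: int = 0

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise InputError("semi-axes must be > 0")
        if self.voxel_size <= 0:
            raise InputError("voxel_size must be > 0")
        if self.background_sd < 0 or self.noise_sd < 0:
            raise InputError("standard deviations must be >= 0")
        if self.attenuation_rate <= 0:
            raise InputError("attenuation_rate must be > 0")
        if self.psf_sigma < 0:
            raise InputError("psf_sigma must be >= 0")
        if not 0 <= self.lobulation_amplitude < 1:
            raise InputError("lobulation_amplitude must be in [0, 1)")
        object.__setattr__(self, "hotspots", tuple(self.hotspots))


@dataclass
class PhantomTruth:
    """Exact ground truth for one generated phantom.

    All quantities come from voxel counting on the pre-blur hotspot mask:
    ``total_iodine_mass`` (mg) is the per-voxel concentration sum times the
    voxel volume in mL; ``occupied_volume`` (mm³) counts hotspot voxels;
    per-shell entries use the depth-shell rules of
    :mod:`lipoct.depth_shells` applied to the analytic tumor mask.
    """

    tumor_mask: TumorMask
    hotspot_mask: np.ndarray
    total_iodine_mass: float
    occupied_volume: float
    per_shell_mass: dict[int, float]
    per_shell_occupied_volume: dict[int, float]


def _grid_coordinates(spec: PhantomSpec):
    """Voxel-center coordinates (mm) relative to the tumor centroid."""
    h = spec.voxel_size * 1e-3
    scale = 1.0 + spec.lobulation_amplitude
    half = [int(np.ceil(a * scale / h)) + spec.margin_voxels for a in spec.semi_axes]
    dims = tuple(2 * n + 1 for n in half)
    axes = [(np.arange(d) - n) * h for d, n in zip(dims, half)]
    return dims, axes


def _tumor_mask_grid(spec: PhantomSpec, axes) -> np.ndarray:
    z, y, x = np.meshgrid(*axes, indexing="ij", sparse=True)
    az, ay, ax = spec.semi_axes
    q = (z / az) ** 2 + (y / ay) ** 2 + (x / ax) ** 2
    if spec.lobulation_amplitude > 0 and spec.lobulation_order > 0:
        phi = np.arctan2(y, x)
        s = 1.0 + spec.lobulation_amplitude * np.cos(spec.lobulation_order * phi)
        return q <= s**2
    return q <= 1.0


def _check_hotspot_inside(spec: PhantomSpec, hs: HotspotSpec):
    # Conservative containment: the ellipsoid shrunk by the hotspot radius
    # (and by the worst-case lobulation) must contain the hotspot center.
    shrink = 1.0 - spec.lobulation_amplitude
    reduced = [a * shrink - hs.radius for a in spec.semi_axes]
    if any(r <= 0 for r in reduced):
        raise GeometryError(
            f"hotspot radius {hs.radius} mm does not fit inside semi-axes "
            f"{spec.semi_axes} mm"
        )
    q = sum((c / r) ** 2 for c, r in zip(hs.center, reduced))
    if q > 1.0:
        raise GeometryError(
            f"hotspot at {hs.center} mm (r={hs.radius} mm) extends outside the tumor"
        )


def _concentration_grid(spec: PhantomSpec, axes, dims) -> np.ndarray:
    """Per-voxel iodine concentration (mg/mL); overlapping hotspots sum."""
    conc = np.zeros(dims, dtype=float)
    h = spec.voxel_size * 1e-3
    for hs in spec.hotspots:
        _check_hotspot_inside(spec, hs)
        # restrict to the bounding box of the sphere for speed
        los, his, local = [], [], []
        for ax_coords, c in zip(axes, hs.center):
            lo = int(np.searchsorted(ax_coords, c - hs.radius - h))
            hi = int(np.searchsorted(ax_coords, c + hs.radius + h))
            los.append(lo)
            his.append(hi)
            local.append(ax_coords[lo:hi] - c)
        dz, dy, dx = np.meshgrid(*local, indexing="ij", sparse=True)
        # center-inclusion rule: a voxel belongs to the hotspot iff its
        # center lies within the sphere
        inside = dz**2 + dy**2 + dx**2 <= hs.radius**2
        conc[los[0]:his[0], los[1]:his[1], los[2]:his[2]][inside] += (
            hs.iodine_concentration
        )
    return conc


def _shell_truth(
    tumor: TumorMask, conc: np.ndarray, voxel_volume_ml: float, voxel_volume_mm3: float
) -> tuple[dict[int, float], dict[int, float]]:
    depth = compute_depth_map(tumor)
    part = partition_shells(depth, thickness=1.0)
    occupied = conc > 0
    mass = {}
    vol = {}
    for s in SHELL_IDS:
        in_shell = part.labels == s
        mass[s] = float(conc[in_shell].sum()) * voxel_volume_ml
        vol[s] = float(np.count_nonzero(occupied & in_shell)) * voxel_volume_mm3
    return mass, vol


def generate_tumor_phantom(
    spec: PhantomSpec, with_shell_truth: bool = True
) -> tuple[AttenuationVolume, PhantomTruth]:
    """Generate a synthetic tumor volume plus its ground-truth ledger.

    The voxel grid is sized to contain the tumor shape plus a margin of
    ``spec.margin_voxels`` voxels per side.  Inside-tumor voxels draw from
    ``Normal(background_mean, background_sd)``; each hotspot voxel's
    pre-noise value is raised by ``concentration × attenuation_rate``; the
    whole field is blurred with the PSF and noise is then added inside the
    tumor only.  Truth is computed on the pre-blur hotspot mask.

    Set ``with_shell_truth=False`` to skip the (comparatively costly)
    per-shell truth when only totals are needed; per-shell entries are then
    empty dicts.
    """
    dims, axes = _grid_coordinates(spec)
    meta = VolumeMetadata(voxel_size=spec.voxel_size, dims=dims)
    mask = _tumor_mask_grid(spec, axes)
    tumor = TumorMask(values=mask, meta=meta)
    conc = _concentration_grid(spec, axes, dims)
    if (conc[~mask] > 0).any():
        raise GeometryError("hotspot voxels fall outside the tumor mask")

    rng = np.random.default_rng(spec.seed)
    field = np.full(dims, spec.outside_value, dtype=float)
    n_inside = int(mask.sum())
    field[mask] = spec.background_mean + spec.background_sd * rng.standard_normal(
        n_inside
    )
    field += conc * spec.attenuation_rate
    if spec.psf_sigma > 0:
        sigma_vox = spec.psf_sigma / (spec.voxel_size * 1e-3)
        field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="nearest")
    if spec.noise_sd > 0:
        field[mask] += spec.noise_sd * rng.standard_normal(n_inside)

    v_ml = meta.voxel_volume_ml
    v_mm3 = meta.voxel_volume_mm3
    total_mass = float(conc.sum()) * v_ml
    occupied = float(np.count_nonzero(conc > 0)) * v_mm3
    if with_shell_truth:
        shell_mass, shell_vol = _shell_truth(tumor, conc, v_ml, v_mm3)
    else:
        shell_mass, shell_vol = {}, {}
    truth = PhantomTruth(
        tumor_mask=tumor,
        hotspot_mask=conc > 0,
        total_iodine_mass=total_mass,
        occupied_volume=occupied,
        per_shell_mass=shell_mass,
        per_shell_occupied_volume=shell_vol,
    )
    return AttenuationVolume(values=field, meta=meta), truth


def null_phantom_spec(seed: int) -> PhantomSpec:
    """Study conditions for the null calibration: a hotspot-free tumor.

    A small ellipsoid (~2.6 mm³) at the scanner's native 16.6144 µm
    resolution (grid ≈ 128³), default noise and PSF, no contrast agent.
    Any detected dose on such a phantom is a false positive of the
    analysis, so batteries of these phantoms calibrate the null.
    """
    return PhantomSpec(
        semi_axes=(0.95, 0.85, 0.78), voxel_size=16.6144, hotspots=(), seed=seed
    )


def recovery_phantom_spec(
    concentration: float, radius: float, seed: int = 0
) -> PhantomSpec:
    """Study conditions for the recovery battery: one sparse IV-like hotspot.

    The design is scale-invariant in the hotspot radius: the voxel size is
    ``radius / 25`` (so the one-voxel PSF is always 4 % of the radius) and
    the tumor semi-axes scale with the radius so the hotspot occupies
    ~0.3 % of the tumor volume — the sparse-accumulation regime the IV
    integration rule presumes (its lower limit is tied to the within-tumor
    99th percentile).  Concentration and radius are free.
    """
    s = radius / 0.3
    voxel_um = radius * 1000.0 / 25.0
    return PhantomSpec(
        semi_axes=(2.4 * s, 2.05 * s, 1.82 * s),
        voxel_size=voxel_um,
        hotspots=(HotspotSpec((0.0, 0.0, 0.0), radius, concentration),),
        psf_sigma=voxel_um * 1e-3,
        seed=seed,
    )


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-serializable form of a :class:`PhantomSpec`."""
    d = {
        "semi_axes": list(spec.semi_axes),
        "voxel_size": spec.voxel_size,
        "background_mean": spec.background_mean,
        "background_sd": spec.background_sd,
        "attenuation_rate": spec.attenuation_rate,
        "hotspots": [
            {
                "center": list(h.center),
                "radius": h.radius,
                "iodine_concentration": h.iodine_concentration,
            }
            for h in spec.hotspots
        ],
        "psf_sigma": spec.psf_sigma,
        "noise_sd": spec.noise_sd,
        "outside_value": spec.outside_value,
        "lobulation_amplitude": spec.lobulation_amplitude,
        "lobulation_order": spec.lobulation_order,
        "margin_voxels": spec.margin_voxels,
        "seed": spec.seed,
    }
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    """Inverse of :func:`spec_to_dict`; unknown keys are rejected."""
    d = dict(d)
    hotspots = tuple(
        HotspotSpec(
            center=tuple(h["center"]),
            radius=float(h["radius"]),
            iodine_concentration=float(h["iodine_concentration"]),
        )
        for h in d.pop("hotspots", [])
    )
    if "semi_axes" in d:
        d["semi_axes"] = tuple(float(a) for a in d["semi_axes"])
    known = set(PhantomSpec.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise InputError(f"unknown phantom spec keys: {sorted(unknown)}")
    return PhantomSpec(hotspots=hotspots, **d)


def truth_to_dict(truth: PhantomTruth) -> dict:
    """JSON-serializable summary of the truth ledger (grids omitted)."""
    return {
        "total_iodine_mass_mg": truth.total_iodine_mass,
        "occupied_volume_mm3": truth.occupied_volume,
        "tumor_volume_mm3": truth.tumor_mask.volume_mm3,
        "per_shell_mass_mg": {str(k): v for k, v in sorted(truth.per_shell_mass.items())},
        "per_shell_occupied_volume_mm3": {
            str(k): v for k, v in sorted(truth.per_shell_occupied_volume.items())
        },
    }


def generate_calibration_phantoms(
    concentrations: Sequence[float],
    base: PhantomSpec,
    roi_shape: tuple[int, int, int] = (24, 24, 24),
) -> list[tuple[AttenuationVolume, float]]:
    """Homogeneous calibration-standard volumes, one per concentration.

    Each volume draws every voxel from
    ``Normal(background_mean + c × attenuation_rate, background_sd)``,
    emulating a scanned tube of contrast solution at concentration ``c``.
    """
    concentrations = [float(c) for c in concentrations]
    if any(c < 0 for c in concentrations):
        raise InputError("calibration concentrations must be non-negative")
    rng = np.random.default_rng(base.seed)
    meta = VolumeMetadata(voxel_size=base.voxel_size, dims=roi_shape)
    out = []
    for c in concentrations:
        mean = base.background_mean + c * base.attenuation_rate
        values = mean + base.background_sd * rng.standard_normal(roi_shape)
        out.append((AttenuationVolume(values=values, meta=meta), c))
    return out
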