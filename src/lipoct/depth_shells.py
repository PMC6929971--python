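"""Depth-from-surface maps and concentric shell analysis of the tumor.

The tumor is partitioned by depth from its surface into three shells of
1 mm thickness (shell 1 at the periphery) plus a fourth shell holding
everything deeper than 3 mm — the core.  Per-shell liposome content is then
reported two ways: the share of total signal found in each shell, and the
occupancy, i.e. the percentage of each shell's own volume filled by
classified liposome voxels.  Occupancy normalizes for the fact that for a
convex tumor the peripheral shell is the largest, so raw per-shell signal
alone would overstate peripheral accumulation.

Depth is the exact Euclidean distance (in mm) from each tumor voxel center
to the nearest non-tumor voxel center.  Shell ``k`` covers depths in
``((k-1)·t, k·t]`` for ``k = 1..3`` and ``(3t, ∞)`` for ``k = 4`` —
half-open on the left, closed on the right, evaluated at voxel centers, so
counts are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, InputError, SegmentationError
from .volume_io import AttenuationVolume, TumorMask, VolumeMetadata

__all__ = [
    "DepthMap",
    "ShellPartition",
    "ShellQuant",
    "compute_depth_map",
    "partition_shells",
    "quantify_shells",
    "liposome_signal_grid",
    "export_depth_coded_labels",
    "SHELL_IDS",
]

logger = logging.getLogger(__name__)

SHELL_IDS = (1, 2, 3, 4)


@dataclass
class DepthMap:
    """Per-voxel depth from the tumor surface in mm; 0 outside the tumor."""

    values: np.ndarray
    meta: VolumeMetadata


@dataclass
class ShellPartition:
    """Shell labels 1..4 on the tumor grid (0 = non-tumor).

    ``shell_volumes`` maps each shell id to its volume in mm³ (voxel counts
    times voxel volume); empty shells are present with volume 0.
    """

    labels: np.ndarray
    thickness: float
    shell_volumes: dict[int, float]
    meta: VolumeMetadata


@dataclass
class ShellQuant:
    """Per-shell liposome quantification.

    fraction_of_signal:
        Percent of the total liposome signal found in each shell; sums to
        100 when any signal is present, all zeros otherwise.
    occupancy:
        Percent of each shell's volume occupied by classified liposome
        voxels (0..100).
    """

    fraction_of_signal: dict[int, float]
    occupancy: dict[int, float]


def compute_depth_map(mask: TumorMask) -> DepthMap:
    """Exact Euclidean distance transform of the tumor mask, in mm.

    Each tumor voxel gets the distance from its center to the nearest
    non-tumor voxel center; an isolated single-voxel tumor therefore has
    depth equal to one voxel size.
    """
    if mask.n_voxels == 0:
        raise SegmentationError("cannot compute a depth map for an empty mask")
    h = mask.meta.voxel_size_mm
    depth = ndimage.distance_transform_edt(mask.values, sampling=(h, h, h))
    return DepthMap(values=depth, meta=mask.meta)


def partition_shells(depth: DepthMap, thickness: float = 1.0) -> ShellPartition:
    """Label tumor voxels into three ``thickness``-mm shells plus a core.

    Shell k occupies depths ((k-1)·t, k·t] for k = 1..3; shell 4 is
    everything deeper than 3·t.  The labels partition the tumor exactly:
    shell volumes sum to the tumor volume in voxel units.
    """
    if thickness <= 0:
        raise InputError(f"shell thickness must be > 0 mm, got {thickness}")
    d = depth.values
    inside = d > 0
    labels = np.zeros(d.shape, dtype=np.uint8)
    # ceil(d/t) maps ((k-1)t, kt] -> k; cap at 4 for the core
    k = np.ceil(d[inside] / thickness).astype(np.int64)
    labels[inside] = np.minimum(k, 4).astype(np.uint8)
    vv = depth.meta.voxel_volume_mm3
    shell_volumes = {
        s: float(np.count_nonzero(labels == s)) * vv for s in SHELL_IDS
    }
    return ShellPartition(
        labels=labels, thickness=float(thickness), shell_volumes=shell_volumes,
        meta=depth.meta,
    )


def liposome_signal_grid(
    volume: AttenuationVolume,
    liposome_voxels: np.ndarray,
    mu0: float,
    attenuation_rate: float,
) -> np.ndarray:
    """Per-voxel iodine mass (mg) on classified liposome voxels.

    The voxel's attenuation excess over the background mean µ₀, divided by
    the calibration slope, gives a concentration (mg/mL); times the voxel
    volume in mL this is a mass.  Negative excess is clipped to zero.  This
    bridges the histogram-level dose estimate to voxel space so per-shell
    signal fractions are mass-weighted consistently with the total dose.
    """
    if attenuation_rate <= 0:
        raise InputError("attenuation_rate must be > 0")
    signal = np.zeros(volume.values.shape, dtype=float)
    lipo = np.asarray(liposome_voxels, dtype=bool)
    if lipo.shape != volume.values.shape:
        raise AlignmentError(
            f"liposome grid shape {lipo.shape} != volume shape {volume.values.shape}"
        )
    excess = np.clip(volume.values[lipo] - mu0, 0.0, None)
    signal[lipo] = excess / attenuation_rate * volume.meta.voxel_volume_ml
    return signal


def quantify_shells(
    partition: ShellPartition,
    liposome_voxels: np.ndarray,
    signal: np.ndarray | None = None,
) -> ShellQuant:
    """Quantify liposome signal per depth shell.

    Parameters
    ----------
    partition:
        Shell labeling of the tumor.
    liposome_voxels:
        Binary grid of classified high-attenuation (liposome) voxels.
    signal:
        Optional per-voxel signal grid (e.g. iodine mass) used to weight
        the per-shell fractions.  When omitted, fractions are voxel-count
        weighted (each liposome voxel counts equally).

    Empty shells report fraction 0 and occupancy 0; if there is no signal at
    all, fractions are returned all-zero with a logged note.
    """
    lipo = np.asarray(liposome_voxels, dtype=bool)
    if lipo.shape != partition.labels.shape:
        raise AlignmentError(
            f"liposome grid shape {lipo.shape} != labels shape {partition.labels.shape}"
        )
    if signal is None:
        signal = lipo.astype(float)
    else:
        signal = np.asarray(signal, dtype=float)
        if signal.shape != partition.labels.shape:
            raise AlignmentError("signal grid does not match partition geometry")
        if (signal < 0).any():
            raise InputError("signal grid must be non-negative")

    total = float(signal[partition.labels > 0].sum())
    vv = partition.meta.voxel_volume_mm3
    fractions: dict[int, float] = {}
    occupancy: dict[int, float] = {}
    if total == 0.0:
        logger.info("quantify_shells: total signal is zero; fractions undefined, "
                    "reporting all-zero")
    for s in SHELL_IDS:
        in_shell = partition.labels == s
        if total > 0:
            fractions[s] = 100.0 * float(signal[in_shell].sum()) / total
        else:
            fractions[s] = 0.0
        shell_vol = partition.shell_volumes[s]
        if shell_vol > 0:
            occ_vol = float(np.count_nonzero(lipo & in_shell)) * vv
            occupancy[s] = 100.0 * occ_vol / shell_vol
        else:
            occupancy[s] = 0.0
    return ShellQuant(fraction_of_signal=fractions, occupancy=occupancy)


def export_depth_coded_labels(
    partition: ShellPartition, liposome_voxels: np.ndarray
) -> AttenuationVolume:
    """Encode liposome voxels by their shell for external 3D viewing.

    Label scheme: 0 = non-tumor, k = plain tumor voxel in shell k,
    10+k = liposome voxel in shell k.  Returned as an
    :class:`AttenuationVolume` so it can be written via :mod:`volume_io`.
    """
    lipo = np.asarray(liposome_voxels, dtype=bool)
    if lipo.shape != partition.labels.shape:
        raise AlignmentError("liposome grid does not match partition geometry")
    out = partition.labels.astype(np.int16)
    out[lipo & (partition.labels > 0)] += 10
    return AttenuationVolume(values=out, meta=partition.meta)
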