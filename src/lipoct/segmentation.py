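"""Tumor segmentation and masking of an ex vivo volume.

An excised tumor sits in a plastic tube surrounded by air, so it is
high-contrast against the rest of the field of view and a global bimodal
threshold suffices.  The mask is the largest 26-connected component of
above-threshold voxels, morphologically closed with a 2-voxel-radius ball
and hole-filled.  A manual threshold override keeps results auditable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .errors import AlignmentError, SegmentationError
from .volume_io import AttenuationVolume, TumorMask

__all__ = ["segment_tumor", "apply_mask"]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_tumor(
    volume: AttenuationVolume, threshold: float | None = None
) -> TumorMask:
    """Segment the tumor as the dominant above-threshold component.

    Parameters
    ----------
    volume:
        Reconstructed attenuation volume containing two separable
        populations (air/container vs tissue).
    threshold:
        Optional explicit attenuation threshold.  Defaults to an automatic
        bimodal (Otsu) split of the full-volume histogram.

    Warns if the foreground touches all six faces of the grid — an ex vivo
    tumor should be interior to the field of view.
    """
    values = volume.values
    if np.ptp(values) == 0:
        raise SegmentationError(
            "volume is constant-valued; no bimodal split exists"
        )
    if threshold is None:
        threshold = float(threshold_otsu(values))
    fg = values > threshold
    if not fg.any():
        raise SegmentationError(
            f"no voxels above threshold {threshold}; segmentation is empty"
        )
    labels, n = ndimage.label(fg, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        fg = labels == keep
    fg = ndimage.binary_closing(fg, structure=ball(2))
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        raise SegmentationError("segmentation empty after morphology")

    faces = (
        fg[0].any(), fg[-1].any(),
        fg[:, 0].any(), fg[:, -1].any(),
        fg[:, :, 0].any(), fg[:, :, -1].any(),
    )
    if all(faces):
        warnings.warn(
            "segmented tumor touches all six faces of the field of view",
            stacklevel=2,
        )
    return TumorMask(values=fg, meta=volume.meta)


def apply_mask(
    volume: AttenuationVolume, mask: TumorMask, sentinel: float | None = None
) -> AttenuationVolume:
    """Set non-tumor voxels to a sentinel value excluded from histograms.

    The sentinel defaults to ``min(in-mask) - (in-mask range + 1)``, far
    below any tissue value, so a re-segmentation of the masked volume
    reproduces the same mask.  Masked (tumor) voxels are untouched.
    """
    if mask.values.shape != volume.values.shape:
        raise AlignmentError(
            f"mask shape {mask.values.shape} != volume shape {volume.values.shape}"
        )
    if mask.n_voxels == 0:
        raise SegmentationError("cannot apply an empty mask")
    inside = volume.values[mask.values]
    if sentinel is None:
        span = float(np.ptp(inside))
        sentinel = float(inside.min()) - (span + 1.0)
    out = np.where(mask.values, volume.values, sentinel)
    return AttenuationVolume(values=out, meta=volume.meta)
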