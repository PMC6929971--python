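import numpy as np
import pytest

from lipoct.phantom import HotspotSpec, PhantomSpec, generate_tumor_phantom
from lipoct.volume_io import AttenuationVolume, TumorMask, VolumeMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def make_volume(values, voxel_size_um=50.0):
    values = np.asarray(values, dtype=float)
    meta = VolumeMetadata(voxel_size=voxel_size_um, dims=values.shape)
    return AttenuationVolume(values=values, meta=meta)


def full_mask(volume):
    return TumorMask(
        values=np.ones(volume.values.shape, dtype=bool), meta=volume.meta
    )


@pytest.fixture
def small_hotspot_phantom():
    """A fast ~100³ phantom with one well-separated hotspot (default noise)."""
    spec = PhantomSpec(
        semi_axes=(1.5, 1.3, 1.2),
        voxel_size=33.0,
        hotspots=(HotspotSpec((0.0, 0.0, 0.5), 0.35, 10.0),),
        psf_sigma=0.0,
        seed=7,
    )
    volume, truth = generate_tumor_phantom(spec)
    return spec, volume, truth


@pytest.fixture
def noiseless_hotspot_phantom():
    """Deterministic phantom: no noise, no blur — closed-form oracle territory."""
    spec = PhantomSpec(
        semi_axes=(1.4, 1.2, 1.1),
        voxel_size=50.0,
        background_sd=0.0,
        noise_sd=0.0,
        psf_sigma=0.0,
        hotspots=(HotspotSpec((0.0, 0.0, 0.0), 0.5, 10.0),),
        seed=5,
    )
    volume, truth = generate_tumor_phantom(spec)
    return spec, volume, truth
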