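import numpy as np
import pytest

from tspmap import (Ellipsoid, LesionModel, PhantomSpec, generate_phantom,
                    make_brain_mask)

# A compact stroke phantom: same physiology as the full-size default
# (lesion delayed 5 s, dispersed x2, amplitude x0.7, 2% noise) on a grid
# small enough that every test stays fast.  The lesion ellipsoid is sized
# to exceed the 1 cm^3 minimum-cluster default.
SMALL_SHAPE = (32, 32, 10)
SMALL_LESION = Ellipsoid(center=(22.0, 14.0, 4.5), semiaxes=(6.0, 6.0, 3.0))


def small_spec(**overrides) -> PhantomSpec:
    kwargs = dict(shape=SMALL_SHAPE, n_dynamics=80,
                  lesion=LesionModel(geometry=SMALL_LESION), rng_seed=7)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def stroke_phantom():
    """(series, ground_truth, brain_mask) for the default stroke physiology."""
    series, gt = generate_phantom(small_spec())
    mask = make_brain_mask(series, ventricle_mask=gt.ventricle_mask)
    return series, gt, mask


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, lesion-free phantom: every brain voxel an affine copy of
    one template curve."""
    series, gt = generate_phantom(small_spec(lesion=None, noise_sigma=0.0, rng_seed=3))
    mask = make_brain_mask(series, ventricle_mask=gt.ventricle_mask)
    return series, gt, mask


@pytest.fixture(scope="session")
def tia_phantom():
    """Lesion-free phantom with the default 2% noise (imaging-negative case)."""
    series, gt = generate_phantom(small_spec(lesion=None, rng_seed=11))
    mask = make_brain_mask(series, ventricle_mask=gt.ventricle_mask)
    return series, gt, mask


def random_series_and_mask(rng, shape=(6, 6, 4), nt=20):
    """A random small 4D series (positive signal) with a full-grid mask,
    for brute-force oracle comparisons."""
    from tspmap import BrainMask, DynamicSeries
    data = 100.0 + 10.0 * rng.standard_normal(shape + (nt,))
    series = DynamicSeries(data=data, tr=1.0, te=24.0, voxel_dims=(1.0, 1.0, 1.0))
    mask = BrainMask(mask=np.ones(shape, dtype=bool))
    return series, mask
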