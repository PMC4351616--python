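import numpy as np
import pytest
from scipy import ndimage

from gmac import LabelVolume, build_shell
from gmac.phantom import BundleSpec, PhantomSpec, make_phantom
from gmac.tracking import TrackingParams, track_all_rois


def random_tissue_volumes(rng: np.random.Generator, shape=(20, 20, 20), n_rois=4):
    """Random smooth parcellation + disjoint white matter mask.

    A smoothed noise field is split into gray (top quartile) and white
    (middle band); gray voxels are labeled by nearest of ``n_rois`` random
    centers, giving compact-ish random regions.
    """
    field = ndimage.gaussian_filter(rng.normal(size=shape), 2.0)
    q40, q75 = np.quantile(field, [0.40, 0.75])
    gray = field > q75
    white = (field <= q75) & (field > q40)
    centers = rng.uniform(0, np.array(shape) - 1, size=(n_rois, 3))
    idx = np.argwhere(gray)
    if len(idx) == 0:
        gray[tuple(s // 2 for s in shape)] = True
        idx = np.argwhere(gray)
    nearest = np.argmin(
        np.linalg.norm(idx[:, None, :] - centers[None, :, :], axis=2), axis=1
    )
    parc = np.zeros(shape, dtype=np.int32)
    parc[tuple(idx.T)] = nearest + 1
    wm = np.zeros(shape, dtype=np.int32)
    wm[white] = 1
    affine = np.eye(4)
    return LabelVolume(parc, affine), LabelVolume(wm, affine)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def thin_bundle_phantom():
    """Two gray balls joined by a single-column straight bundle along x."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 24),
        n_rois=2,
        roi_radius=3.0,
        roi_centers=[(5.0, 11.0, 11.0), (17.0, 11.0, 11.0)],
        bundle_specs=[BundleSpec(1, 2, radius_mm=0.6)],
        seed=0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def asym_bundle_phantom():
    """Three gray balls, two single-column bundles of unequal length from
    ROI 1, so visitation path lengths (and hence distance-corrected counts)
    differ between bundles."""
    spec = PhantomSpec(
        grid_shape=(28, 28, 24),
        n_rois=3,
        roi_radius=3.0,
        roi_centers=[(5.0, 11.0, 11.0), (21.0, 11.0, 11.0), (5.0, 21.0, 11.0)],
        bundle_specs=[BundleSpec(1, 2, radius_mm=0.6), BundleSpec(1, 3, radius_mm=0.6)],
        seed=0,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def thin_bundle_tracked(thin_bundle_phantom):
    """Shell + integer-count visitation maps for the thin-bundle phantom."""
    ph = thin_bundle_phantom
    shell = build_shell(ph.parcellation, ph.wm_mask, seed=11)
    params = TrackingParams(n_samples=100, distance_correction=False,
                            dispersion_deg=0.0, seed=13)
    maps = track_all_rois(ph.field, shell, params)
    return ph, shell, maps, params
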