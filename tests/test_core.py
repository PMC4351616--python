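import numpy as np
import pytest
from scipy.stats import rankdata

from gmac import (
    AffineTransform,
    LabelVolume,
    ScalarVolume,
    build_shell,
    compute_gmac,
    gmac_to_standard_space,
    log_transform,
    normalize_within_subject,
    resample_scalar,
    sum_nonlocal_counts,
)
from gmac.shell import shell_from_label_volume
from gmac.tracking import VisitationMap

from conftest import random_tissue_volumes


def naive_nonlocal_sum(shell, maps):
    """Triple-loop reference: per shell voxel, sum counts of all maps whose
    seed region differs from the voxel's assignment."""
    out = np.zeros(shell.grid_shape)
    for vox in shell.voxels:
        own = shell.roi_assignment[vox]
        out[vox] = sum(m.counts[vox] for m in maps if m.seed_roi != own)
    return out


def make_shell_and_maps(rng, n_rois=5, shape=(12, 12, 12)):
    parc, wm = random_tissue_volumes(rng, shape=shape, n_rois=n_rois)
    shell = build_shell(parc, wm, seed=int(rng.integers(1 << 30)))
    maps = [VisitationMap(lab, rng.poisson(3.0, size=shape).astype(float), np.eye(4))
            for lab in range(1, n_rois + 1)]
    return shell, maps


class TestSumNonlocalCounts:
    def test_three_roi_voxel_sums_exclude_own(self):
        vol = np.zeros((3, 3, 3), dtype=np.int32)
        vol[1, 1, 1] = 1  # single shell voxel assigned ROI 1
        shell = shell_from_label_volume(LabelVolume(vol, np.eye(4)))
        counts = [5.0, 2.0, 7.0]
        maps = [VisitationMap(lab, np.full((3, 3, 3), c), np.eye(4))
                for lab, c in zip((1, 2, 3), counts)]
        f = sum_nonlocal_counts(shell, maps)
        assert f.data[1, 1, 1] == 9.0  # 2 + 7, own ROI 1 excluded

    def test_own_roi_only_visits_give_zero(self):
        vol = np.zeros((3, 3, 3), dtype=np.int32)
        vol[1, 1, 1] = 1
        shell = shell_from_label_volume(LabelVolume(vol, np.eye(4)))
        own = np.zeros((3, 3, 3))
        own[1, 1, 1] = 50.0
        maps = [VisitationMap(1, own, np.eye(4)),
                VisitationMap(2, np.zeros((3, 3, 3)), np.eye(4))]
        f = sum_nonlocal_counts(shell, maps)
        assert f.data[1, 1, 1] == 0.0

    def test_all_zero_maps_give_zero_volume(self, rng):
        shell, maps = make_shell_and_maps(rng)
        zero_maps = [VisitationMap(m.seed_roi, np.zeros(m.counts.shape), m.affine)
                     for m in maps]
        f = sum_nonlocal_counts(shell, zero_maps)
        assert (f.data == 0).all()

    def test_missing_map_rejected_by_label(self, rng):
        shell, maps = make_shell_and_maps(rng)
        present = sorted(int(l) for l in shell.labels())
        dropped = present[0]
        kept = [m for m in maps if m.seed_roi != dropped]
        with pytest.raises(ValueError, match=str(dropped)):
            sum_nonlocal_counts(shell, kept)

    @pytest.mark.parametrize("case_seed", range(5))
    def test_matches_naive_triple_loop_oracle(self, case_seed):
        rng = np.random.default_rng(5000 + case_seed)
        shell, maps = make_shell_and_maps(rng)
        assert len(shell) <= 500
        f = sum_nonlocal_counts(shell, maps)
        np.testing.assert_array_equal(f.data, naive_nonlocal_sum(shell, maps))
        assert (f.data[~(shell_volume_mask(shell))] == 0).all()


def shell_volume_mask(shell):
    mask = np.zeros(shell.grid_shape, dtype=bool)
    for vox in shell.voxels:
        mask[vox] = True
    return mask


class TestLogTransform:
    def test_analytic_values(self):
        data = np.zeros((2, 2, 2))
        data[0, 0, 0] = np.e - 1
        out = log_transform(ScalarVolume(data, np.eye(4)))
        assert out.data[1, 1, 1] == 0.0
        np.testing.assert_allclose(out.data[0, 0, 0], 1.0)

    def test_monotone(self, rng):
        a = rng.uniform(0, 100, size=(4, 4, 4))
        out = log_transform(ScalarVolume(a, np.eye(4)))
        order = np.argsort(a.ravel())
        assert (np.diff(out.data.ravel()[order]) >= 0).all()

    def test_negative_rejected(self):
        data = np.full((2, 2, 2), -0.5)
        with pytest.raises(ValueError, match="negative"):
            log_transform(ScalarVolume(data, np.eye(4)))


def single_row_shell(values):
    """A shell of len(values) voxels along x, all assigned ROI 1, with
    raw counts given by ``values`` (ROI 2 exists so the sum is non-local)."""
    n = len(values)
    vol = np.zeros((n, 3, 3), dtype=np.int32)
    vol[:, 1, 1] = 1
    shell = shell_from_label_volume(LabelVolume(vol, np.eye(4)))
    f = np.zeros((n, 3, 3))
    f[:, 1, 1] = values
    return shell, ScalarVolume(f, np.eye(4))


class TestNormalization:
    def test_printed_formula_values(self):
        shell, f_vol = single_row_shell([1.0, 2.0, 10.0])
        gmac = normalize_within_subject(log_transform(f_vol), shell, f_vol)
        expected_mid = (np.log(3) - np.log(2)) / (np.log(11) - np.log(2))
        np.testing.assert_allclose(gmac.F[1, 1, 1], expected_mid)
        np.testing.assert_allclose(expected_mid, 0.2376, atol=5e-4)
        assert gmac.F[0, 1, 1] == 0.0  # attains the minimum
        assert gmac.F[2, 1, 1] == 1.0  # attains the maximum

    def test_zero_voxels_get_zero_and_are_flagged(self):
        shell, f_vol = single_row_shell([0.0, 2.0, 10.0])
        gmac = normalize_within_subject(log_transform(f_vol), shell, f_vol)
        assert gmac.F[0, 1, 1] == 0.0
        assert gmac.zero_mask[0, 1, 1]
        assert not gmac.zero_mask[1, 1, 1]

    def test_equal_counts_get_equal_F(self):
        shell, f_vol = single_row_shell([3.0, 7.0, 3.0, 12.0])
        gmac = normalize_within_subject(log_transform(f_vol), shell, f_vol)
        assert gmac.F[0, 1, 1] == gmac.F[2, 1, 1]

    def test_all_zero_rejected(self):
        shell, f_vol = single_row_shell([0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="no connectivity signal"):
            normalize_within_subject(log_transform(f_vol), shell, f_vol)

    def test_degenerate_range_rejected(self):
        shell, f_vol = single_row_shell([4.0, 4.0, 4.0])
        with pytest.raises(ValueError, match="degenerate normalization range"):
            normalize_within_subject(log_transform(f_vol), shell, f_vol)

    def test_F_bounds_and_extremes_on_random_counts(self, rng):
        values = rng.poisson(4.0, size=50).astype(float)
        values[values.argmax()] += 2  # ensure a unique, nonzero max
        shell, f_vol = single_row_shell(values)
        gmac = normalize_within_subject(log_transform(f_vol), shell, f_vol)
        on = values >= 1
        F_shell = gmac.F[:, 1, 1]
        assert (F_shell[on] >= 0).all() and (F_shell[on] <= 1).all()
        assert F_shell[values.argmax()] == 1.0
        assert (F_shell[~on] == 0).all()

    def test_log_base_invariance(self, rng):
        # computing f' in any base changes f'(min/max) by the same factor,
        # which cancels in the min-max ratio
        values = rng.poisson(5.0, size=20).astype(float) + 1
        shell, f_vol = single_row_shell(values)
        natural = normalize_within_subject(log_transform(f_vol), shell, f_vol)
        base10 = ScalarVolume(np.log10(f_vol.data + 1), f_vol.affine)
        alt = normalize_within_subject(base10, shell, f_vol)
        np.testing.assert_allclose(alt.F, natural.F)

    def test_rescaling_counts_preserves_ranking(self, rng):
        values = rng.poisson(4.0, size=40).astype(float)
        values[:2] = [1.0, 30.0]  # guarantee two distinct nonzero values
        shell, f_vol = single_row_shell(values)
        scaled = ScalarVolume(f_vol.data * 7.0, f_vol.affine)
        g1 = normalize_within_subject(log_transform(f_vol), shell, f_vol)
        g2 = normalize_within_subject(log_transform(scaled), shell, scaled)
        a, b = g1.F[:, 1, 1], g2.F[:, 1, 1]
        assert not np.allclose(a, b)  # F itself changes...
        np.testing.assert_array_equal(rankdata(a), rankdata(b))  # ...ranks do not

    def test_F_monotone_in_f(self, rng):
        values = rng.poisson(6.0, size=60).astype(float)
        values[:2] = [1.0, 40.0]
        shell, f_vol = single_row_shell(values)
        gmac = normalize_within_subject(log_transform(f_vol), shell, f_vol)
        F_shell = gmac.F[:, 1, 1]
        order = np.argsort(values)
        assert (np.diff(F_shell[order]) >= -1e-12).all()


class TestStandardSpace:
    def _gmac(self, rng):
        values = rng.poisson(4.0, size=30).astype(float)
        values[:2] = [1.0, 20.0]
        shell, f_vol = single_row_shell(values)
        return normalize_within_subject(log_transform(f_vol), shell, f_vol)

    def test_identity_transforms_preserve_map(self, rng):
        gmac = self._gmac(rng)
        ident = AffineTransform.identity()
        out = gmac_to_standard_space(gmac, ident, ident, gmac.F.shape, gmac.affine)
        np.testing.assert_allclose(out.data, gmac.F)

    def test_composition_close_to_sequential(self, rng):
        # a smooth map, so the one-interpolation error bound is meaningful
        from dataclasses import replace
        from scipy import ndimage

        gmac = self._gmac(rng)
        smooth = ndimage.gaussian_filter(rng.normal(size=(12, 12, 12)), 2.0)
        smooth = (smooth - smooth.min()) / np.ptp(smooth)
        gmac = replace(gmac, F=smooth, f=np.zeros_like(smooth),
                       f_prime=np.zeros_like(smooth),
                       zero_mask=np.zeros_like(smooth, dtype=bool))
        m1 = np.eye(4); m1[:3, 3] = [0.3, -0.2, 0.1]
        m2 = np.eye(4); m2[:3, 3] = [-0.1, 0.25, 0.2]
        x1, x2 = AffineTransform(m1), AffineTransform(m2)
        composed = gmac_to_standard_space(gmac, x1, x2, gmac.F.shape, gmac.affine)
        step1 = resample_scalar(ScalarVolume(gmac.F, gmac.affine), x1, gmac.F.shape, gmac.affine)
        step2 = resample_scalar(step1, x2, gmac.F.shape, gmac.affine)
        # double interpolation smooths; agreement within a loose tolerance
        # away from the volume border
        diff = np.abs(composed.data - step2.data)[1:-1, 1:-1, 1:-1]
        assert diff.max() < 0.05
        assert np.mean(diff) < 0.01

    def test_zero_map_stays_zero(self, rng):
        gmac = self._gmac(rng)
        gmac.F[:] = 0.0
        ident = AffineTransform.identity()
        out = gmac_to_standard_space(gmac, ident, ident, gmac.F.shape, gmac.affine)
        assert (out.data == 0).all()


class TestPhantomRecovery:
    def test_measured_support_is_exactly_the_bundle_shell_crossing(self, thin_bundle_tracked):
        ph, shell, maps, params = thin_bundle_tracked
        f = sum_nonlocal_counts(shell, maps)
        bundle_shell = {tuple(v) for v in np.argwhere(ph.bundle_masks[0])} & set(shell.voxels)
        assert {tuple(v) for v in np.argwhere(f.data > 0)} == bundle_shell
        np.testing.assert_array_equal(f.data[f.data > 0], params.n_samples)

    def test_full_gmac_on_asymmetric_phantom(self, asym_bundle_phantom):
        from gmac.tracking import TrackingParams, track_all_rois

        ph = asym_bundle_phantom
        shell = build_shell(ph.parcellation, ph.wm_mask, seed=2)
        params = TrackingParams(n_samples=50, dispersion_deg=0.0,
                                distance_correction=True, seed=4)
        maps = track_all_rois(ph.field, shell, params)
        gmac = compute_gmac(shell, maps)
        measured = {tuple(v) for v in np.argwhere(gmac.f > 0)}
        expected = set()
        for bundle in ph.bundle_masks:
            expected |= {tuple(v) for v in np.argwhere(bundle)} & set(shell.voxels)
        assert measured == expected
        # normalized values: 1 at the long bundle's entries, 0 at the short
        # bundle's (the measured minimum), zero-flag only off the bundles
        vals = sorted({round(float(gmac.F[v]), 10) for v in measured})
        assert vals == [0.0, 1.0]
        assert not any(gmac.zero_mask[v] for v in measured)
        off = set(shell.voxels) - measured
        assert all(gmac.zero_mask[v] and gmac.F[v] == 0.0 for v in off)
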