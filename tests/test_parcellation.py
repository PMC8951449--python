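"""Winner-take-all parcellation: partial correlation, windowed variant,
group maps, Dice similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cstcnet as c
from cstcnet.parcellation import WTAMap, _partial_coeffs
from cstcnet.series import Series4D


def residual_corr_oracle(x, signals):
    """Partial correlation by explicit pseudoinverse regression of both
    variables on the covariates, then plain correlation of residuals."""
    t = x.shape[0]
    out = np.empty((x.shape[1], 5))
    for ci in range(5):
        z = np.column_stack([np.ones(t), np.delete(signals, ci, axis=1)])
        proj = z @ np.linalg.pinv(z)
        rx = x - proj @ x
        ry = signals[:, ci] - proj @ signals[:, ci]
        for v in range(x.shape[1]):
            out[v, ci] = np.corrcoef(rx[:, v], ry)[0, 1]
    return out


class TestParcelMeanSignals:
    def test_matches_brute_force_mean(self, hc_voxel_cohort):
        cfg, subjects, clean, truth, atlas = hc_voxel_cohort
        series = clean[0]
        sig = c.parcel_mean_signals(series, atlas)
        for lab in range(1, 6):
            vox = atlas.cortical_labels == lab
            voxels = series.data[vox].astype(np.float64)
            oracle = np.stack(
                [voxels[:, t].sum() / voxels.shape[0] for t in range(series.n_timepoints)]
            )
            np.testing.assert_allclose(sig.matrix[:, lab - 1], oracle, atol=1e-12)

    def test_identical_voxels_give_member_series(self):
        atlas, _ = c.make_toy_atlas((16, 16, 12))
        rng = np.random.default_rng(0)
        data = np.zeros((*atlas.shape, 30))
        base = rng.standard_normal(30)
        for lab in range(1, 6):
            data[atlas.cortical_labels == lab] = base * lab
        series = Series4D(data, 2.0)
        sig = c.parcel_mean_signals(series, atlas)
        np.testing.assert_allclose(sig.matrix[:, 2], base * 3, atol=1e-12)

    def test_opposite_voxels_cancel(self):
        atlas, _ = c.make_toy_atlas((16, 16, 12))
        data = np.zeros((*atlas.shape, 20))
        vox = np.argwhere(atlas.cortical_labels == 1)
        rng = np.random.default_rng(1)
        a = rng.standard_normal(20)
        half = len(vox) // 2
        for k, (i, j, z) in enumerate(vox):
            data[i, j, z] = a if k < half else -a
        if len(vox) % 2:
            data[tuple(vox[-1])] = 0.0
        series = Series4D(data, 2.0)
        sig = c.parcel_mean_signals(series, atlas)
        np.testing.assert_allclose(sig.matrix[:, 0], 0.0, atol=1e-12)


class TestVoxelPartialWTA:
    def test_matches_residual_correlation_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((60, 8))
        signals = rng.standard_normal((60, 5))
        got = _partial_coeffs(x, signals)
        np.testing.assert_allclose(got, residual_corr_oracle(x, signals), atol=1e-10)

    def test_planted_copy_recovers_label_with_unit_coefficient(self):
        rng = np.random.default_rng(3)
        signals, _ = np.linalg.qr(rng.standard_normal((80, 5)))
        x = signals[:, [1]].copy()  # exact copy of system 2
        coeffs = _partial_coeffs(x, signals)
        assert np.argmax(coeffs[0]) == 1
        assert coeffs[0, 1] == pytest.approx(1.0, abs=1e-8)

    def test_conditioning_removes_chained_correlation(self):
        """x = s1 + noise where s1 and s3 correlate: after conditioning on
        s1 (a covariate for system 3), partial r(x, s3) is ~0."""
        rng = np.random.default_rng(4)
        base = rng.standard_normal(500)
        signals = rng.standard_normal((500, 5)) * 0.5
        signals[:, 0] += base
        signals[:, 2] += base  # s1 and s3 share variance
        x = (signals[:, 0] + 0.1 * rng.standard_normal(500))[:, None]
        coeffs = _partial_coeffs(x, signals)
        assert abs(coeffs[0, 2]) < 0.1
        assert coeffs[0, 0] > 0.9

    def test_zero_variance_voxel_unassigned(self, hc_voxel_cohort):
        cfg, subjects, clean, truth, atlas = hc_voxel_cohort
        series = clean[0]
        data = series.data.copy()
        mask = atlas.thalamus
        vox = tuple(np.argwhere(mask)[0])
        data[vox] = 0.0
        sig = c.parcel_mean_signals(series, atlas)
        wta = c.voxel_partial_wta(Series4D(data, 2.0), mask, sig, "thalamus")
        assert wta.labels[0] == 0
        assert np.isnan(wta.coeffs[0]).all()
        assert (wta.labels[1:] > 0).all()

    def test_cohort_recovers_planted_labels(self, hc_voxel_cohort):
        cfg, subjects, clean, truth, atlas = hc_voxel_cohort
        for series in clean:
            sig = c.parcel_mean_signals(series, atlas)
            for structure in c.SUBCORTICAL_STRUCTURES:
                mask = atlas.structure_mask(structure)
                wta = c.voxel_partial_wta(series, mask, sig, structure)
                recovery = (wta.label_volume()[mask] == truth.voxel_labels[structure][mask]).mean()
                assert recovery >= 0.95

    def test_too_few_timepoints_rejected(self):
        rng = np.random.default_rng(0)
        atlas, _ = c.make_toy_atlas((16, 16, 12))
        series = Series4D(rng.standard_normal((*atlas.shape, 6)), 2.0)
        sig = c.ParcelSignals(rng.standard_normal((6, 5)))
        with pytest.raises(ValueError, match="timepoints"):
            c.voxel_partial_wta(series, atlas.thalamus, sig)


class TestWTAInvariance:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_labels_invariant_to_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        coeffs = rng.uniform(-1, 1, size=(30, 5))
        mask = np.ones((30, 1, 1), dtype=bool)
        a = WTAMap.from_coeffs("thalamus", mask, coeffs, "static")
        # strictly increasing map applied uniformly to each voxel's vector
        b = WTAMap.from_coeffs("thalamus", mask, np.tanh(2 * coeffs) + 0.1, "static")
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_tie_broken_to_lowest_label(self):
        coeffs = np.array([[0.5, 0.5, 0.1, 0.1, 0.1]])
        mask = np.ones((1, 1, 1), dtype=bool)
        m = WTAMap.from_coeffs("striatum", mask, coeffs, "static")
        assert m.labels[0] == 1


class TestWindowedWTA:
    def test_single_window_equals_static(self, hc_voxel_cohort):
        cfg, subjects, clean, truth, atlas = hc_voxel_cohort
        series = clean[0]
        sig = c.parcel_mean_signals(series, atlas)
        static = c.voxel_partial_wta(series, atlas.thalamus, sig, "thalamus")
        dyn = c.windowed_voxel_wta(
            series, atlas.thalamus, sig,
            window_tr=series.n_timepoints, step_tr=5, structure="thalamus",
        )
        np.testing.assert_allclose(dyn.coeffs, static.coeffs, atol=1e-12)
        np.testing.assert_array_equal(dyn.labels, static.labels)

    def test_window_larger_than_series_rejected(self, hc_voxel_cohort):
        cfg, subjects, clean, truth, atlas = hc_voxel_cohort
        series = clean[0]
        sig = c.parcel_mean_signals(series, atlas)
        with pytest.raises(ValueError):
            c.windowed_voxel_wta(series, atlas.thalamus, sig, window_tr=500)

    def test_stationary_dynamic_map_close_to_static(self, hc_voxel_cohort):
        """Stationary coupling: the window-averaged map agrees with the
        static map (Dice >= 0.9 per label)."""
        cfg, subjects, clean, truth, atlas = hc_voxel_cohort
        series = clean[0]
        sig = c.parcel_mean_signals(series, atlas)
        for structure in ("thalamus", "cerebellum"):
            mask = atlas.structure_mask(structure)
            static = c.voxel_partial_wta(series, mask, sig, structure)
            dyn = c.windowed_voxel_wta(series, mask, sig, structure=structure)
            for lab in range(1, 6):
                assert c.dice(static, dyn, lab) >= 0.9


class TestGroupWTA:
    def test_identical_maps_unchanged(self, hc_voxel_cohort):
        cfg, subjects, clean, truth, atlas = hc_voxel_cohort
        sig = c.parcel_mean_signals(clean[0], atlas)
        m = c.voxel_partial_wta(clean[0], atlas.striatum, sig, "striatum")
        g = c.group_wta([m, m, m])
        np.testing.assert_array_equal(g.labels, m.labels)
        np.testing.assert_allclose(g.coeffs, m.coeffs, atol=1e-12)

    def test_group_map_recovers_planted_labels(self, hc_voxel_cohort):
        cfg, subjects, clean, truth, atlas = hc_voxel_cohort
        for structure in c.SUBCORTICAL_STRUCTURES:
            mask = atlas.structure_mask(structure)
            maps = [
                c.voxel_partial_wta(s, mask, c.parcel_mean_signals(s, atlas), structure)
                for s in clean
            ]
            g = c.group_wta(maps)
            recovery = (g.label_volume()[mask] == truth.voxel_labels[structure][mask]).mean()
            assert recovery >= 0.99

    def test_winner_decided_by_mean_with_tie_rule(self):
        mask = np.ones((1, 1, 1), dtype=bool)
        a = WTAMap.from_coeffs("thalamus", mask, np.array([[0.8, -0.2, 0, 0, 0]]), "static")
        b = WTAMap.from_coeffs("thalamus", mask, np.array([[-0.8, 0.2, 0, 0, 0]]), "static")
        g = c.group_wta([a, b])
        # mean vector is [0, 0, 0, 0, 0]: all tied, lowest label wins
        assert g.labels[0] == 1

    def test_mixed_structures_rejected(self, hc_voxel_cohort):
        cfg, subjects, clean, truth, atlas = hc_voxel_cohort
        sig = c.parcel_mean_signals(clean[0], atlas)
        a = c.voxel_partial_wta(clean[0], atlas.striatum, sig, "striatum")
        b = c.voxel_partial_wta(clean[0], atlas.thalamus, sig, "thalamus")
        with pytest.raises(ValueError, match="structure"):
            c.group_wta([a, b])


def map_from_labels(labels, n=6):
    """WTAMap with prescribed labels on an n-voxel line."""
    coeffs = np.full((n, 5), -1.0)
    for v, lab in enumerate(labels):
        if lab > 0:
            coeffs[v, lab - 1] = 1.0
        else:
            coeffs[v] = np.nan
    return WTAMap.from_coeffs("thalamus", np.ones((n, 1, 1), dtype=bool), coeffs, "static")


class TestDice:
    def test_identical_maps_dice_one(self):
        m = map_from_labels([1, 1, 2, 2, 3, 3])
        for lab in (1, 2, 3):
            assert c.dice(m, m, lab) == 1.0

    def test_hand_computed_overlap(self):
        # A = {v0,v1,v2}, B = {v1,v2,v3} for label 1 -> 2*2/(3+3)
        a = map_from_labels([1, 1, 1, 2, 2, 2])
        b = map_from_labels([2, 1, 1, 1, 2, 2])
        assert c.dice(a, b, 1) == pytest.approx(2 * 2 / 6)

    def test_disjoint_supports_dice_zero(self):
        a = map_from_labels([1, 1, 2, 2, 2, 2])
        b = map_from_labels([2, 2, 1, 1, 1, 1])
        assert c.dice(a, b, 1) == 0.0

    def test_label_absent_from_both_errors(self):
        a = map_from_labels([1, 1, 1, 1, 1, 1])
        with pytest.raises(ValueError, match="undefined"):
            c.dice(a, a, 5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = map_from_labels(rng.integers(1, 4, size=6))
            b = map_from_labels(rng.integers(1, 4, size=6))
            for lab in (1, 2, 3):
                d1 = c.dice(a, b, lab)
                assert d1 == c.dice(b, a, lab)
                assert 0.0 <= d1 <= 1.0

    def test_unassigned_voxels_excluded(self):
        a = map_from_labels([1, 1, 0, 2, 2, 2])
        b = map_from_labels([1, 1, 1, 2, 2, 2])
        # voxel 2 unassigned in a: |A|=2, |B|=3, overlap 2
        assert c.dice(a, b, 1) == pytest.approx(2 * 2 / 5)


class TestDiceProfile:
    def test_profile_against_itself_standardizes_to_one(self):
        maps = {"thalamus": map_from_labels([1, 2, 3, 4, 5, 1])}
        ref = c.dice_profile(maps, maps)
        prof = c.dice_profile(maps, maps, reference=ref)
        assert (prof.table.standardized.dropna() == 1.0).all()

    def test_reference_division(self):
        static = {"thalamus": map_from_labels([1, 1, 2, 3, 4, 5])}
        dynamic = {"thalamus": map_from_labels([1, 2, 2, 3, 4, 5])}
        ref_tbl = c.dice_profile(static, static)  # all ones
        prof = c.dice_profile(static, dynamic, reference=ref_tbl)
        # label 1: dice = 2*1/(2+1) = 0.6667, reference 1.0
        assert prof.table.set_index("label").loc[1, "standardized"] == pytest.approx(2 / 3)

    def test_missing_labels_reported_absent(self):
        static = {"thalamus": map_from_labels([1, 1, 2, 2, 3, 3])}
        dynamic = {"thalamus": map_from_labels([1, 1, 2, 2, 3, 4])}
        prof = c.dice_profile(static, dynamic)
        tbl = prof.table.set_index("label")
        assert np.isnan(tbl.loc[4, "dice"])  # absent from static map
        assert np.isnan(tbl.loc[5, "dice"])  # absent from both
        assert tbl.loc[1, "dice"] == 1.0

    def test_zero_reference_cell_rejected(self):
        static = {"thalamus": map_from_labels([1, 1, 2, 2, 3, 3])}
        dynamic = {"thalamus": map_from_labels([2, 2, 1, 1, 3, 3])}
        ref = c.dice_profile(static, dynamic)  # label 1 dice = 0
        with pytest.raises(ValueError, match="reference"):
            c.dice_profile(static, dynamic, reference=ref)
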