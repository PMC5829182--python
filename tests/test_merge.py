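import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import linear_sum_assignment

from dwel import (compute_ndi, match_intersection, merge_intersection,
                  merge_union, shot_ndi, synthesize_missing_band)
from dwel.bispectral_merge import MergeStateError
from dwel.pointcloud_io import NIR, SWIR
from conftest import make_mono

rho = st.floats(min_value=0.0, max_value=5.0, allow_nan=False)


class TestComputeNdi:
    def test_leaf_reference_pair(self):
        assert compute_ndi(0.431, 0.239) == pytest.approx(0.287, abs=5e-4)

    def test_equal_bands_zero(self):
        for a in (0.1, 0.4, 2.0):
            assert compute_ndi(a, a) == 0.0

    def test_boundary_one(self):
        assert compute_ndi(0.5, 0.0) == 1.0

    def test_zero_denominator_is_sentinel_not_error(self):
        assert np.isnan(compute_ndi(0.0, 0.0))

    def test_negative_reflectance_rejected(self):
        with pytest.raises(ValueError):
            compute_ndi(-0.1, 0.2)

    @given(a=rho, b=rho)
    def test_antisymmetric_under_band_swap(self, a, b):
        x, y = compute_ndi(a, b), compute_ndi(b, a)
        if np.isnan(x):
            assert np.isnan(y)
        else:
            assert x == pytest.approx(-y, abs=1e-12)

    @given(a=rho, b=rho, c=st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_under_joint_scaling(self, a, b, c):
        x, y = compute_ndi(a, b), compute_ndi(c * a, c * b)
        if np.isnan(x):
            assert np.isnan(y)
        else:
            assert x == pytest.approx(y, abs=1e-9)


class TestSynthesizeMissingBand:
    def test_inverts_leaf_pair(self):
        ndi = compute_ndi(0.431, 0.239)
        assert synthesize_missing_band(0.431, NIR, ndi) == \
            pytest.approx(0.239, abs=1e-9)
        assert synthesize_missing_band(0.239, SWIR, ndi) == \
            pytest.approx(0.431, abs=1e-9)

    def test_zero_ndi_copies_band(self):
        assert synthesize_missing_band(0.37, NIR, 0.0) == pytest.approx(0.37)

    def test_limit_ndi_to_one(self):
        vals = [synthesize_missing_band(0.431, NIR, 1.0 - e)
                for e in (1e-2, 1e-4, 1e-6)]
        assert all(np.diff(vals) < 0) and vals[-1] < 1e-5

    def test_undefined_at_unit_ndi(self):
        assert np.isnan(synthesize_missing_band(0.4, SWIR, 1.0))
        assert np.isnan(synthesize_missing_band(0.4, NIR, -1.0))

    @given(r=st.floats(min_value=1e-3, max_value=5.0),
           ndi=st.floats(min_value=-0.99, max_value=0.99))
    def test_round_trip_reproduces_ndi(self, r, ndi):
        other = synthesize_missing_band(r, NIR, ndi)
        assert compute_ndi(r, other) == pytest.approx(ndi, abs=1e-12)


class TestShotNdi:
    def test_single_pair_leaf_values(self):
        assert shot_ndi([0.431], [0.239]) == pytest.approx(0.287, abs=5e-4)

    def test_mean_of_pairs_symmetry(self):
        assert shot_ndi([0.4, 0.2], [0.2, 0.4]) == pytest.approx(0.0, abs=1e-12)

    def test_equidistant_neighbours_average(self):
        assert shot_ndi(neighbour_ndis=[0.1, 0.3],
                        neighbour_distances=[0.004, 0.004]) == \
            pytest.approx(0.2, abs=1e-12)

    def test_no_information_gives_sentinel(self):
        assert np.isnan(shot_ndi())


class TestMatchIntersection:
    def test_identical_geometry_all_matched(self):
        nir = make_mono([5.0, 7.0, 9.0], [0, 1, 2], NIR, rho=[0.4, 0.4, 0.4])
        swir = make_mono([5.0, 7.0, 9.0], [0, 1, 2], SWIR, rho=[0.2, 0.2, 0.2])
        pairs, lone_n, lone_s = match_intersection(nir, swir, 0.1)
        assert len(pairs) == 3 and len(lone_n) == 0 and len(lone_s) == 0

    def test_forced_matching_in_one_shot(self):
        nir = make_mono([5.00, 9.00], [7, 7], NIR, rho=[0.4, 0.4])
        swir = make_mono([5.04], [7], SWIR, rho=[0.2])
        pairs, lone_n, lone_s = match_intersection(nir, swir, 0.10)
        assert len(pairs) == 1
        assert pairs["range"].iloc[0] == pytest.approx(5.00)
        assert len(lone_n) == 1 and lone_n["range"].iloc[0] == 9.00
        assert len(lone_s) == 0

    def test_uncalibrated_input_is_state_error(self):
        nir = make_mono([5.0], [0], NIR, intensity=[100.0])
        swir = make_mono([5.0], [0], SWIR, intensity=[80.0])
        with pytest.raises(MergeStateError):
            match_intersection(nir, swir, 0.1)

    def test_count_bookkeeping_identity(self, small_scan_sim):
        _, nir, swir = small_scan_sim
        pairs, lone_n, lone_s = match_intersection(nir, swir, 0.10)
        assert len(pairs) + len(lone_n) == len(nir)
        assert len(pairs) + len(lone_s) == len(swir)

    def test_permutation_invariance(self, small_scan_sim):
        _, nir, swir = small_scan_sim
        rng = np.random.default_rng(0)
        nir2 = nir.sample(frac=1.0, random_state=1).reset_index(drop=True)
        swir2 = swir.sample(frac=1.0, random_state=2).reset_index(drop=True)
        a, _, _ = match_intersection(nir, swir, 0.10)
        b, _, _ = match_intersection(nir2, swir2, 0.10)
        key = ["shot_number", "range", "rho_nir", "rho_swir"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True)[key],
            b.sort_values(key).reset_index(drop=True)[key])

    def test_greedy_equals_optimal_assignment_oracle(self, small_scan_sim):
        """Shot-wise greedy matching attains the optimal pair count."""
        _, nir, swir = small_scan_sim
        tol = 0.10
        pairs, _, _ = match_intersection(nir, swir, tol)
        greedy_counts = pairs.groupby("shot_number").size()
        total_opt = 0
        for shot, gn in nir.groupby("shot_number"):
            gs = swir[swir["shot_number"] == shot]
            if not len(gs):
                continue
            d = np.abs(gn["range"].to_numpy()[:, None]
                       - gs["range"].to_numpy()[None, :])
            big = 1e6
            cost = np.where(d <= tol, d, big)
            ri, ci = linear_sum_assignment(cost)
            n_opt = int(np.sum(cost[ri, ci] < big))
            total_opt += n_opt
            assert greedy_counts.get(shot, 0) == n_opt
        assert len(pairs) == total_opt

    def test_dropout_free_matched_count_equals_shotwise_minimum(self):
        """With no dropouts, every shot matches min(n_nir, n_swir) pairs."""
        rng = np.random.default_rng(42)
        nir_parts, swir_parts = [], []
        for shot in range(1000):
            k = rng.integers(1, 4)
            base = np.sort(rng.uniform(2, 60, k))
            # returns within a shot are >= 0.5 m apart (multi-return spacing)
            base = base + np.arange(k) * 1.0
            nir_parts.append((base, np.full(k, shot)))
            keep = rng.uniform(size=k) < 1.0  # dropout-free
            swir_parts.append((base[keep] + rng.normal(0, 0.01, keep.sum()),
                               np.full(int(keep.sum()), shot)))
        nir = make_mono(np.concatenate([p[0] for p in nir_parts]),
                        np.concatenate([p[1] for p in nir_parts]), NIR,
                        rho=0.4 * np.ones(sum(len(p[0]) for p in nir_parts)))
        swir = make_mono(np.concatenate([p[0] for p in swir_parts]),
                         np.concatenate([p[1] for p in swir_parts]), SWIR,
                         rho=0.2 * np.ones(sum(len(p[0]) for p in swir_parts)))
        pairs, lone_n, lone_s = match_intersection(nir, swir, 0.10)
        expected = sum(min(len(p[0]), len(q[0]))
                       for p, q in zip(nir_parts, swir_parts))
        assert len(pairs) == expected


class TestMergeUnion:
    def test_dropout_free_union_equals_intersection(self):
        nir = make_mono([5.0, 7.0], [0, 1], NIR, rho=[0.4, 0.4])
        swir = make_mono([5.0, 7.0], [0, 1], SWIR, rho=[0.2, 0.2])
        uni = merge_union(nir, swir)
        inter = merge_intersection(nir, swir)
        assert len(uni) == len(inter)
        assert (uni["source"] == "matched").all()

    def test_union_superset_with_exact_counts(self, small_scan_sim):
        _, nir, swir = small_scan_sim
        pairs, lone_n, lone_s = match_intersection(nir, swir, 0.10)
        uni = merge_union(nir, swir, angular_step_mrad=4.0)
        n_synth = (uni["source"] != "matched").sum()
        assert len(uni) == len(pairs) + n_synth
        assert n_synth <= len(lone_n) + len(lone_s)
        # matched subset identical to intersection result
        key = ["shot_number", "range"]
        um = uni[uni["source"] == "matched"].sort_values(key).reset_index(drop=True)
        pm = pairs.sort_values(key).reset_index(drop=True)
        np.testing.assert_allclose(um["rho_nir"], pm["rho_nir"])
        np.testing.assert_allclose(um["rho_swir"], pm["rho_swir"])

    def test_all_points_satisfy_ndi_invariant(self, small_scan_sim):
        _, nir, swir = small_scan_sim
        uni = merge_union(nir, swir, angular_step_mrad=4.0)
        s = uni["rho_nir"] + uni["rho_swir"]
        ok = s > 0
        np.testing.assert_allclose(
            uni.loc[ok, "ndi"],
            (uni.loc[ok, "rho_nir"] - uni.loc[ok, "rho_swir"]) / s[ok],
            atol=1e-9)
        assert uni["ndi"].dropna().between(-1, 1).all()

    def test_isolated_leftover_without_neighbours_dropped(self):
        # shot 5 has a NIR-only return and no shot anywhere has pairs
        nir = make_mono([5.0], [5], NIR, rho=[0.4])
        swir = make_mono([], [], SWIR, rho=[])
        uni = merge_union(nir, swir)
        assert len(uni) == 0
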