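"""Profile referencing, dG_par / dG_trans extraction, partition conversions."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

import mempart as mp
from mempart.exceptions import ParameterError, StateError

RT = mp.rt(310.15)


def profile(z, g, **kw):
    return mp.PMFProfile(z=np.asarray(z, float), g=np.asarray(g, float), **kw)


class TestSetReference:
    def test_subtracts_value_at_reference(self):
        p = mp.set_reference(profile([3.8, 3.9, 4.0], [5, 7, 9]), 4.0)
        np.testing.assert_allclose(p.g, [-4, -2, 0])
        assert p.reference_z == 4.0

    def test_idempotent(self):
        p = mp.set_reference(profile([3.8, 3.9, 4.0], [5, 7, 9]), 4.0)
        q = mp.set_reference(p, 4.0)
        np.testing.assert_array_equal(p.g, q.g)

    def test_nearest_point_rule(self):
        p = mp.set_reference(profile([3.8, 3.9, 4.0], [5, 7, 9]), 3.96)
        np.testing.assert_allclose(p.g, [-4, -2, 0])   # 4.0 is nearest to 3.96

    def test_reference_outside_span_rejected(self):
        with pytest.raises(ParameterError):
            mp.set_reference(profile([0, 1], [0, 1]), 5.0)


class TestAsymmetry:
    def test_even_profile_scores_zero(self):
        z = np.array([-1.5, -1.0, -0.5, 0.5, 1.0, 1.5])
        assert mp.asymmetry_score(profile(z, z ** 2)) == pytest.approx(0.0)

    def test_odd_profile_hand_value(self):
        assert mp.asymmetry_score(profile([-1, 1], [-1, 1])) == pytest.approx(2.0)

    def test_additive_constant_invariance(self):
        z = np.array([-2, -1, 1, 2], float)
        g = np.array([3.0, 1.0, 2.0, 5.0])
        assert mp.asymmetry_score(profile(z, g)) == pytest.approx(
            mp.asymmetry_score(profile(z, g + 11.0)))

    def test_one_sided_profile_rejected(self):
        with pytest.raises(ParameterError):
            mp.asymmetry_score(profile([0.5, 1.0], [1.0, 2.0]))


class TestDeltaGPar:
    @pytest.mark.parametrize("minimum", [-23.16, -6.36])
    def test_minimum_is_reported_relative_to_bulk(self, minimum):
        z = np.array([-4.0, -1.2, 0.0, 4.0])
        g = np.array([0.0, minimum, 20.0, 0.0])
        p = mp.set_reference(profile(z, g), 4.0)
        dg, z_min = mp.delta_g_par(p)
        assert dg == pytest.approx(minimum)
        assert z_min == pytest.approx(-1.2)

    def test_monotone_nonnegative_profile_gives_zero(self):
        p = mp.set_reference(profile([3.0, 3.5, 4.0], [4.0, 2.0, 0.0]), 4.0)
        dg, z_min = mp.delta_g_par(p)
        assert dg == 0.0
        assert z_min == 4.0

    def test_unreferenced_profile_rejected(self):
        with pytest.raises(StateError):
            mp.delta_g_par(profile([0, 1], [1, 2]))

    def test_reference_must_be_in_bulk(self):
        p = mp.set_reference(profile([-1, 0, 1], [1.0, 0.0, 1.0]), 0.0)
        with pytest.raises(StateError):
            mp.delta_g_par(p)

    def test_degenerate_minima_pick_largest_abs_z(self):
        z = np.array([-4.0, -1.2, 0.5, 1.2, 4.0])
        g = np.array([0.0, -5.0, 3.0, -5.0, 0.0])
        p = mp.set_reference(profile(z, g), 4.0)
        _, z_min = mp.delta_g_par(p)
        assert z_min in (-1.2, 1.2) and abs(z_min) == 1.2


class TestDeltaGTransDirect:
    def test_headline_differences(self):
        p = mp.set_reference(
            profile([-4, 0, 1.2, 4], [0.0, 22.27, -6.36, 0.0]), 4.0)
        assert mp.delta_g_trans_direct(p) == pytest.approx(28.63)
        q = mp.set_reference(
            profile([-4, 0, 1.2, 4], [0.0, 30.18, -5.0, 0.0]), 4.0)
        assert mp.delta_g_trans_direct(q) == pytest.approx(35.18)

    def test_constant_profile_gives_zero(self):
        p = mp.set_reference(profile([3, 4], [0.0, 0.0]), 4.0)
        assert mp.delta_g_trans_direct(p) == 0.0


class TestDeltaGTransExtrapolated:
    def one_sided_toy(self):
        z = [0.1, 0.3, 0.5, 0.7, 0.9, 1.2, 3.0, 4.0]
        g = [30.0, 30.0, 28.0, 24.0, 20.0, -5.0, 0.0, 0.0]
        return mp.set_reference(profile(z, g), 4.0)

    def test_collinear_worked_example(self):
        """3rd-5th closest points (0.5, 28), (0.7, 24), (0.9, 20) lie on
        g = 38 - 20 z; intercept 38, minimum -5 -> 43."""
        value, diag = mp.delta_g_trans_extrapolated(self.one_sided_toy())
        assert value == pytest.approx(43.0, abs=1e-9)
        side = diag.sides["positive"]
        assert side["slope"] == pytest.approx(-20.0, abs=1e-9)
        assert side["intercept"] == pytest.approx(38.0, abs=1e-9)
        np.testing.assert_allclose(side["z"], [0.5, 0.7, 0.9])

    def test_flat_plateau_reduces_to_direct_value(self):
        z = [0.1, 0.3, 0.5, 0.7, 0.9, 1.2, 4.0]
        g = [25.0, 25.0, 25.0, 25.0, 25.0, -5.0, 0.0]
        p = mp.set_reference(profile(z, g), 4.0)
        value, _ = mp.delta_g_trans_extrapolated(p)
        assert value == pytest.approx(mp.delta_g_trans_direct(p))

    def test_symmetric_profile_sides_agree(self):
        zp = np.array([0.1, 0.3, 0.5, 0.7, 0.9, 1.2, 4.0])
        g_half = np.array([30.0, 30.0, 28.0, 24.0, 20.0, -5.0, 0.0])
        z = np.concatenate([-zp[::-1], zp])
        g = np.concatenate([g_half[::-1], g_half])
        p = mp.set_reference(profile(z, g), 4.0)
        value, diag = mp.delta_g_trans_extrapolated(p)
        assert diag.sides["negative"]["intercept"] == pytest.approx(
            diag.sides["positive"]["intercept"])
        one_sided, _ = mp.delta_g_trans_extrapolated(
            mp.set_reference(profile(zp, g_half), 4.0))
        assert value == pytest.approx(one_sided)

    def test_too_few_points_rejected(self):
        p = mp.set_reference(profile([0.5, 1.0, 2.0, 4.0],
                                     [20.0, -5.0, 1.0, 0.0]), 4.0)
        with pytest.raises(ParameterError):
            mp.delta_g_trans_extrapolated(p)

    def test_extrapolation_raises_plateau_estimate(self, default_potential):
        """With a negative flank slope the intercept at z = 0 exceeds the
        plateau value, so the extrapolated barrier >= the direct midplane one."""
        prof = mp.generate_partition_profile(default_potential, n_slices=21,
                                             noise_sd=0.0,
                                             plateau_halfwidth=0.5)
        p = mp.pmf_from_partition(prof)
        p = mp.set_reference(p, p.z[-1])
        value, diag = mp.delta_g_trans_extrapolated(p)
        i0 = np.argmin(np.abs(p.z))
        assert all(s["slope"] * np.sign(np.mean(s["z"])) < 0
                   for s in diag.sides.values())
        assert value >= p.g[i0] - p.g.min() - 1e-9


class TestPartitionConversions:
    def test_ln_k_two_maps_to_minus_5p157(self):
        prof = mp.PartitionProfile(z=np.array([0.0]), ln_K=np.array([2.0]),
                                   temperature=310.15)
        p = mp.pmf_from_partition(prof)
        assert p.g[0] == pytest.approx(-2 * RT)          # -5.157 kJ/mol
        assert p.g[0] == pytest.approx(-5.157, abs=5e-4)

    def test_zero_ln_k_is_zero_free_energy(self):
        prof = mp.PartitionProfile(z=np.array([0.0, 1.0]),
                                   ln_K=np.array([0.0, 0.0]))
        np.testing.assert_array_equal(mp.pmf_from_partition(prof).g, 0.0)

    def test_well_depth_round_trip_value(self):
        prof = mp.PartitionProfile(z=np.array([1.2]),
                                   ln_K=np.array([10.0 / RT]),
                                   temperature=310.15)
        assert mp.pmf_from_partition(prof).g[0] == pytest.approx(-10.0)

    @given(hnp.arrays(np.float64, st.integers(2, 30),
                      elements=st.floats(-50, 50)))
    def test_round_trip_is_identity(self, g):
        z = np.arange(len(g), dtype=float)
        p = profile(z, g, temperature=310.15)
        back = mp.pmf_from_partition(mp.partition_from_pmf(p))
        assert np.max(np.abs(back.g - p.g)) < 1e-12
        np.testing.assert_array_equal(back.z, p.z)

    def test_partition_dg_par_matches_well_depth(self, default_potential):
        """Noiseless, plateau-free partition profile: dG_par equals the true
        well depth up to slice resolution."""
        prof = mp.generate_partition_profile(default_potential, n_slices=241,
                                             noise_sd=0.0,
                                             plateau_halfwidth=0.0,
                                             half_span=2.4)
        p = mp.pmf_from_partition(prof)
        p = mp.set_reference(p, p.z[0])
        dg, z_min = mp.delta_g_par(p, bulk_cutoff=2.0)
        assert dg == pytest.approx(-10.0, abs=0.1)
        assert abs(abs(z_min) - 1.2) < 0.05


class TestCombineReplicates:
    def summary(self, dg_par, dg_trans=30.0, method="direct_max"):
        return mp.FreeEnergySummary(dg_par=dg_par, dg_trans=dg_trans,
                                    trans_method=method, z_min=-1.2)

    def test_identical_replicates_have_zero_error(self):
        out = mp.combine_replicates([self.summary(-10.0)] * 3)
        assert out.dg_par_err == 0.0 and out.dg_trans_err == 0.0

    def test_three_values_standard_error(self):
        out = mp.combine_replicates([self.summary(v) for v in (1.0, 2.0, 3.0)])
        assert out.dg_par == pytest.approx(2.0)
        assert out.dg_par_err == pytest.approx(1.0 / np.sqrt(3.0))

    def test_two_values_standard_error(self):
        out = mp.combine_replicates([self.summary(4.0), self.summary(6.0)])
        assert out.dg_par == pytest.approx(5.0)
        assert out.dg_par_err == pytest.approx(1.0)

    def test_mixed_methods_rejected(self):
        with pytest.raises(ParameterError):
            mp.combine_replicates([self.summary(1.0),
                                   self.summary(2.0, method="extrapolated")])


def test_extrapolated_tracks_direct_across_panel(default_potential):
    """Across plateaued profiles of varying depth/barrier, extrapolated and
    direct-midplane barriers are strongly linearly related (r > 0.9)."""
    direct, extrap = [], []
    i = 0
    for depth in (5.0, 8.0, 11.0, 14.0):
        for barrier in (12.0, 18.0, 24.0, 30.0):
            pot = mp.make_model_pmf(well_depth=depth, barrier_height=barrier)
            prof = mp.generate_partition_profile(pot, n_slices=20,
                                                 noise_sd=0.3,
                                                 plateau_halfwidth=0.5,
                                                 seed=i)
            i += 1
            p = mp.pmf_from_partition(prof)
            p = mp.set_reference(p, p.z[-1])
            i0 = np.argmin(np.abs(p.z))
            direct.append(p.g[i0] - p.g.min())
            value, _ = mp.delta_g_trans_extrapolated(p)
            extrap.append(value)
    r = np.corrcoef(direct, extrap)[0, 1]
    assert r > 0.9


def test_gauge_invariance_of_downstream_quantities():
    z = np.array([-4.0, -1.2, 0.0, 1.2, 4.0])
    g = np.array([0.0, -8.0, 20.0, -8.0, 0.0])
    a = mp.set_reference(profile(z, g), 4.0)
    b = mp.set_reference(profile(z, g + 123.0), 4.0)
    assert mp.delta_g_par(a) == mp.delta_g_par(b)
    assert mp.delta_g_trans_direct(a) == mp.delta_g_trans_direct(b)
    assert mp.asymmetry_score(a) == mp.asymmetry_score(b)
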