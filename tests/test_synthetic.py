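"""Generators: sampler statistics, umbrella layouts, profiles, panels."""

import math

import numpy as np
import pandas as pd
import pytest

import mempart as mp
from mempart.exceptions import ParameterError

RT = mp.rt(310.15)


class TestSampler:
    @pytest.mark.parametrize("k, expected_sd", [
        (1500.0, math.sqrt(2.5787306 / 1500)),   # 0.0415 nm
        (200.0, math.sqrt(2.5787306 / 200)),     # 0.1136 nm
    ])
    def test_harmonic_sd_closed_form(self, flat_potential, k, expected_sd):
        """On a flat landscape the biased density is Gaussian with sd sqrt(RT/k)."""
        s = mp.sample_window(flat_potential, 0.0, k, 50_000, 310.15, seed=1,
                             thin=1)
        assert s.std() == pytest.approx(expected_sd, rel=0.03)

    def test_seeded_determinism(self, default_potential):
        a = mp.sample_window(default_potential, -1.2, 500.0, 2000, seed=7)
        b = mp.sample_window(default_potential, -1.2, 500.0, 2000, seed=7)
        np.testing.assert_array_equal(a, b)
        c = mp.sample_window(default_potential, -1.2, 500.0, 2000, seed=8)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("kwargs", [
        {"n": 0}, {"force_constant": 0.0}, {"force_constant": -5.0},
        {"temperature": 0.0}, {"temperature": -1.0},
    ])
    def test_invalid_parameters_rejected(self, default_potential, kwargs):
        args = {"n": 100, "force_constant": 500.0, "temperature": 310.15}
        args.update(kwargs)
        with pytest.raises(ParameterError):
            mp.sample_window(default_potential, 0.0, args["force_constant"],
                             args["n"], args["temperature"], seed=0)

    def test_boltzmann_consistency_near_unbiased(self):
        """With k ~ 0 in a confining box, -RT ln(histogram) recovers U(z)
        up to a constant (RMSE < 0.5 kJ/mol at n = 2e5)."""
        pot = mp.make_model_pmf(well_depth=5.0, barrier_height=5.0)
        s = mp.sample_window(pot, 0.0, 1e-6, 200_000, seed=11,
                             proposal_sd=0.5, thin=5, burn_in=2000,
                             z_bounds=(-2.5, 2.5))
        counts, edges = np.histogram(s, bins=np.arange(-2.5, 2.51, 0.1))
        centers = 0.5 * (edges[:-1] + edges[1:])
        occupied = counts > 0
        g = -RT * np.log(counts[occupied])
        true = pot(centers[occupied])
        g -= (g - true).mean()
        assert np.sqrt(np.mean((g - true) ** 2)) < 0.5


class TestUmbrellaLayout:
    def test_default_ladder_has_53_windows(self):
        layout = mp.UmbrellaLayout(z_start=-4.0, z_stop=1.2, spacing=0.1)
        centers = layout.window_centers()
        assert len(centers) == 53
        assert centers[0] == pytest.approx(-4.0)
        assert centers[-1] == pytest.approx(1.2)

    def test_small_ladder_enumeration(self):
        layout = mp.UmbrellaLayout(z_start=0.0, z_stop=0.2, spacing=0.1)
        np.testing.assert_allclose(layout.window_centers(), [0.0, 0.1, 0.2])

    def test_extra_windows_appended_with_own_force_constants(self):
        layout = mp.UmbrellaLayout(z_start=0.0, z_stop=0.2, spacing=0.1,
                                   extra_windows=((0.05, 1500.0),))
        np.testing.assert_allclose(layout.window_centers(), [0, 0.1, 0.2, 0.05])
        np.testing.assert_allclose(layout.window_force_constants(),
                                   [500, 500, 500, 1500])

    @pytest.mark.parametrize("kwargs", [
        {"spacing": 0.0}, {"spacing": -0.1}, {"z_start": 1.0, "z_stop": 0.0},
        {"force_constants": -200.0}, {"samples_per_window": 0},
        {"equilibration_fraction": 1.0},
    ])
    def test_invalid_layouts_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            mp.UmbrellaLayout(**kwargs)


class TestUmbrellaDataset:
    def test_one_window_per_center_and_metadata(self, default_potential):
        layout = mp.UmbrellaLayout(z_start=0.0, z_stop=0.3, spacing=0.1,
                                   samples_per_window=50)
        ens = mp.generate_umbrella_dataset(default_potential, layout, seed=0)
        assert len(ens.windows) == 4
        np.testing.assert_allclose(ens.centers, [0.0, 0.1, 0.2, 0.3])
        assert ens.temperature == 310.15
        assert all(w.samples.size == 50 for w in ens.windows)

    def test_seeded_reproducibility(self, default_potential):
        layout = mp.UmbrellaLayout(z_start=0.0, z_stop=0.2, spacing=0.1,
                                   samples_per_window=100)
        a = mp.generate_umbrella_dataset(default_potential, layout, seed=3)
        b = mp.generate_umbrella_dataset(default_potential, layout, seed=3)
        for wa, wb in zip(a.windows, b.windows):
            np.testing.assert_array_equal(wa.samples, wb.samples)

    def test_neighboring_windows_overlap(self, default_potential):
        """Adjacent 0.1 nm windows share occupied bins even at k = 1500."""
        layout = mp.UmbrellaLayout(z_start=-0.2, z_stop=0.3, spacing=0.1,
                                   force_constants=1500.0,
                                   samples_per_window=5000)
        ens = mp.generate_umbrella_dataset(default_potential, layout, seed=5,
                                           thin=2)
        hist = mp.histogram_windows(ens, bin_width=0.05)
        occ = hist.counts > 0
        for i in range(len(ens.windows) - 1):
            assert (occ[i] & occ[i + 1]).any()


class TestPartitionProfile:
    def test_ln_k_is_zero_in_bulk(self, default_potential):
        prof = mp.generate_partition_profile(default_potential, n_slices=21,
                                             noise_sd=0.0,
                                             plateau_halfwidth=0.0,
                                             half_span=4.0)
        assert prof.ln_K[0] == pytest.approx(0.0, abs=1e-4)
        assert prof.ln_K[-1] == pytest.approx(0.0, abs=1e-4)

    def test_plateau_flattens_profile_inside_halfwidth(self, default_potential):
        prof = mp.generate_partition_profile(default_potential, n_slices=21,
                                             noise_sd=0.0,
                                             plateau_halfwidth=0.4,
                                             half_span=2.0)
        i0 = np.argmin(np.abs(prof.z))
        ip = np.argmin(np.abs(prof.z - 0.4))
        assert prof.ln_K[i0] == pytest.approx(prof.ln_K[ip], abs=1e-12)

    def test_well_slice_matches_partition_coefficient(self):
        """At a slice where U = -10 kJ/mol, ln K = 10/RT = 3.878 at 310.15 K.
        A narrow barrier keeps the well value at exactly -10."""
        pot = mp.make_model_pmf(barrier_width=0.3)
        prof = mp.generate_partition_profile(pot, n_slices=5,
                                             noise_sd=0.0,
                                             plateau_halfwidth=0.0,
                                             half_span=2.4)
        i = np.argmin(np.abs(prof.z - 1.2))
        assert prof.z[i] == pytest.approx(1.2)
        assert prof.ln_K[i] == pytest.approx(10.0 / RT, abs=1e-3)

    def test_noise_is_seeded_and_scaled(self, default_potential):
        a = mp.generate_partition_profile(default_potential, noise_sd=1.0, seed=4)
        b = mp.generate_partition_profile(default_potential, noise_sd=1.0, seed=4)
        np.testing.assert_array_equal(a.ln_K, b.ln_K)

    def test_too_few_slices_rejected(self, default_potential):
        with pytest.raises(ParameterError):
            mp.generate_partition_profile(default_potential, n_slices=4)


class TestScreeningPanel:
    def test_noiseless_linear_model_arithmetic(self):
        """intercept 3, slope -1.5, offset 5: tail 12 plain -> -15; oxo -> -10."""
        panel, _ = mp.generate_screening_panel(noise_sd=0.0, seed=0)
        ahl = panel[panel.category == "AHL"].set_index(
            ["tail_carbons", "has_3oxo"])
        assert ahl.loc[(12, False), "dg_par"] == pytest.approx(-15.0)
        assert ahl.loc[(12, True), "dg_par"] == pytest.approx(-10.0)

    def test_matched_records_differ_by_exactly_the_offset(self):
        panel, _ = mp.generate_screening_panel(noise_sd=0.0, oxo_offset=5.0,
                                               seed=0)
        result = mp.oxo_offset(panel)
        np.testing.assert_allclose(result.pairs["offset"], 5.0)

    def test_weak_partitioners_have_larger_median_concentration(self):
        panel, act = mp.generate_screening_panel(seed=0)
        joined = act.merge(panel[["qsm_id", "dg_par"]], on="qsm_id")
        above = joined.loc[joined.dg_par > -10.0, "concentration_uM"].median()
        below = joined.loc[joined.dg_par <= -10.0, "concentration_uM"].median()
        assert above > below

    def test_noiseless_ols_recovers_slope_exactly(self):
        panel, _ = mp.generate_screening_panel(noise_sd=0.0, seed=0)
        sub = panel[(panel.category == "AHL") & (~panel.has_3oxo)]
        slope, intercept = np.polyfit(sub.tail_carbons, sub.dg_par, 1)
        residuals = sub.dg_par - (slope * sub.tail_carbons + intercept)
        assert slope == pytest.approx(-1.5, abs=1e-12)
        assert np.abs(residuals).max() < 1e-9

    def test_panel_is_seed_stable(self):
        a_panel, a_act = mp.generate_screening_panel(seed=12)
        b_panel, b_act = mp.generate_screening_panel(seed=12)
        pd.testing.assert_frame_equal(a_panel, b_panel)
        pd.testing.assert_frame_equal(a_act, b_act)

    def test_trend_direction_is_enforced(self):
        with pytest.raises(ParameterError):
            mp.generate_screening_panel(tail_slope=1.5)
        with pytest.raises(ParameterError):
            mp.generate_screening_panel(tail_slope=0.0)

    def test_record_validation(self):
        with pytest.raises(ParameterError):
            mp.QSMRecord("X1", "alkane", 4, False, "DOPC", -1.0, 5.0)
        with pytest.raises(ParameterError):
            mp.QSMRecord("X1", "AHL", 4, False, "DOPC", -1.0, -5.0)
        with pytest.raises(ParameterError):
            mp.ActivityRecord("X1", "EC50", "E_coli", -2.0)
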