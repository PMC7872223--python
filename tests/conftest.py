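import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mempart as mp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_potential() -> mp.ModelPotential:
    """Default landscape: 10 kJ/mol wells at +/-1.2 nm, 25 kJ/mol barrier."""
    return mp.make_model_pmf()


@pytest.fixture(scope="session")
def flat_potential() -> mp.ModelPotential:
    """Numerically flat landscape (negligible wells and barrier)."""
    return mp.make_model_pmf(well_depth=1e-12, barrier_height=1e-12)


@pytest.fixture(scope="session")
def recovered_profile(default_potential) -> tuple[mp.PMFProfile, mp.ModelPotential]:
    """One WHAM-recovered profile at moderate sampling, shared across tests."""
    layout = mp.UmbrellaLayout(samples_per_window=1500)
    ens = mp.generate_umbrella_dataset(default_potential, layout, seed=42)
    hist = mp.histogram_windows(ens, bin_width=0.05)
    bias = mp.harmonic_bias_matrix(ens.centers, ens.force_constants,
                                   hist.bin_centers)
    sol = mp.solve_wham(hist, bias)
    return sol.to_profile(reference_z=-4.0), default_potential


def reference_free_energy(potential, profile):
    """True potential evaluated on the profile grid, matched to its reference."""
    true = potential(profile.z)
    return true - potential(profile.reference_z)


@pytest.fixture(scope="session")
def default_panel():
    """Default noisy screening panel plus activity records (seed 0)."""
    return mp.generate_screening_panel(seed=0)
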