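"""Synthetic data with known ground truth for the whole pipeline.

Everything downstream (WHAM, feature extraction, screening, activity
association) is exercised on data generated here: biased window samples on
an analytic model landscape, slice-wise partition-coefficient profiles with
the characteristic midplane plateau of implicit-solvent membrane models, and
a screening panel of quorum-sensing modulators (QSMs) whose partition free
energy is a known linear function of tail length and head-group chemistry,
joined to activity records whose potency degrades above a partitioning
threshold.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, rt
from .exceptions import ParameterError
from .pmf import PartitionProfile
from .potential import ModelPotential, make_model_pmf  # noqa: F401  (re-export)
from .wham import BiasedEnsemble, Window

__all__ = [
    "UmbrellaLayout", "QSMRecord", "ActivityRecord",
    "make_model_pmf", "sample_window", "generate_umbrella_dataset",
    "generate_partition_profile", "generate_screening_panel",
    "CATEGORIES", "BILAYERS", "ASSAYS", "ORGANISMS",
    "PANEL_COLUMNS", "ACTIVITY_COLUMNS",
]

CATEGORIES = ("AHL", "AHT", "oxoC12_derivative", "misc")
BILAYERS = ("DOPC", "POPE_POPG")
ASSAYS = ("EC50", "IC50")
ORGANISMS = ("E_coli", "P_aeruginosa")

PANEL_COLUMNS = ["qsm_id", "category", "tail_carbons", "has_3oxo", "bilayer",
                 "dg_par", "dg_trans", "dg_par_err", "dg_trans_err"]
ACTIVITY_COLUMNS = ["qsm_id", "assay", "organism", "concentration_uM", "source"]


@dataclass(frozen=True)
class UmbrellaLayout:
    """Ladder of harmonic umbrella windows along the bilayer normal.

    Window centers are ``z_start + i * spacing`` up to ``z_stop`` inclusive
    (to within spacing/2).  ``force_constants`` is a scalar applied to every
    window or a sequence with one value per regular window.  ``extra_windows``
    optionally appends irregular (center, force_constant) pairs, emulating
    protocols that densify coverage in steep regions.
    """

    z_start: float = -4.0
    z_stop: float = 1.2
    spacing: float = 0.1
    force_constants: float | tuple[float, ...] = 500.0
    samples_per_window: int = 5000
    equilibration_fraction: float = 5.0 / 32.0
    extra_windows: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.spacing > 0:
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        if not self.z_start < self.z_stop:
            raise ParameterError("z_start must be < z_stop")
        if self.samples_per_window < 1:
            raise ParameterError("samples_per_window must be >= 1")
        if not 0 <= self.equilibration_fraction < 1:
            raise ParameterError("equilibration_fraction must be in [0, 1)")
        ks = np.atleast_1d(np.asarray(self.force_constants, float))
        if np.any(ks <= 0):
            raise ParameterError("all force constants must be positive")
        n = self.n_regular_windows
        if ks.size not in (1, n):
            raise ParameterError(
                f"force_constants has {ks.size} entries for {n} windows")
        for c, k in self.extra_windows:
            if not k > 0:
                raise ParameterError(f"extra window at {c} has force constant {k}")

    @property
    def n_regular_windows(self) -> int:
        return int(math.floor((self.z_stop - self.z_start) / self.spacing + 0.5)) + 1

    def window_centers(self) -> np.ndarray:
        base = self.z_start + self.spacing * np.arange(self.n_regular_windows)
        extras = np.array([c for c, _ in self.extra_windows], float)
        return np.concatenate([base, extras]) if extras.size else base

    def window_force_constants(self) -> np.ndarray:
        ks = np.atleast_1d(np.asarray(self.force_constants, float))
        base = np.full(self.n_regular_windows, ks[0]) if ks.size == 1 else ks.copy()
        extras = np.array([k for _, k in self.extra_windows], float)
        return np.concatenate([base, extras]) if extras.size else base


@dataclass(frozen=True)
class QSMRecord:
    """One screening-panel entry: descriptors plus free-energy features."""

    qsm_id: str
    category: str
    tail_carbons: int
    has_3oxo: bool
    bilayer: str
    dg_par: float
    dg_trans: float
    dg_par_err: float = 0.0
    dg_trans_err: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ParameterError(f"unknown category {self.category!r}; "
                                 f"expected one of {CATEGORIES}")
        if self.bilayer not in BILAYERS:
            raise ParameterError(f"unknown bilayer {self.bilayer!r}")
        if self.tail_carbons < 0:
            raise ParameterError("tail_carbons must be >= 0")
        if self.dg_trans < 0:
            raise ParameterError("dg_trans must be >= 0 (it is max - min)")
        if self.dg_par_err < 0 or self.dg_trans_err < 0:
            raise ParameterError("errors must be >= 0")


@dataclass(frozen=True)
class ActivityRecord:
    """One potency measurement (EC50 for activators, IC50 for inhibitors)."""

    qsm_id: str
    assay: str
    organism: str
    concentration_uM: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ParameterError(f"unknown assay {self.assay!r}")
        if self.organism not in ORGANISMS:
            raise ParameterError(f"unknown organism {self.organism!r}")
        if not self.concentration_uM > 0:
            raise ParameterError("concentration must be positive")


def sample_window(potential: ModelPotential,
                  center: float,
                  force_constant: float,
                  n: int,
                  temperature: float = DEFAULT_TEMPERATURE,
                  seed: int | np.random.SeedSequence | None = None,
                  *,
                  proposal_sd: float = 0.05,
                  burn_in: int = 500,
                  thin: int = 20,
                  z_bounds: tuple[float, float] | None = None,
                  z_init: float | None = None) -> np.ndarray:
    """Metropolis Monte Carlo samples of one biased umbrella window.

    Samples are distributed proportionally to
    ``exp(-[U(z) + k (z - center)^2 / 2] / RT)``.  A single particle takes
    Gaussian steps of sd ``proposal_sd`` (nm); ``burn_in`` initial steps are
    discarded so the returned chain starts equilibrated, and one sample is
    recorded every ``thin`` steps to reduce serial correlation (the
    Monte Carlo analogue of saving an MD trajectory frame every fixed number
    of integrator steps).  ``z_bounds`` optionally confines the walker by
    rejecting proposals outside the interval (used for near-unbiased
    sampling where the landscape alone does not confine).  Reproducible for
    a fixed seed.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if not force_constant > 0:
        raise ParameterError(f"force_constant must be positive, got {force_constant}")
    if not temperature > 0:
        raise ParameterError(f"temperature must be positive, got {temperature}")
    if not proposal_sd > 0:
        raise ParameterError("proposal_sd must be positive")
    if burn_in < 0:
        raise ParameterError("burn_in must be >= 0")
    if thin < 1:
        raise ParameterError("thin must be >= 1")

    rng = np.random.default_rng(seed)
    steps = burn_in + n * thin
    proposals = rng.normal(0.0, proposal_sd, steps)
    log_u = np.log1p(-rng.random(steps))        # log of Uniform(0,1], no log(0)
    lo, hi = (-math.inf, math.inf) if z_bounds is None else map(float, z_bounds)
    beta = 1.0 / rt(temperature)
    energy = potential.energy
    half_k = 0.5 * force_constant
    z = float(center if z_init is None else z_init)
    z = min(max(z, lo), hi)
    e = energy(z) + half_k * (z - center) ** 2
    out = np.empty(n)
    j = 0
    for i in range(steps):
        zn = z + proposals[i]
        if lo <= zn <= hi:
            en = energy(zn) + half_k * (zn - center) ** 2
            if en <= e or beta * (e - en) >= log_u[i]:
                z, e = zn, en
        if i >= burn_in and (i - burn_in) % thin == thin - 1:
            out[j] = z
            j += 1
    return out


def generate_umbrella_dataset(potential: ModelPotential,
                              layout: UmbrellaLayout,
                              temperature: float = DEFAULT_TEMPERATURE,
                              seed: int | None = None,
                              *,
                              proposal_sd: float = 0.05,
                              burn_in: int = 500,
                              thin: int = 20) -> BiasedEnsemble:
    """Sample every window of ``layout`` independently on ``potential``.

    Each window gets its own child random stream derived from ``seed``, so
    the full ensemble is reproducible while windows remain independent.  All
    generated samples are stored; the MD-style equilibration discard
    (``layout.equilibration_fraction``) is applied downstream by the block
    analysis.
    """
    centers = layout.window_centers()
    ks = layout.window_force_constants()
    children = np.random.SeedSequence(seed).spawn(len(centers))
    windows = tuple(
        Window(center=float(c), force_constant=float(k),
               samples=sample_window(potential, float(c), float(k),
                                     layout.samples_per_window, temperature,
                                     seed=child, proposal_sd=proposal_sd,
                                     burn_in=burn_in, thin=thin))
        for c, k, child in zip(centers, ks, children))
    return BiasedEnsemble(windows=windows, temperature=temperature)


def generate_partition_profile(potential: ModelPotential,
                               n_slices: int = 20,
                               temperature: float = DEFAULT_TEMPERATURE,
                               noise_sd: float = 0.0,
                               plateau_halfwidth: float = 0.5,
                               seed: int | None = None,
                               *,
                               half_span: float = 2.0) -> PartitionProfile:
    """Slice-wise ln K_{w->m}(z) profile emulating implicit-solvent output.

    Slice centers are ``n_slices`` evenly spaced points on
    [-half_span, half_span] (20 slices over +/-2 nm gives ~0.2 nm spacing,
    the convention for spanning a membrane).  The underlying PMF is the model
    potential flattened to its value at |z| = ``plateau_halfwidth`` for
    |z| < ``plateau_halfwidth`` — the characteristic midplane plateau of
    implicit-solvent profiles that cannot capture bilayer deformation —
    converted by ln K(z) = -PMF(z)/RT, plus independent Gaussian noise of
    sd ``noise_sd``/RT on each slice.
    """
    if n_slices < 5:
        raise ParameterError(f"n_slices must be >= 5, got {n_slices}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if plateau_halfwidth < 0:
        raise ParameterError("plateau_halfwidth must be >= 0")
    if not half_span > 0:
        raise ParameterError("half_span must be positive")
    kt = rt(temperature)
    z = np.linspace(-half_span, half_span, n_slices)
    g = np.asarray(potential(z), float)
    if plateau_halfwidth > 0:
        g = np.where(np.abs(z) < plateau_halfwidth,
                     potential.energy(plateau_halfwidth), g)
    ln_k = -g / kt
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ln_k = ln_k + rng.normal(0.0, noise_sd / kt, n_slices)
    return PartitionProfile(z=z, ln_K=ln_k, temperature=temperature)


# Tail-carbon schedules per category: AHL/AHT cycle oxo / non-oxo pairs over
# even tail lengths; the oxo-C12 derivative family shares one tail; misc are
# short-tailed molecules without the 3-oxo motif.
_CATEGORY_CODE = {"AHL": "L", "AHT": "T", "oxoC12_derivative": "F", "misc": "M"}


def _descriptors(category: str, i: int) -> tuple[int, bool]:
    if category in ("AHL", "AHT"):
        return 4 + 2 * (i // 2), bool(i % 2)
    if category == "oxoC12_derivative":
        return 12, True
    return 2 + (i % 6), False


def generate_screening_panel(n_per_category: int = 10,
                             tail_slope: float = -1.5,
                             oxo_offset: float = 5.0,
                             potency_threshold: float = -10.0,
                             noise_sd: float = 1.0,
                             seed: int | None = None,
                             *,
                             intercept: float = 3.0,
                             bilayers: tuple[str, ...] = ("DOPC",),
                             trans_intercept: float = 28.0,
                             trans_slope: float = 0.5,
                             activity_intercept: float = 0.0,
                             activity_slope: float = 0.15,
                             activity_noise_sd: float = 0.35,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screening panel plus matched activity records with known structure.

    The partition free energy follows the linear model

        dg_par = intercept + tail_slope * tail_carbons
                 + oxo_offset * [has_3oxo] + Normal(0, noise_sd),

    the translocation free energy co-varies positively with dg_par
    (``trans_intercept + trans_slope * (dg_par - potency_threshold)``,
    clipped at 0), and potency follows the documented monotone rule

        log10(concentration_uM) = activity_intercept
            + activity_slope * max(0, dg_par - potency_threshold)
            + Normal(0, activity_noise_sd),

    so molecules partitioning more weakly than the threshold have larger
    (worse) EC50/IC50 concentrations in the median.  Setting
    ``activity_slope = 0`` severs the link (for null calibration).

    Returns ``(panel, activity)`` DataFrames with columns ``PANEL_COLUMNS``
    and ``ACTIVITY_COLUMNS``.
    """
    if n_per_category < 1:
        raise ParameterError("n_per_category must be >= 1")
    if not tail_slope < 0:
        raise ParameterError(
            f"tail_slope must be negative (longer tails partition more "
            f"strongly), got {tail_slope}")
    if oxo_offset < 0:
        raise ParameterError("oxo_offset must be >= 0")
    if noise_sd < 0 or activity_noise_sd < 0:
        raise ParameterError("noise sds must be >= 0")
    if activity_slope < 0:
        raise ParameterError("activity_slope must be >= 0")
    for b in bilayers:
        if b not in BILAYERS:
            raise ParameterError(f"unknown bilayer {b!r}")

    rng = np.random.default_rng(seed)
    panel_rows: list[QSMRecord] = []
    activity_rows: list[ActivityRecord] = []
    mol_index = 0
    for ci, category in enumerate(CATEGORIES):
        for i in range(n_per_category):
            tail, oxo = _descriptors(category, i)
            qsm_id = f"{_CATEGORY_CODE[category]}{i + 1:02d}"
            dg_par_by_bilayer = {}
            for bilayer in bilayers:
                dg_par = (intercept + tail_slope * tail + oxo_offset * oxo
                          + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
                dg_trans = max(0.0, trans_intercept
                               + trans_slope * (dg_par - potency_threshold)
                               + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0))
                panel_rows.append(QSMRecord(
                    qsm_id=qsm_id, category=category, tail_carbons=tail,
                    has_3oxo=oxo, bilayer=bilayer,
                    dg_par=dg_par, dg_trans=dg_trans,
                    dg_par_err=abs(rng.normal(0.8, 0.2)),
                    dg_trans_err=abs(rng.normal(0.8, 0.2))))
                dg_par_by_bilayer[bilayer] = dg_par
            # activity keyed to the first (reference) bilayer
            dg_ref = dg_par_by_bilayer[bilayers[0]]
            assay = ASSAYS[(mol_index) % 2]
            organism = ("P_aeruginosa" if assay == "IC50" and mol_index % 4 == 1
                        else "E_coli")
            log10_c = (activity_intercept
                       + activity_slope * max(0.0, dg_ref - potency_threshold)
                       + (rng.normal(0.0, activity_noise_sd)
                          if activity_noise_sd > 0 else 0.0))
            activity_rows.append(ActivityRecord(
                qsm_id=qsm_id, assay=assay, organism=organism,
                concentration_uM=10.0 ** log10_c, source="synthetic"))
            mol_index += 1
        del ci
    panel = pd.DataFrame([vars(r) for r in panel_rows], columns=PANEL_COLUMNS)
    activity = pd.DataFrame([vars(r) for r in activity_rows],
                            columns=ACTIVITY_COLUMNS)
    return panel, activity
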