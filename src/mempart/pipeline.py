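"""End-to-end pipeline: simulate -> wham -> features -> screen -> associate.

The pipeline regenerates the whole analysis from a flat configuration:
synthetic umbrella windows and panels are written to disk in their text
dialects, re-read, and pushed through WHAM, feature extraction, screening
trends and activity association.  Every artifact records the configuration
hash and seed, and a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as mio
from .activity import merge_activity, rank_correlation, threshold_split
from .exceptions import ParameterError, StageError
from .pmf import set_reference, summarize_pmf
from .screening import (bilayer_contrast, correlate_par_trans, oxo_offset,
                        tail_length_trend)
from .synthetic import (UmbrellaLayout, generate_partition_profile,
                        generate_screening_panel, generate_umbrella_dataset,
                        make_model_pmf)
from .wham import BiasedEnsemble, Window, two_block_pmfs

__all__ = ["RunConfig", "read_config", "write_config", "run_pipeline",
           "load_ensemble"]

logger = logging.getLogger("mempart")


@dataclass(frozen=True)
class RunConfig:
    """Flat, validated configuration for the demo pipeline.

    Defaults are sized so the full pipeline completes in seconds while still
    exercising every stage; the acceptance-scale umbrella study is run
    through the library directly.
    """

    seed: int = 1
    temperature: float = 310.15

    # model landscape
    well_depth: float = 10.0
    well_position: float = 1.2
    well_width: float = 0.3
    barrier_height: float = 25.0
    barrier_width: float = 0.5

    # umbrella layout
    z_start: float = -4.0
    z_stop: float = 1.2
    spacing: float = 0.1
    force_constant: float = 500.0
    samples_per_window: int = 1000
    equilibration_fraction: float = 0.15625

    # WHAM solver
    bin_width: float = 0.05
    tolerance: float = 1e-7
    max_iter: int = 100000

    # feature extraction
    reference_z: float = -4.0
    trans_method: str = "direct_max"
    bulk_cutoff: float = 3.0

    # partition profile emulation
    n_slices: int = 20
    plateau_halfwidth: float = 0.5
    profile_noise_sd: float = 0.25
    half_span: float = 2.0

    # screening panel / activity generation
    n_per_category: int = 10
    tail_slope: float = -1.5
    oxo_offset: float = 5.0
    potency_threshold: float = -10.0
    panel_noise_sd: float = 1.0
    activity_slope: float = 0.15
    activity_noise_sd: float = 0.35

    # association settings
    assay: str = "all"
    cutoff: float = -10.0
    n_permutations: int = 10000

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ParameterError("seed must be a nonnegative integer")
        if self.trans_method not in ("direct_max", "extrapolated"):
            raise ParameterError(f"unknown trans_method {self.trans_method!r}")
        if self.assay not in ("all", "EC50", "IC50"):
            raise ParameterError(f"unknown assay {self.assay!r}")
        for name in ("temperature", "bin_width", "tolerance", "spacing",
                     "force_constant", "half_span"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if self.max_iter < 1 or self.samples_per_window < 1:
            raise ParameterError("max_iter and samples_per_window must be >= 1")

    @property
    def hash(self) -> str:
        return mio.config_hash(mio.dataclass_items(self))


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat 'key = value' config file; unknown keys are rejected."""
    overrides: dict[str, object] = {}
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            if "=" not in body:
                raise ParameterError(
                    f"{path}: line {lineno}: expected 'key = value'")
            key, _, raw = body.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in fields:
                raise ParameterError(f"{path}: line {lineno}: unknown key {key!r}")
            ftype = fields[key].type
            try:
                if ftype == "int":
                    overrides[key] = int(raw)
                elif ftype == "float":
                    overrides[key] = float(raw)
                else:
                    overrides[key] = raw
            except ValueError:
                raise ParameterError(
                    f"{path}: line {lineno}: cannot parse {raw!r} as {ftype}") from None
    return RunConfig(**overrides)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in mio.dataclass_items(config).items():
            fh.write(f"{key} = {value}\n")


def load_ensemble(windows_meta: str | Path, windows_dir: str | Path | None,
                  temperature: float) -> BiasedEnsemble:
    """Rebuild a :class:`BiasedEnsemble` from windows.tsv plus sample files."""
    meta = mio.read_windows_meta(windows_meta)
    base = Path(windows_dir) if windows_dir is not None else Path(windows_meta).parent
    windows = []
    for row in meta.itertuples(index=False):
        path = Path(row.file)
        if not path.is_absolute():
            path = base / path
        _, z = mio.read_xy_table(path)
        windows.append(Window(center=float(row.center_nm),
                              force_constant=float(row.k_kJ_mol_nm2),
                              samples=z))
    return BiasedEnsemble(windows=tuple(windows), temperature=temperature)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: starting", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s: failed: %s", name, exc)
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


@_stage("simulate")
def stage_simulate(config: RunConfig, out: Path) -> dict[str, Path]:
    meta = {"config_sha256": config.hash, "seed": config.seed}
    potential = make_model_pmf(config.well_depth, config.well_position,
                               config.well_width, config.barrier_height,
                               config.barrier_width)
    layout = UmbrellaLayout(z_start=config.z_start, z_stop=config.z_stop,
                            spacing=config.spacing,
                            force_constants=config.force_constant,
                            samples_per_window=config.samples_per_window,
                            equilibration_fraction=config.equilibration_fraction)
    ensemble = generate_umbrella_dataset(potential, layout,
                                         temperature=config.temperature,
                                         seed=config.seed)

    windows_dir = out / "windows"
    windows_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i, w in enumerate(ensemble.windows):
        name = f"window_{i:03d}.dat"
        mio.write_xy_table(windows_dir / name, np.arange(w.samples.size),
                           w.samples,
                           header=[f"config_sha256 = {config.hash}",
                                   f"seed = {config.seed}",
                                   f"center_nm = {w.center!r}",
                                   f"k_kJ_mol_nm2 = {w.force_constant!r}"])
        files.append(f"windows/{name}")
    mio.write_windows_meta(out / "windows.tsv", files,
                           [w.center for w in ensemble.windows],
                           [w.force_constant for w in ensemble.windows],
                           meta=meta)

    profile = generate_partition_profile(
        potential, n_slices=config.n_slices, temperature=config.temperature,
        noise_sd=config.profile_noise_sd,
        plateau_halfwidth=config.plateau_halfwidth,
        seed=config.seed + 1, half_span=config.half_span)
    mio.write_partition_table(out / "partition.tsv", profile, meta=meta)

    panel, act = generate_screening_panel(
        n_per_category=config.n_per_category, tail_slope=config.tail_slope,
        oxo_offset=config.oxo_offset,
        potency_threshold=config.potency_threshold,
        noise_sd=config.panel_noise_sd, seed=config.seed + 2,
        activity_slope=config.activity_slope,
        activity_noise_sd=config.activity_noise_sd)
    mio.write_panel(out / "panel.tsv", panel, meta=meta)
    mio.write_activity(out / "activity.tsv", act, meta=meta)
    return {"windows_meta": out / "windows.tsv",
            "partition": out / "partition.tsv",
            "panel": out / "panel.tsv", "activity": out / "activity.tsv"}


@_stage("wham")
def stage_wham(config: RunConfig, out: Path) -> Path:
    ensemble = load_ensemble(out / "windows.tsv", out, config.temperature)
    result = two_block_pmfs(ensemble, bin_width=config.bin_width,
                            equilibration_fraction=config.equilibration_fraction,
                            reference_z=config.reference_z,
                            tolerance=config.tolerance,
                            max_iter=config.max_iter)
    prof = result.mean
    occ = np.isfinite(result.solutions[0].pmf_values) \
        & np.isfinite(result.solutions[1].pmf_values)
    counts = (result.solutions[0].total_counts
              + result.solutions[1].total_counts)[occ]
    mio.write_pmf_table(out / "pmf.tsv", prof, total_counts=counts,
                        meta={"config_sha256": config.hash, "seed": config.seed})
    return out / "pmf.tsv"


@_stage("features")
def stage_features(config: RunConfig, out: Path) -> Path:
    profile, _, _ = mio.read_pmf_table(out / "pmf.tsv")
    profile = set_reference(profile, config.reference_z)
    summary = summarize_pmf(profile, trans_method=config.trans_method,
                            bulk_cutoff=config.bulk_cutoff)
    mio.write_summary(summary, out / "summary.json",
                      meta={"config_sha256": config.hash, "seed": config.seed})
    return out / "summary.json"


@_stage("screen")
def stage_screen(config: RunConfig, out: Path) -> Path:
    panel = mio.read_panel(out / "panel.tsv")
    trend_ahl = tail_length_trend(panel, category="AHL")
    offset = oxo_offset(panel)
    r, slope = correlate_par_trans(panel)
    payload = {
        "tail_trend_AHL": {"slope": trend_ahl.slope,
                           "intercept": trend_ahl.intercept,
                           "r": trend_ahl.r, "n": trend_ahl.n},
        "oxo_offset": {"mean": offset.mean_offset, "n_pairs": offset.n_pairs},
        "par_trans_correlation": {"r": r, "slope": slope},
        "_meta": {"config_sha256": config.hash, "seed": config.seed},
    }
    if set(panel["bilayer"]) >= {"DOPC", "POPE_POPG"}:
        contrast = bilayer_contrast(panel)
        payload["bilayer_contrast"] = {
            "mean_dg_par": contrast.mean_dg_par, "se_dg_par": contrast.se_dg_par,
            "mean_dg_trans": contrast.mean_dg_trans,
            "se_dg_trans": contrast.se_dg_trans, "n": contrast.n}
    mio.write_json(out / "trends.json", payload)
    return out / "trends.json"


@_stage("associate")
def stage_associate(config: RunConfig, out: Path) -> Path:
    panel = mio.read_panel(out / "panel.tsv")
    act = mio.read_activity(out / "activity.tsv")
    join = merge_activity(panel, act)
    assay = None if config.assay == "all" else config.assay
    rank = rank_correlation(join, assay=assay,
                            n_permutations=config.n_permutations,
                            seed=config.seed)
    split = threshold_split(join, cutoff=config.cutoff, assay=assay)
    payload = {
        "rank_correlation": {"rho": rank.rho, "p_value": rank.p_value,
                             "n": rank.n,
                             "n_permutations": rank.n_permutations},
        "threshold_split": {"cutoff": split.cutoff,
                            "median_above": split.median_above,
                            "median_below": split.median_below,
                            "statistic": split.statistic,
                            "p_value": split.p_value, "method": split.method,
                            "n_above": split.n_above, "n_below": split.n_below},
        "unmatched_panel_ids": list(join.unmatched_panel_ids),
        "unmatched_activity_ids": list(join.unmatched_activity_ids),
        "_meta": {"config_sha256": config.hash, "seed": config.seed},
    }
    mio.write_json(out / "assoc.json", payload)
    return out / "assoc.json"


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run all stages in order into ``out_dir``; returns artifact paths.

    Any stage failure raises :class:`~mempart.exceptions.StageError` naming
    the stage.  Reruns with the same config and seed reproduce byte-identical
    outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = stage_simulate(config, out)
    artifacts["pmf"] = stage_wham(config, out)
    artifacts["summary"] = stage_features(config, out)
    artifacts["trends"] = stage_screen(config, out)
    artifacts["assoc"] = stage_associate(config, out)
    return artifacts
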