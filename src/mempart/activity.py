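"""Association between membrane partitioning and modulator potency.

Potency is an EC50 (half-maximal activation) or IC50 (half-maximal
inhibition) concentration in uM; smaller is more potent.  The observation
under test is that modulators partitioning weakly into the bilayer
(dg_par above roughly -10 kJ/mol) tend to be less potent.  Two computable
counterparts are provided: a Spearman rank correlation between dg_par and
log10 concentration with a permutation p-value, and a two-group comparison
of log10 concentrations split at a dg_par cutoff with a Wilcoxon rank-sum
test (exact for small tie-free samples, normal approximation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .screening import validate_panel
from .synthetic import ACTIVITY_COLUMNS, ASSAYS, ORGANISMS

__all__ = [
    "ActivityJoin", "merge_activity", "rank_correlation", "threshold_split",
    "RankCorrelation", "ThresholdSplit",
]

JOIN_COLUMNS = ["qsm_id", "assay", "organism", "log10_concentration_uM", "dg_par"]


@dataclass(frozen=True)
class ActivityJoin:
    """Inner join of panel free energies with activity records.

    ``frame`` has one row per (qsm_id, assay, organism); unmatched keys on
    either side are reported, not silently dropped.
    """

    frame: pd.DataFrame
    unmatched_panel_ids: tuple[str, ...]
    unmatched_activity_ids: tuple[str, ...]


def merge_activity(panel: pd.DataFrame, activities: pd.DataFrame) -> ActivityJoin:
    """Join dg_par onto activity records by qsm_id, log10-transforming potency.

    The panel must contain each qsm_id once (filter to a single bilayer
    first); duplicate (qsm_id, assay, organism) activity rows are an error,
    as is an empty join.
    """
    validate_panel(panel)
    missing = [c for c in ACTIVITY_COLUMNS[:4] if c not in activities.columns]
    if missing:
        raise ParameterError(f"activity table is missing columns {missing}")
    if not (activities["concentration_uM"] > 0).all():
        raise ParameterError("all concentrations must be positive")
    bad_assay = set(activities["assay"]) - set(ASSAYS)
    if bad_assay:
        raise ParameterError(f"unknown assays {sorted(bad_assay)}")
    bad_org = set(activities["organism"]) - set(ORGANISMS)
    if bad_org:
        raise ParameterError(f"unknown organisms {sorted(bad_org)}")
    dup = activities.duplicated(subset=["qsm_id", "assay", "organism"])
    if dup.any():
        raise ParameterError(
            "duplicate (qsm_id, assay, organism) activity rows: "
            f"{activities.loc[dup, ['qsm_id', 'assay', 'organism']].values.tolist()}")
    if panel["qsm_id"].duplicated().any():
        raise ParameterError(
            "panel has duplicate qsm_id rows (multiple bilayers?); "
            "filter to one bilayer before joining")

    panel_ids = set(panel["qsm_id"])
    act_ids = set(activities["qsm_id"])
    shared = panel_ids & act_ids
    if not shared:
        raise ParameterError(
            f"no shared qsm_id between panel {sorted(panel_ids)} and "
            f"activities {sorted(act_ids)}")
    merged = activities.merge(panel[["qsm_id", "dg_par"]], on="qsm_id", how="inner")
    merged["log10_concentration_uM"] = np.log10(merged["concentration_uM"])
    frame = merged[JOIN_COLUMNS].reset_index(drop=True)
    if not np.isfinite(frame[["log10_concentration_uM", "dg_par"]].to_numpy()).all():
        raise ParameterError("joined table contains non-finite values")
    return ActivityJoin(frame=frame,
                        unmatched_panel_ids=tuple(sorted(panel_ids - act_ids)),
                        unmatched_activity_ids=tuple(sorted(act_ids - panel_ids)))


def _filtered(join: ActivityJoin | pd.DataFrame, assay: str | None) -> pd.DataFrame:
    frame = join.frame if isinstance(join, ActivityJoin) else join
    if assay is not None and assay != "all":
        if assay not in ASSAYS:
            raise ParameterError(f"unknown assay filter {assay!r}")
        frame = frame[frame["assay"] == assay]
    return frame


@dataclass(frozen=True)
class RankCorrelation:
    """Spearman rho with a label-permutation p-value."""

    rho: float
    p_value: float
    n: int
    n_permutations: int


def rank_correlation(join: ActivityJoin | pd.DataFrame,
                     assay: str | None = None,
                     n_permutations: int = 10_000,
                     seed: int | None = 0) -> RankCorrelation:
    """Spearman correlation between dg_par and log10 potency concentration.

    A positive rho means weak partitioners need higher concentrations.  The
    two-sided p-value comes from ``n_permutations`` random relabelings of
    dg_par with a fixed seed, using the add-one estimate
    p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_permutations + 1), so
    p is in [1/(B+1), 1] and bit-reproducible.
    """
    frame = _filtered(join, assay)
    x = frame["dg_par"].to_numpy(float)
    y = frame["log10_concentration_uM"].to_numpy(float)
    n = len(x)
    if n < 4:
        raise ParameterError(f"need n >= 4 records, got {n}")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ParameterError("rank correlation undefined: a variable is all ties")
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / np.linalg.norm(rx - rx.mean())
    ry = (ry - ry.mean()) / np.linalg.norm(ry - ry.mean())
    rho = float(rx @ ry)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(rx, (n_permutations, 1)), axis=1)
    rho_perm = perms @ ry
    exceed = int(np.count_nonzero(np.abs(rho_perm) >= abs(rho) - 1e-12))
    p = (1 + exceed) / (n_permutations + 1)
    return RankCorrelation(rho=rho, p_value=float(p), n=n,
                           n_permutations=n_permutations)


@dataclass(frozen=True)
class ThresholdSplit:
    """Two-group potency comparison split at a dg_par cutoff."""

    cutoff: float
    median_above: float     # median log10 concentration, dg_par > cutoff
    median_below: float     # median log10 concentration, dg_par <= cutoff
    statistic: float        # Mann-Whitney U form of the rank-sum statistic
    p_value: float
    method: str             # "exact" or "normal_approx"
    n_above: int
    n_below: int


def threshold_split(join: ActivityJoin | pd.DataFrame,
                    cutoff: float = -10.0,
                    assay: str | None = None,
                    *,
                    exact_max_n: int = 30) -> ThresholdSplit:
    """Compare potency between weak (dg_par > cutoff) and strong partitioners.

    Reports group medians of log10 concentration and a two-sided Wilcoxon
    rank-sum (Mann-Whitney) test: exact when the pooled sample is small
    (n <= ``exact_max_n``) and tie-free, otherwise the normal approximation
    with continuity correction.  The method actually used is reported.
    """
    frame = _filtered(join, assay)
    above = frame.loc[frame["dg_par"] > cutoff, "log10_concentration_uM"].to_numpy(float)
    below = frame.loc[frame["dg_par"] <= cutoff, "log10_concentration_uM"].to_numpy(float)
    if above.size == 0 or below.size == 0:
        raise ParameterError(
            f"threshold split at cutoff={cutoff} kJ/mol leaves an empty group "
            f"(n_above={above.size}, n_below={below.size})")
    pooled = np.concatenate([above, below])
    tie_free = np.unique(pooled).size == pooled.size
    if pooled.size <= exact_max_n and tie_free:
        method = "exact"
        res = stats.mannwhitneyu(above, below, alternative="two-sided",
                                 method="exact")
    else:
        method = "normal_approx"
        res = stats.mannwhitneyu(above, below, alternative="two-sided",
                                 method="asymptotic")
    return ThresholdSplit(cutoff=float(cutoff),
                          median_above=float(np.median(above)),
                          median_below=float(np.median(below)),
                          statistic=float(res.statistic),
                          p_value=float(res.pvalue),
                          method=method,
                          n_above=int(above.size),
                          n_below=int(below.size))
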