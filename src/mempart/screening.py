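"""Trend analyses across a panel of screened quorum-sensing modulators.

The panel is a tidy DataFrame (one row per molecule x bilayer) joining
molecular descriptors — category, acyl-tail carbon count, presence of a
3-oxo head-group motif, bilayer composition — with the free-energy features
dg_par and dg_trans.  The operations here turn the qualitative
structure-activity observations into computable statistics: the tail-length
dependence of partitioning, the systematic 3-oxo offset, the (absence of a)
bilayer-composition effect, and the partitioning/translocation correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .synthetic import BILAYERS, CATEGORIES, PANEL_COLUMNS

__all__ = [
    "validate_panel", "tail_length_trend", "oxo_offset",
    "bilayer_contrast", "correlate_par_trans",
    "TrendFit", "OxoOffsetResult", "BilayerContrast",
]


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel schema, closed label sets and per-(id, bilayer) uniqueness."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ParameterError(f"panel is missing columns {missing}")
    bad_cat = set(panel["category"]) - set(CATEGORIES)
    if bad_cat:
        raise ParameterError(f"unknown categories {sorted(bad_cat)}; "
                             f"expected one of {CATEGORIES}")
    bad_bil = set(panel["bilayer"]) - set(BILAYERS)
    if bad_bil:
        raise ParameterError(f"unknown bilayers {sorted(bad_bil)}")
    dup = panel.duplicated(subset=["qsm_id", "bilayer"])
    if dup.any():
        raise ParameterError(
            f"duplicate (qsm_id, bilayer) rows: "
            f"{panel.loc[dup, ['qsm_id', 'bilayer']].values.tolist()}")
    if (panel["dg_trans"] < 0).any():
        raise ParameterError("dg_trans must be >= 0 for all records")
    if (panel[["dg_par_err", "dg_trans_err"]] < 0).any().any():
        raise ParameterError("errors must be >= 0")
    return panel


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of dg_par against tail_carbons."""

    slope: float        # kJ/mol per tail carbon
    intercept: float    # kJ/mol
    r: float            # Pearson correlation
    n: int


def tail_length_trend(panel: pd.DataFrame,
                      category: str | None = None) -> TrendFit:
    """Ordinary least-squares trend of dg_par with acyl tail length.

    Longer tails partition more strongly, so the fitted slope is negative on
    panels that follow the amphiphile trend.  Requires >= 3 records with
    distinct tail-carbon counts.
    """
    validate_panel(panel)
    sub = panel if category is None else panel[panel["category"] == category]
    x = sub["tail_carbons"].to_numpy(float)
    y = sub["dg_par"].to_numpy(float)
    if np.unique(x).size < 3:
        raise ParameterError(
            f"need >= 3 distinct tail_carbons values, got {np.unique(x).size}")
    fit = stats.linregress(x, y)
    return TrendFit(slope=float(fit.slope), intercept=float(fit.intercept),
                    r=float(fit.rvalue), n=len(sub))


@dataclass(frozen=True)
class OxoOffsetResult:
    """Mean dg_par shift attributable to the 3-oxo head-group motif."""

    mean_offset: float
    n_pairs: int
    pairs: pd.DataFrame   # one row per matched (category, tail, bilayer) key


def oxo_offset(panel: pd.DataFrame) -> OxoOffsetResult:
    """Mean dg_par(3-oxo) - dg_par(plain) over matched molecule pairs.

    Pairs are matched on (category, tail_carbons, bilayer); multiple records
    per matched key and oxo state are averaged before differencing.  A
    positive offset means the 3-oxo motif weakens partitioning.
    """
    validate_panel(panel)
    keys = ["category", "tail_carbons", "bilayer"]
    means = (panel.groupby(keys + ["has_3oxo"], observed=True)["dg_par"]
             .mean().unstack("has_3oxo"))
    if True not in means.columns or False not in means.columns:
        pairs = means.iloc[0:0]
    else:
        pairs = means.dropna(subset=[True, False])
    if len(pairs) == 0:
        unmatched = panel["qsm_id"].tolist()
        raise ParameterError(
            "no (category, tail_carbons, bilayer) keys contain both a 3-oxo "
            f"and a plain record; unmatched records: {unmatched}")
    diffs = (pairs[True] - pairs[False]).rename("offset").reset_index()
    return OxoOffsetResult(mean_offset=float(diffs["offset"].mean()),
                           n_pairs=len(diffs), pairs=diffs)


@dataclass(frozen=True)
class BilayerContrast:
    """Paired per-molecule free-energy differences between bilayers."""

    per_molecule: pd.DataFrame   # qsm_id, d_dg_par, d_dg_trans
    mean_dg_par: float
    se_dg_par: float
    mean_dg_trans: float
    se_dg_trans: float
    n: int


def bilayer_contrast(panel: pd.DataFrame,
                     bilayer_a: str = "DOPC",
                     bilayer_b: str = "POPE_POPG") -> BilayerContrast:
    """Per-molecule dg_par/dg_trans differences (a minus b) across bilayers.

    Only molecules present in both bilayers contribute; summary mean and
    standard error (sd/sqrt(n)) quantify any systematic composition effect.
    """
    validate_panel(panel)
    a = panel[panel["bilayer"] == bilayer_a].set_index("qsm_id")
    b = panel[panel["bilayer"] == bilayer_b].set_index("qsm_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ParameterError(
            f"no molecule appears in both {bilayer_a} and {bilayer_b}")
    per = pd.DataFrame({
        "qsm_id": shared,
        "d_dg_par": (a.loc[shared, "dg_par"] - b.loc[shared, "dg_par"]).to_numpy(),
        "d_dg_trans": (a.loc[shared, "dg_trans"] - b.loc[shared, "dg_trans"]).to_numpy(),
    })
    n = len(per)
    se = lambda v: float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return BilayerContrast(per_molecule=per,
                           mean_dg_par=float(per["d_dg_par"].mean()),
                           se_dg_par=se(per["d_dg_par"]),
                           mean_dg_trans=float(per["d_dg_trans"].mean()),
                           se_dg_trans=se(per["d_dg_trans"]),
                           n=n)


def correlate_par_trans(panel: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation and OLS slope of dg_trans against dg_par.

    Returns ``(r, slope)``.  Raises on fewer than 3 records or zero variance
    in either variable.
    """
    validate_panel(panel)
    x = panel["dg_par"].to_numpy(float)
    y = panel["dg_trans"].to_numpy(float)
    if len(x) < 3:
        raise ParameterError(f"need >= 3 records, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero variance in dg_par or dg_trans")
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope)
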