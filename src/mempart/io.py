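"""Readers and writers for the package's plain-text table dialects.

Window time series use an xvg-like dialect: header lines starting with '#'
or '@' are ignored and data rows carry whitespace-separated numeric columns
(time-index, z in nm).  Profiles and panels are TSV with a header row,
preceded by '# key = value' metadata lines (config hash, seed, units).
Summaries are JSON.  Floats survive every round trip at full precision
(shortest-repr serialization).  Run configuration is a flat 'key = value'
text file with '#' comments; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError
from .pmf import FreeEnergySummary, PartitionProfile, PMFProfile
from .synthetic import ACTIVITY_COLUMNS, PANEL_COLUMNS

__all__ = [
    "read_xy_table", "write_xy_table",
    "read_windows_meta", "write_windows_meta",
    "read_pmf_table", "write_pmf_table",
    "read_partition_table", "write_partition_table",
    "read_panel", "write_panel", "read_activity", "write_activity",
    "read_summary", "write_summary", "write_json", "read_json",
]

SUMMARY_KEYS = ("dg_par", "dg_trans", "dg_par_err", "dg_trans_err",
                "z_min", "trans_method", "asymmetry_score")


# ---------------------------------------------------------------- xy tables

def read_xy_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a two-column whitespace table, skipping '#'/'@' header lines.

    Extra columns beyond the first two are ignored (common in simulation
    output).  A row with fewer than two columns or a non-numeric cell raises
    :class:`~mempart.exceptions.ParseError` citing the 1-based line number.
    """
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0] in "#@":
                continue
            cols = stripped.split()
            if len(cols) < 2:
                raise ParseError(f"{path}: line {lineno}: expected >= 2 columns, "
                                 f"got {len(cols)}")
            try:
                xs.append(float(cols[0]))
                ys.append(float(cols[1]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric value "
                                 f"({exc})") from None
    return np.asarray(xs), np.asarray(ys)


def write_xy_table(path: str | Path, x: Iterable[float], y: Iterable[float],
                   header: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for xi, yi in zip(x, y):
            fh.write(f"{float(xi)!r} {float(yi)!r}\n")


# --------------------------------------------------------- metadata helpers

def _meta_lines(meta: Mapping[str, Any] | None) -> list[str]:
    if not meta:
        return []
    return [f"# {key} = {value}" for key, value in meta.items()]


def _read_meta(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def config_hash(items: Mapping[str, Any]) -> str:
    """sha256 over the canonical sorted 'key = value' rendering of a config."""
    canonical = "".join(f"{k} = {items[k]!r}\n" for k in sorted(items))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write_tsv(path: str | Path, frame: pd.DataFrame,
               meta: Mapping[str, Any] | None) -> None:
    with open(path, "w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        frame.to_csv(fh, sep="\t", index=False,
                     float_format=lambda v: repr(float(v)))


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")


# ------------------------------------------------------------ window layout

def write_windows_meta(path: str | Path, files: Iterable[str],
                       centers: Iterable[float], force_constants: Iterable[float],
                       meta: Mapping[str, Any] | None = None) -> None:
    frame = pd.DataFrame({"file": list(files),
                          "center_nm": list(centers),
                          "k_kJ_mol_nm2": list(force_constants)})
    _write_tsv(path, frame, meta)


def read_windows_meta(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv(path)
    missing = [c for c in ("file", "center_nm", "k_kJ_mol_nm2")
               if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: windows metadata missing columns {missing}")
    return frame


# -------------------------------------------------------------- pmf tables

def write_pmf_table(path: str | Path, profile: PMFProfile,
                    total_counts: np.ndarray | None = None,
                    meta: Mapping[str, Any] | None = None) -> None:
    sd = profile.g_sd if profile.g_sd is not None else np.zeros_like(profile.g)
    counts = (np.asarray(total_counts) if total_counts is not None
              else np.zeros(profile.z.size, dtype=int))
    meta = dict(meta or {})
    meta.setdefault("temperature_K", profile.temperature)
    if profile.reference_z is not None:
        meta.setdefault("reference_z_nm", profile.reference_z)
    frame = pd.DataFrame({"z_nm": profile.z, "pmf_kJ_mol": profile.g,
                          "sd_kJ_mol": sd, "total_counts": counts})
    _write_tsv(path, frame, meta)


def read_pmf_table(path: str | Path) -> tuple[PMFProfile, np.ndarray, dict]:
    meta = _read_meta(path)
    frame = _read_tsv(path)
    missing = [c for c in ("z_nm", "pmf_kJ_mol", "sd_kJ_mol", "total_counts")
               if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: PMF table missing columns {missing}")
    temperature = float(meta.get("temperature_K", 310.15))
    ref = meta.get("reference_z_nm")
    profile = PMFProfile(z=frame["z_nm"].to_numpy(),
                         g=frame["pmf_kJ_mol"].to_numpy(),
                         g_sd=frame["sd_kJ_mol"].to_numpy(),
                         reference_z=None if ref is None else float(ref),
                         temperature=temperature)
    return profile, frame["total_counts"].to_numpy(), meta


# -------------------------------------------------------- partition tables

def write_partition_table(path: str | Path, profile: PartitionProfile,
                          meta: Mapping[str, Any] | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("temperature_K", profile.temperature)
    frame = pd.DataFrame({"z_nm": profile.z, "ln_K": profile.ln_K})
    _write_tsv(path, frame, meta)


def read_partition_table(path: str | Path) -> PartitionProfile:
    meta = _read_meta(path)
    frame = _read_tsv(path)
    missing = [c for c in ("z_nm", "ln_K") if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: partition table missing columns {missing}")
    return PartitionProfile(z=frame["z_nm"].to_numpy(),
                            ln_K=frame["ln_K"].to_numpy(),
                            temperature=float(meta.get("temperature_K", 310.15)))


# -------------------------------------------------------- panels/activities

def write_panel(path: str | Path, panel: pd.DataFrame,
                meta: Mapping[str, Any] | None = None) -> None:
    _write_tsv(path, panel[PANEL_COLUMNS], meta)


def read_panel(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv(path)
    missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: panel missing columns {missing}")
    frame["has_3oxo"] = frame["has_3oxo"].astype(bool)
    return frame


def write_activity(path: str | Path, activity: pd.DataFrame,
                   meta: Mapping[str, Any] | None = None) -> None:
    _write_tsv(path, activity[ACTIVITY_COLUMNS], meta)


def read_activity(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv(path)
    missing = [c for c in ACTIVITY_COLUMNS[:4] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: activity table missing columns {missing}")
    if "source" not in frame.columns:
        frame["source"] = ""
    return frame


# ------------------------------------------------------------------- JSON

def write_json(path: str | Path, payload: Mapping[str, Any]) -> None:
    """Deterministic JSON: sorted keys, shortest-repr floats, NaN rejected."""
    def _clean(obj):
        if isinstance(obj, Mapping):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            obj = obj.item()
        if isinstance(obj, float) and not math.isfinite(obj):
            raise SchemaError(f"non-finite value {obj!r} cannot be serialized")
        return obj

    with open(path, "w") as fh:
        json.dump(_clean(dict(payload)), fh, indent=2, sort_keys=True,
                  allow_nan=False)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_summary(summary: FreeEnergySummary, path: str | Path,
                  meta: Mapping[str, Any] | None = None) -> None:
    """Serialize a free-energy summary; NaN fields are rejected at write time."""
    payload: dict[str, Any] = {
        "dg_par": summary.dg_par,
        "dg_trans": summary.dg_trans,
        "dg_par_err": summary.dg_par_err,
        "dg_trans_err": summary.dg_trans_err,
        "z_min": summary.z_min,
        "trans_method": summary.trans_method,
        "asymmetry_score": summary.asymmetry,
    }
    for key, value in payload.items():
        if isinstance(value, float) and not math.isfinite(value):
            raise SchemaError(f"summary field {key!r} is non-finite ({value})")
    if meta:
        payload["_meta"] = dict(meta)
    write_json(path, payload)


def read_summary(path: str | Path) -> FreeEnergySummary:
    payload = read_json(path)
    missing = [k for k in SUMMARY_KEYS if k not in payload]
    if missing:
        raise SchemaError(f"{path}: summary missing keys {missing}")
    return FreeEnergySummary(
        dg_par=payload["dg_par"], dg_trans=payload["dg_trans"],
        dg_par_err=payload["dg_par_err"], dg_trans_err=payload["dg_trans_err"],
        trans_method=payload["trans_method"], z_min=payload["z_min"],
        asymmetry=payload["asymmetry_score"])


def dataclass_items(obj) -> dict[str, Any]:
    """Flat field dict of a dataclass instance (for configs and metadata)."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
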