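"""Free-energy profiles and the headline partitioning quantities.

A potential of mean force (PMF) along the bilayer normal z is summarised by
two numbers: the partition free energy dG_par (PMF minimum relative to the
bulk-water reference; more negative = stronger membrane partitioning) and
the translocation free energy dG_trans (PMF maximum minus minimum; the
barrier to crossing the midplane).

Implicit-solvent partition-coefficient profiles report the slice-wise
water-to-membrane partition coefficient K_{w->m}(z) instead; the two
representations are related by PMF(z) = -RT ln K_{w->m}(z).  Such profiles
plateau near the midplane, so dG_trans is alternatively estimated by
linearly extrapolating the steep flank of the profile (the 3rd-5th grid
points closest to z = 0 on each side) to z = 0 and taking the intercept
minus the minimum (:func:`delta_g_trans_extrapolated`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, rt
from .exceptions import ParameterError, StateError

__all__ = [
    "PMFProfile", "PartitionProfile", "FreeEnergySummary",
    "set_reference", "asymmetry_score", "delta_g_par",
    "delta_g_trans_direct", "delta_g_trans_extrapolated",
    "ExtrapolationDiagnostics", "pmf_from_partition", "partition_from_pmf",
    "combine_replicates", "summarize_pmf",
]

#: Default |z| below which a reference point is not considered bulk water.
DEFAULT_BULK_CUTOFF = 3.0


@dataclass(frozen=True)
class PMFProfile:
    """Free-energy curve g(z) on a strictly increasing z grid (gaps allowed).

    ``reference_z`` records the bulk-water point at which the profile was
    zeroed; it is None for raw, unreferenced profiles.
    """

    z: np.ndarray
    g: np.ndarray
    g_sd: np.ndarray | None = None
    reference_z: float | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        z = np.asarray(self.z, float)
        g = np.asarray(self.g, float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "g", g)
        if z.ndim != 1 or z.shape != g.shape or z.size == 0:
            raise ParameterError("z and g must be nonempty 1D arrays of equal length")
        if not np.all(np.diff(z) > 0):
            raise ParameterError("z grid must be strictly increasing")
        if not np.all(np.isfinite(g)):
            raise ParameterError("g must be finite on all stored points")
        if self.g_sd is not None:
            sd = np.asarray(self.g_sd, float)
            object.__setattr__(self, "g_sd", sd)
            if sd.shape != g.shape or np.any(sd < 0) or not np.all(np.isfinite(sd)):
                raise ParameterError("g_sd must be finite, nonnegative, same shape as g")
        if not self.temperature > 0:
            raise ParameterError(f"temperature must be positive, got {self.temperature}")
        if self.reference_z is not None:
            i = int(np.argmin(np.abs(z - self.reference_z)))
            if abs(g[i]) > 1e-9:
                raise ParameterError(
                    f"referenced profile must be 0 at the grid point nearest "
                    f"reference_z={self.reference_z} (found g={g[i]!r})")


@dataclass(frozen=True)
class PartitionProfile:
    """Slice-wise ln K_{w->m}(z) profile at a stated temperature."""

    z: np.ndarray
    ln_K: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        z = np.asarray(self.z, float)
        k = np.asarray(self.ln_K, float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "ln_K", k)
        if z.ndim != 1 or z.shape != k.shape or z.size == 0:
            raise ParameterError("z and ln_K must be nonempty 1D arrays of equal length")
        if not np.all(np.diff(z) > 0):
            raise ParameterError("slice centers must be strictly increasing")
        if not np.all(np.isfinite(k)):
            raise ParameterError("ln_K must be finite")
        if not self.temperature > 0:
            raise ParameterError(f"temperature must be positive, got {self.temperature}")


@dataclass(frozen=True)
class FreeEnergySummary:
    """dG_par / dG_trans with uncertainties and method provenance."""

    dg_par: float
    dg_trans: float
    dg_par_err: float = 0.0
    dg_trans_err: float = 0.0
    trans_method: Literal["direct_max", "extrapolated"] = "direct_max"
    z_min: float = math.nan
    asymmetry: float | None = None

    def __post_init__(self) -> None:
        if self.dg_trans < 0:
            raise ParameterError(f"dg_trans must be >= 0, got {self.dg_trans}")
        if self.dg_par_err < 0 or self.dg_trans_err < 0:
            raise ParameterError("uncertainties must be >= 0")
        if self.trans_method not in ("direct_max", "extrapolated"):
            raise ParameterError(f"unknown trans_method {self.trans_method!r}")


def set_reference(pmf: PMFProfile, z_ref: float) -> PMFProfile:
    """Zero the profile at the grid point nearest ``z_ref`` (nearest-point rule)."""
    if not (pmf.z[0] <= z_ref <= pmf.z[-1]):
        raise ParameterError(
            f"z_ref={z_ref} outside the grid span [{pmf.z[0]}, {pmf.z[-1]}]")
    i = int(np.argmin(np.abs(pmf.z - z_ref)))
    return replace(pmf, g=pmf.g - pmf.g[i], reference_z=float(z_ref))


def asymmetry_score(pmf: PMFProfile) -> float:
    """Mean |g(z) - g(-z)| over mirrored pairs (kJ/mol); 0 when even.

    The mirrored value is linearly interpolated; only points whose mirror
    image lies inside the grid span contribute.  Additive constants cancel.
    """
    pos = pmf.z > 0
    neg = pmf.z < 0
    if not (pos.any() and neg.any()):
        raise ParameterError(
            "profile is one-sided; the symmetry diagnostic does not apply")
    zs = pmf.z[pos]
    zs = zs[(-zs >= pmf.z[0]) & (-zs <= pmf.z[-1])]
    if zs.size == 0:
        raise ParameterError("no mirrored pairs inside the grid span")
    g_pos = np.interp(zs, pmf.z, pmf.g)
    g_neg = np.interp(-zs, pmf.z, pmf.g)
    return float(np.mean(np.abs(g_pos - g_neg)))


def _require_bulk_reference(pmf: PMFProfile, bulk_cutoff: float) -> None:
    if pmf.reference_z is None:
        raise StateError("profile must be referenced to bulk water first "
                         "(call set_reference)")
    if abs(pmf.reference_z) < bulk_cutoff:
        raise StateError(
            f"reference_z={pmf.reference_z} is inside |z| < {bulk_cutoff} nm "
            "and cannot be considered bulk water")


def delta_g_par(pmf: PMFProfile,
                bulk_cutoff: float = DEFAULT_BULK_CUTOFF) -> tuple[float, float]:
    """Partition free energy: PMF minimum relative to the bulk reference.

    Returns ``(dg_par, z_min)``.  The minimum is taken over stored grid
    points only; among ties the point with largest |z| (closest to the
    interface approached from bulk) is reported.
    """
    _require_bulk_reference(pmf, bulk_cutoff)
    gmin = pmf.g.min()
    ties = np.flatnonzero(pmf.g == gmin)
    i = ties[np.argmax(np.abs(pmf.z[ties]))]
    return float(gmin), float(pmf.z[i])


def delta_g_trans_direct(pmf: PMFProfile) -> float:
    """Translocation free energy as global maximum minus global minimum."""
    if pmf.reference_z is None:
        raise StateError("profile must be referenced first (call set_reference)")
    return float(pmf.g.max() - pmf.g.min())


@dataclass(frozen=True)
class ExtrapolationDiagnostics:
    """Per-side fit details of the flank extrapolation."""

    sides: dict   # side name -> {"slope", "intercept", "z", "g"}
    intercept: float


def _side_fit(z: np.ndarray, g: np.ndarray):
    order = np.argsort(np.abs(z), kind="stable")
    sel = order[2:5]                       # 3rd, 4th and 5th closest to z = 0
    zs, gs = z[sel], g[sel]
    slope, intercept = np.polyfit(zs, gs, 1)
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ParameterError("flank fit is non-finite (degenerate points)")
    return float(slope), float(intercept), zs, gs


def delta_g_trans_extrapolated(pmf: PMFProfile) -> tuple[float, ExtrapolationDiagnostics]:
    """Translocation free energy by linear extrapolation of the flank.

    On each side of the bilayer with at least five grid points, an ordinary
    least-squares line through the 3rd, 4th and 5th points closest to z = 0
    is evaluated at z = 0; when both sides qualify the two intercepts are
    averaged.  The result is intercept minus the global minimum.  Grid points
    at exactly z = 0 are assigned to the negative side.
    """
    if pmf.reference_z is None:
        raise StateError("profile must be referenced first (call set_reference)")
    neg = pmf.z <= 0        # midplane point belongs to the negative side
    pos = pmf.z > 0
    sides: dict[str, dict] = {}
    for name, mask in (("negative", neg), ("positive", pos)):
        if mask.sum() >= 5:
            slope, intercept, zs, gs = _side_fit(pmf.z[mask], pmf.g[mask])
            sides[name] = {"slope": slope, "intercept": intercept,
                           "z": zs, "g": gs}
    if not sides:
        raise ParameterError(
            "need at least 5 grid points on one side of z = 0 to extrapolate")
    intercept = float(np.mean([s["intercept"] for s in sides.values()]))
    value = intercept - float(pmf.g.min())
    return value, ExtrapolationDiagnostics(sides=sides, intercept=intercept)


def pmf_from_partition(profile: PartitionProfile) -> PMFProfile:
    """Convert ln K_{w->m}(z) to a PMF: g(z) = -RT ln K(z), unreferenced."""
    kt = rt(profile.temperature)
    return PMFProfile(z=profile.z.copy(), g=-kt * profile.ln_K,
                      temperature=profile.temperature)


def partition_from_pmf(pmf: PMFProfile) -> PartitionProfile:
    """Inverse conversion: ln K(z) = -g(z)/RT; round-trips to 1e-12."""
    kt = rt(pmf.temperature)
    return PartitionProfile(z=pmf.z.copy(), ln_K=-pmf.g / kt,
                            temperature=pmf.temperature)


def combine_replicates(summaries: Sequence[FreeEnergySummary]) -> FreeEnergySummary:
    """Mean and standard error (sd/sqrt(n)) over independent replicates.

    All replicates must share one ``trans_method``; mixing a direct-maximum
    estimate with an extrapolated one is not comparable and raises.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ParameterError("need at least 2 replicate summaries")
    methods = {s.trans_method for s in summaries}
    if len(methods) > 1:
        raise ParameterError(f"mixed trans_method values {sorted(methods)}")
    n = len(summaries)
    par = np.array([s.dg_par for s in summaries])
    trans = np.array([s.dg_trans for s in summaries])
    zmin = np.array([s.z_min for s in summaries])
    se = lambda v: float(np.std(v, ddof=1) / math.sqrt(n))
    return FreeEnergySummary(dg_par=float(par.mean()), dg_trans=float(trans.mean()),
                             dg_par_err=se(par), dg_trans_err=se(trans),
                             trans_method=summaries[0].trans_method,
                             z_min=float(zmin.mean()))


def summarize_pmf(pmf: PMFProfile,
                  trans_method: Literal["direct_max", "extrapolated"] = "direct_max",
                  bulk_cutoff: float = DEFAULT_BULK_CUTOFF) -> FreeEnergySummary:
    """Extract a :class:`FreeEnergySummary` from a referenced profile.

    Uncertainties are propagated from the per-bin sd when the profile has
    one: dG_par inherits the sd at the minimum, dG_trans adds the sds at the
    extrema in quadrature.  The symmetry diagnostic is included when the grid
    covers both sides of the midplane.
    """
    dg_par, z_min = delta_g_par(pmf, bulk_cutoff=bulk_cutoff)
    if trans_method == "direct_max":
        dg_trans = delta_g_trans_direct(pmf)
    elif trans_method == "extrapolated":
        dg_trans, _ = delta_g_trans_extrapolated(pmf)
    else:
        raise ParameterError(f"unknown trans_method {trans_method!r}")
    par_err = trans_err = 0.0
    if pmf.g_sd is not None:
        i_min = int(np.argmin(pmf.g))
        i_max = int(np.argmax(pmf.g))
        par_err = float(pmf.g_sd[i_min])
        trans_err = float(math.hypot(pmf.g_sd[i_min], pmf.g_sd[i_max]))
    try:
        asym = asymmetry_score(pmf)
    except ParameterError:
        asym = None
    return FreeEnergySummary(dg_par=dg_par, dg_trans=max(dg_trans, 0.0),
                             dg_par_err=par_err, dg_trans_err=trans_err,
                             trans_method=trans_method, z_min=z_min,
                             asymmetry=asym)
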