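"""Weighted histogram analysis method (WHAM) for 1D umbrella sampling.

Biased window samples are histogrammed on a shared grid and combined through
the self-consistent WHAM equations

    rho(b) = sum_i n_i(b) / sum_i N_i exp[(f_i - u_i(b)) / RT]
    f_i    = -RT ln sum_b rho(b) exp[-u_i(b) / RT]

iterated to convergence, where n_i(b) are per-window bin counts, N_i window
sample totals and u_i(b) the harmonic bias energies.  The potential of mean
force is PMF(b) = -RT ln rho(b) up to an additive constant; referencing to a
bulk-water point is a separate operation (:func:`mempart.pmf.set_reference`).

Uncertainties follow the block protocol: the post-equilibration samples of
every window are split into two equal contiguous blocks, WHAM is run per
block, and the per-bin standard deviation of the two commonly-referenced
profiles is reported (:func:`two_block_pmfs`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .constants import DEFAULT_TEMPERATURE, rt
from .exceptions import DisconnectedWindowsError, ParameterError

__all__ = [
    "Window", "BiasedEnsemble", "WindowHistograms", "WhamSolution",
    "histogram_windows", "harmonic_bias_matrix", "solve_wham",
    "two_block_pmfs", "TwoBlockResult",
]

#: Per-iteration gauge: window 0's free energy is pinned to zero.
_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class Window:
    """One umbrella window: harmonic bias centre/stiffness and its samples."""

    center: float
    force_constant: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("window samples must be a nonempty 1D sequence")
        if not self.force_constant >= 0:
            raise ParameterError(f"force_constant must be >= 0, got {self.force_constant}")


@dataclass(frozen=True)
class BiasedEnsemble:
    """A set of umbrella windows sharing one temperature."""

    windows: tuple[Window, ...]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        if len(self.windows) == 0:
            raise ParameterError("ensemble must contain at least one window")
        if not self.temperature > 0:
            raise ParameterError(f"temperature must be positive, got {self.temperature}")

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    @property
    def force_constants(self) -> np.ndarray:
        return np.array([w.force_constant for w in self.windows])


@dataclass(frozen=True)
class WindowHistograms:
    """Per-window counts on a shared bin grid, with clipping bookkeeping."""

    bin_edges: np.ndarray
    bin_centers: np.ndarray
    counts: np.ndarray          # shape (n_windows, n_bins)
    clipped: np.ndarray         # samples per window outside the range

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def histogram_windows(ensemble: BiasedEnsemble,
                      bin_width: float = 0.05,
                      z_range: tuple[float, float] | None = None,
                      *,
                      max_clipped_fraction: float = 0.10,
                      warn_clipped_fraction: float = 0.01) -> WindowHistograms:
    """Histogram every window of ``ensemble`` on one shared grid.

    If ``z_range`` is None the grid spans all samples.  Samples outside an
    explicit range are clipped: counted per window, a warning above 1% of the
    total and an error above 10% (the clipping is then considered a setup
    mistake rather than edge trimming).
    """
    if not bin_width > 0:
        raise ParameterError(f"bin_width must be positive, got {bin_width}")
    all_samples = np.concatenate([w.samples for w in ensemble.windows])
    if z_range is None:
        lo, hi = float(all_samples.min()), float(all_samples.max())
    else:
        lo, hi = map(float, z_range)
        if not lo < hi:
            raise ParameterError(f"empty z_range {z_range}")
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.empty((len(ensemble.windows), n_bins))
    clipped = np.empty(len(ensemble.windows), dtype=int)
    for i, w in enumerate(ensemble.windows):
        counts[i], _ = np.histogram(w.samples, bins=edges)
        clipped[i] = w.samples.size - int(counts[i].sum())
    frac = clipped.sum() / all_samples.size
    if frac > max_clipped_fraction:
        raise ParameterError(
            f"{frac:.1%} of samples fall outside the histogram range {lo, hi}; "
            "widen the range or check the window metadata")
    if frac > warn_clipped_fraction:
        warnings.warn(f"{frac:.2%} of samples clipped by the histogram range",
                      stacklevel=2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return WindowHistograms(bin_edges=edges, bin_centers=centers,
                            counts=counts, clipped=clipped)


def harmonic_bias_matrix(centers: Sequence[float],
                         force_constants: Sequence[float],
                         bin_centers: np.ndarray) -> np.ndarray:
    """Bias energies u_i(b) = k_i (z_b - z0_i)^2 / 2 on the histogram grid."""
    c = np.asarray(centers, float)[:, None]
    k = np.asarray(force_constants, float)[:, None]
    z = np.asarray(bin_centers, float)[None, :]
    return 0.5 * k * (z - c) ** 2


@dataclass(frozen=True)
class WhamSolution:
    """Converged (or best-effort) output of the self-consistent iteration."""

    bin_centers: np.ndarray
    pmf_values: np.ndarray            # NaN on bins with zero total count
    density: np.ndarray               # unbiased probability per bin, sums to 1
    window_free_energies: np.ndarray  # f_i, gauge f_0 = 0
    total_counts: np.ndarray
    temperature: float
    n_iterations: int
    converged: bool
    max_residual: float
    residual_trace: np.ndarray = field(repr=False, default=None)

    def to_profile(self, reference_z: float | None = None):
        """Export the occupied bins as a :class:`mempart.pmf.PMFProfile`."""
        from .pmf import PMFProfile, set_reference

        occ = np.isfinite(self.pmf_values)
        prof = PMFProfile(z=self.bin_centers[occ], g=self.pmf_values[occ],
                          temperature=self.temperature)
        if reference_z is not None:
            prof = set_reference(prof, reference_z)
        return prof


def _connectivity_groups(counts: np.ndarray) -> list[list[int]]:
    occ = counts > 0
    adjacency = (occ @ occ.T) > 0
    n, labels = connected_components(adjacency, directed=False)
    return [list(np.flatnonzero(labels == c)) for c in range(n)]


def solve_wham(histograms: WindowHistograms | np.ndarray,
               biases: np.ndarray,
               temperature: float = DEFAULT_TEMPERATURE,
               tolerance: float = 1e-7,
               max_iter: int = 100_000) -> WhamSolution:
    """Solve the WHAM equations by damped-free direct iteration.

    Parameters
    ----------
    histograms:
        :class:`WindowHistograms` or a raw (n_windows, n_bins) count array.
    biases:
        Bias energy matrix u_i(b) in kJ/mol, same shape as the counts
        (see :func:`harmonic_bias_matrix`).
    tolerance:
        Convergence threshold on max_i |f_i^{t+1} - f_i^t| in kJ/mol.

    The window free energies are initialised to zero and gauged to f_0 = 0
    after every update; the density is renormalised to sum to one, which
    fixes the arbitrary additive constant of the returned PMF.  Windows whose
    histograms form disconnected islands raise
    :class:`~mempart.exceptions.DisconnectedWindowsError` naming the groups.
    """
    if isinstance(histograms, WindowHistograms):
        counts = histograms.counts
        bin_centers = histograms.bin_centers
    else:
        counts = np.asarray(histograms, float)
        bin_centers = np.arange(counts.shape[1], dtype=float)
    biases = np.asarray(biases, float)
    if biases.shape != counts.shape:
        raise ParameterError(
            f"bias matrix shape {biases.shape} != counts shape {counts.shape}")
    if not tolerance > 0:
        raise ParameterError(f"tolerance must be positive, got {tolerance}")
    if max_iter < 1:
        raise ParameterError(f"max_iter must be >= 1, got {max_iter}")

    groups = _connectivity_groups(counts)
    if len(groups) > 1:
        raise DisconnectedWindowsError(groups)

    kt = rt(temperature)
    n_w = counts.sum(axis=1)                      # N_i
    c_b = counts.sum(axis=0)                      # total counts per bin
    occ = c_b > 0
    boltz = np.exp(-biases / kt)                  # may underflow to 0: fine
    f = np.zeros(counts.shape[0])
    trace: list[float] = []
    converged = False
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        denom = (n_w[:, None] * np.exp(f / kt)[:, None] * boltz).sum(axis=0)
        rho = np.where(occ, c_b / np.maximum(denom, _TINY), 0.0)
        rho /= rho.sum()
        with np.errstate(divide="ignore"):
            f_new = -kt * np.log(np.maximum((boltz * rho[None, :]).sum(axis=1), _TINY))
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        trace.append(residual)
        f = f_new
        if residual <= tolerance:
            converged = True
            break

    denom = (n_w[:, None] * np.exp(f / kt)[:, None] * boltz).sum(axis=0)
    rho = np.where(occ, c_b / np.maximum(denom, _TINY), 0.0)
    rho /= rho.sum()
    with np.errstate(divide="ignore"):
        pmf = np.where(occ, -kt * np.log(np.maximum(rho, _TINY)), np.nan)
    return WhamSolution(bin_centers=bin_centers, pmf_values=pmf, density=rho,
                        window_free_energies=f, total_counts=c_b,
                        temperature=temperature, n_iterations=it,
                        converged=converged, max_residual=residual,
                        residual_trace=np.asarray(trace))


@dataclass(frozen=True)
class TwoBlockResult:
    """Mean profile (with per-bin sd) and the two underlying block profiles."""

    mean: "object"        # PMFProfile with g_sd set
    blocks: tuple         # the two referenced block PMFProfiles
    solutions: tuple      # the two WhamSolutions


def _split_window(samples: np.ndarray, equilibration_fraction: float):
    n_eq = int(round(samples.size * equilibration_fraction))
    prod = samples[n_eq:]
    if prod.size < 2:
        raise ParameterError(
            f"window has {prod.size} post-equilibration samples; need >= 2")
    if prod.size % 2 == 1:     # drop the first sample, never unequal blocks
        prod = prod[1:]
    half = prod.size // 2
    return prod[:half], prod[half:]


def two_block_pmfs(ensemble: BiasedEnsemble,
                   *,
                   bin_width: float = 0.05,
                   z_range: tuple[float, float] | None = None,
                   equilibration_fraction: float = 0.0,
                   reference_z: float | None = None,
                   tolerance: float = 1e-7,
                   max_iter: int = 100_000) -> TwoBlockResult:
    """Two-block PMF estimate with per-bin standard deviations.

    Each window's post-equilibration samples are split into two equal
    contiguous blocks (odd counts drop the first sample); WHAM runs per block
    on a shared grid; the blocks are put on a common reference (the bin
    nearest ``reference_z``, or their mean over commonly occupied bins when
    ``reference_z`` is None) and the mean and per-bin sd over the two blocks
    are returned on the bins occupied in both.
    """
    if not 0 <= equilibration_fraction < 1:
        raise ParameterError(
            f"equilibration_fraction must be in [0, 1), got {equilibration_fraction}")
    halves = [_split_window(w.samples, equilibration_fraction)
              for w in ensemble.windows]
    ensembles = []
    for j in (0, 1):
        ensembles.append(BiasedEnsemble(
            windows=tuple(Window(w.center, w.force_constant, halves[i][j])
                          for i, w in enumerate(ensemble.windows)),
            temperature=ensemble.temperature))
    if z_range is None:
        allz = np.concatenate([np.concatenate(h) for h in halves])
        z_range = (float(allz.min()), float(allz.max()) + 1e-12)

    solutions = []
    for ens in ensembles:
        hist = histogram_windows(ens, bin_width=bin_width, z_range=z_range)
        u = harmonic_bias_matrix(ens.centers, ens.force_constants, hist.bin_centers)
        solutions.append(solve_wham(hist, u, temperature=ensemble.temperature,
                                    tolerance=tolerance, max_iter=max_iter))
    a, b = solutions
    occ = np.isfinite(a.pmf_values) & np.isfinite(b.pmf_values)
    if not occ.any():
        raise ParameterError("blocks share no occupied bins")
    z = a.bin_centers[occ]
    ga = a.pmf_values[occ].copy()
    gb = b.pmf_values[occ].copy()
    if reference_z is None:
        ga -= ga.mean()
        gb -= gb.mean()
        ref = None
    else:
        i_ref = int(np.argmin(np.abs(z - reference_z)))
        ga -= ga[i_ref]
        gb -= gb[i_ref]
        ref = float(z[i_ref])

    from .pmf import PMFProfile

    mean = 0.5 * (ga + gb)
    sd = np.abs(ga - gb) / np.sqrt(2.0)     # ddof=1 sd of two values
    mean_prof = PMFProfile(z=z, g=mean, g_sd=sd, reference_z=ref,
                           temperature=ensemble.temperature)
    blocks = (PMFProfile(z=z, g=ga, reference_z=ref, temperature=ensemble.temperature),
              PMFProfile(z=z, g=gb, reference_z=ref, temperature=ensemble.temperature))
    return TwoBlockResult(mean=mean_prof, blocks=blocks, solutions=tuple(solutions))
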