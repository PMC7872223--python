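"""Analytic model free-energy landscapes for a solute crossing a bilayer.

The landscape mimics the canonical amphiphile profile along the bilayer
normal z: two symmetric interfacial minima (head group at the interface, tail
inserted) and a central barrier at the midplane, decaying to a bulk-water
level of exactly zero far from the membrane.  The functional form is a sum of
Gaussians,

    U(z) = -D [g(z - z_w) + g(z + z_w)] + B g(z),

with g(x) = exp(-(x/w)^2) a Gaussian bump of unit height.  Width parameters
are 1/e half-widths w (standard deviation w/sqrt(2)); with the defaults the
components are well separated, so U(0) = B and min U = -D hold to better
than 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError


@dataclass(frozen=True)
class ModelPotential:
    """Even double-well / central-barrier potential along the bilayer normal.

    Parameters
    ----------
    well_depth:
        Depth D of each interfacial minimum in kJ/mol (positive).
    well_position:
        |z| of the minima in nm.
    well_width:
        1/e half-width of the well Gaussians in nm.
    barrier_height:
        Value B of the midplane barrier at z = 0 relative to bulk, kJ/mol.
    barrier_width:
        1/e half-width of the barrier Gaussian in nm.
    """

    well_depth: float = 10.0
    well_position: float = 1.2
    well_width: float = 0.3
    barrier_height: float = 25.0
    barrier_width: float = 0.5

    def __post_init__(self) -> None:
        for name in ("well_depth", "well_position", "well_width",
                     "barrier_height", "barrier_width"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ParameterError(f"{name} must be positive and finite, got {value!r}")

    @property
    def bulk_level(self) -> float:
        """Free energy in bulk water; fixed at 0 kJ/mol by construction."""
        return 0.0

    def __call__(self, z):
        """Evaluate U(z) in kJ/mol; accepts scalars or arrays."""
        z = np.asarray(z, dtype=float)
        iw = 1.0 / self.well_width ** 2
        ib = 1.0 / self.barrier_width ** 2
        wells = (np.exp(-((z - self.well_position) ** 2) * iw)
                 + np.exp(-((z + self.well_position) ** 2) * iw))
        barrier = np.exp(-(z * z) * ib)
        out = -self.well_depth * wells + self.barrier_height * barrier
        return float(out) if out.ndim == 0 else out

    def energy(self, z: float) -> float:
        """Scalar fast path of :meth:`__call__` for tight sampling loops."""
        iw = 1.0 / self.well_width ** 2
        ib = 1.0 / self.barrier_width ** 2
        dm = z - self.well_position
        dp = z + self.well_position
        return (-self.well_depth * (math.exp(-dm * dm * iw) + math.exp(-dp * dp * iw))
                + self.barrier_height * math.exp(-z * z * ib))


def make_model_pmf(well_depth: float = 10.0,
                   well_position: float = 1.2,
                   well_width: float = 0.3,
                   barrier_height: float = 25.0,
                   barrier_width: float = 0.5) -> ModelPotential:
    """Build a :class:`ModelPotential` with validated parameters.

    The result is an even function of z with bulk level exactly 0, two
    symmetric minima of depth ``well_depth`` at +/- ``well_position`` and a
    central barrier of height ``barrier_height`` at z = 0.
    """
    return ModelPotential(well_depth=well_depth,
                          well_position=well_position,
                          well_width=well_width,
                          barrier_height=barrier_height,
                          barrier_width=barrier_width)
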