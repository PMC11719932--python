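"""Closed-form links between 3D solution concentration and 2D surface counts.

The mean centre-to-centre spacing of particles in solution is taken as the
edge of the volume each particle occupies on average (simple-cubic
convention):

    spacing = (N_A · C)^(−1/3),   C in particles per nm³

which gives 1.18 nm at 1 M and 1180 nm at 1 nM — a thousand-fold spacing
change for a billion-fold concentration change.  Surface counts convert to
densities with Poisson precision: a count of k carries a relative standard
error of 1/√k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ValidationError

AVOGADRO = 6.02214076e23  # particles per mol (exact, SI 2019)
_NM3_PER_L = 1e24
_NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class ConcentrationSpec:
    """A molar concentration; ``molarity`` in mol/L, must be positive."""

    molarity: float

    def __post_init__(self) -> None:
        if not (self.molarity > 0):
            raise ValidationError("molarity must be positive")

    @property
    def number_density_nm3(self) -> float:
        """Particles per nm³."""
        return self.molarity * AVOGADRO / _NM3_PER_L


def spacing_from_concentration(c: ConcentrationSpec | float) -> float:
    """Mean inter-particle spacing (nm) in a solution of concentration ``c``.

    Accepts a :class:`ConcentrationSpec` or a bare molarity in mol/L.
    """
    if not isinstance(c, ConcentrationSpec):
        c = ConcentrationSpec(float(c))
    return c.number_density_nm3 ** (-1.0 / 3.0)


def surface_density_estimate(total_count: int, total_area_nm2: float
                             ) -> tuple[float, float]:
    """Surface density (particles per µm²) and its Poisson relative SE.

    Returns ``(density_per_um2, relative_se)`` where the relative standard
    error is 1/√count.  A zero count yields density 0 with SE ``nan``
    (undefined).
    """
    if total_count < 0:
        raise ValidationError("total_count must be non-negative")
    if not (total_area_nm2 > 0):
        raise ValidationError("total_area must be positive")
    density = total_count / total_area_nm2 * _NM2_PER_UM2
    if total_count == 0:
        return 0.0, float("nan")
    return density, 1.0 / np.sqrt(total_count)
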