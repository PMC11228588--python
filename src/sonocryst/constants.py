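"""Physical constants, atomic weights, and molecular parameters.

All classical-nucleation-theory formulas in :mod:`sonocryst.cnt` pull the
Boltzmann constant and Avogadro number from :data:`CONSTANTS`; internal units
are strict SI (J, m, K, s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "ATOMIC_WEIGHTS",
    "MolecularParams",
    "molecular_weight_from_formula",
    "molecular_volume_from_density",
    "SPEED_OF_LIGHT_NM_PER_PS",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA values used throughout the CNT formulas (immutable)."""

    boltzmann: float = 1.380649e-23  # J/K (exact, SI 2019)
    avogadro: float = 6.02214076e23  # 1/mol (exact, SI 2019)


CONSTANTS = PhysicalConstants()

#: Speed of light in nm/ps, used when deriving the field angular frequency
#: from a wavelength (omega = 2*pi*c/lambda).
SPEED_OF_LIGHT_NM_PER_PS = 299792.458 / 1e3  # 299.792458 nm/ps

#: Conventional IUPAC standard atomic weights (g/mol). Only the elements of
#: the solute and solvents of interest are tabulated.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.00794,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "Na": 22.98976928,
    "P": 30.973762,
    "S": 32.065,
}


def molecular_weight_from_formula(formula: dict[str, int]) -> float:
    """Molecular weight (g/mol) from an element -> count map.

    >>> round(molecular_weight_from_formula({"C": 6, "H": 14, "O": 12, "P": 2}), 2)
    340.12
    """
    try:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - message check only
        raise KeyError(f"no atomic weight tabulated for element {exc}") from None


def molecular_volume_from_density(molecular_weight: float, density_g_per_cm3: float) -> float:
    """Molecular volume v (m^3/molecule) from MW (g/mol) and crystal density.

    v = MW / (rho * N_A), converted from cm^3 to m^3.
    """
    if molecular_weight <= 0 or density_g_per_cm3 <= 0:
        raise ValueError("molecular weight and density must be positive")
    v_cm3 = molecular_weight / (density_g_per_cm3 * CONSTANTS.avogadro)
    return v_cm3 * 1e-6


@dataclass(frozen=True)
class MolecularParams:
    """Solute molecular parameters feeding the CNT formulas.

    Parameters
    ----------
    molecular_volume : float
        Volume per molecule, m^3 (symbol v in the CNT relations).
    molecular_weight : float, optional
        g/mol; if ``formula`` is given the two must agree within 0.05 g/mol.
    formula : dict, optional
        Element -> count map.
    """

    molecular_volume: float
    molecular_weight: float | None = None
    formula: dict[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.molecular_volume <= 0:
            raise ValueError("molecular_volume must be positive")
        if self.formula is not None:
            mw = molecular_weight_from_formula(self.formula)
            if self.molecular_weight is None:
                object.__setattr__(self, "molecular_weight", mw)
            elif not math.isclose(self.molecular_weight, mw, abs_tol=0.05):
                raise ValueError(
                    f"molecular_weight {self.molecular_weight} inconsistent with "
                    f"formula ({mw:.4f} g/mol)"
                )
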