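"""Association/interaction free energies and the negative-cooperativity /
two-different-sites equivalence mapping.

Free energies use a 1 uM standard state, so the numeric values of the
intrinsic association constants (in uM^-1) enter the logarithms directly:
Delta_G_assoc = -RT ln(K_o * c_std) is 0 kJ/mol for K_o = 1 uM^-1.

At equilibrium, two identical sites with negative cooperativity (K_o,
omega < 1) and two different independent sites (K_o1, K_o2) produce the
same binding polynomial when

    K_o1 + K_o2 = 2 K_o      and      K_o1 K_o2 = omega K_o^2,

i.e. K_o1,2 = K_o (1 +/- sqrt(1 - omega)).  For omega > 1 the roots are
complex, so a positively cooperative isotherm can never be mistaken for two
different sites; for omega = 1 both roots coincide with K_o (identical
independent sites).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ThermoContext", "EquivalenceResult", "ThermoError", "EquivalenceError",
    "assoc_free_energy", "interaction_free_energy",
    "equivalent_two_sites", "equivalent_cooperative",
]

#: gas constant in kJ mol^-1 K^-1
R_KJ = 8.314e-3


class ThermoError(ValueError):
    """Invalid thermodynamic input."""


class EquivalenceError(ThermoError):
    """No physically meaningful equivalent model exists."""


@dataclass(frozen=True)
class ThermoContext:
    """Temperature, gas constant and standard concentration.

    ``c_std`` (uM) makes association constants dimensionless inside
    logarithms; the default 1 uM matches the unit convention of the rate
    coefficients.
    """

    temperature: float = 298.15   # K
    r_gas: float = R_KJ           # kJ mol^-1 K^-1
    c_std: float = 1.0            # uM

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ThermoError("temperature must be positive")
        if self.r_gas <= 0 or self.c_std <= 0:
            raise ThermoError("r_gas and c_std must be positive")

    @property
    def rt(self) -> float:
        return self.r_gas * self.temperature


@dataclass(frozen=True)
class EquivalenceResult:
    """Outcome of mapping between the two equilibrium-equivalent models."""
    direction: str            # "cooperative_to_two_sites" or the reverse
    k_o: float
    omega: float
    k_o1: float
    k_o2: float


def assoc_free_energy(k_on: float, k_off: float,
                      ctx: ThermoContext | None = None) -> float:
    """Standard association free energy -RT ln(K c_std) in kJ/mol, with
    K = k_on / k_off taken from the kinetic coefficients."""
    ctx = ctx or ThermoContext()
    if k_on <= 0 or k_off <= 0:
        raise ThermoError("rate coefficients must be strictly positive")
    return -ctx.rt * math.log((k_on / k_off) * ctx.c_std)


def interaction_free_energy(omega: float,
                            ctx: ThermoContext | None = None) -> float:
    """Gibbs free energy of interaction between sites, -RT ln(omega):
    zero for independent sites, negative for positive cooperativity and
    positive for negative cooperativity.  Independent of K_o."""
    ctx = ctx or ThermoContext()
    if omega <= 0:
        raise ThermoError("omega must be strictly positive")
    return -ctx.rt * math.log(omega)


def equivalent_two_sites(k_o: float, omega: float) -> tuple[float, float]:
    """Intrinsic constants (K_o1, K_o2) of the two-different-sites model
    equilibrium-equivalent to (K_o, omega).

    Only defined for omega <= 1; omega > 1 yields complex roots with no
    physical meaning and raises :class:`EquivalenceError`.
    """
    if k_o <= 0 or omega <= 0:
        raise ThermoError("k_o and omega must be strictly positive")
    if omega > 1.0:
        raise EquivalenceError(
            f"omega={omega:g} > 1: the equivalent two-site constants are "
            "complex, so a positively cooperative isotherm has no "
            "two-different-sites counterpart")
    root = math.sqrt(1.0 - omega)
    return k_o * (1.0 + root), k_o * (1.0 - root)


def equivalent_cooperative(k_o1: float, k_o2: float) -> tuple[float, float]:
    """Cooperative-model parameters (K_o, omega) equilibrium-equivalent to
    two different independent sites; omega <= 1 always (AM-GM), with
    omega = 1 exactly when the two constants coincide."""
    if k_o1 <= 0 or k_o2 <= 0:
        raise ThermoError("site constants must be strictly positive")
    k_o = 0.5 * (k_o1 + k_o2)
    omega = (k_o1 * k_o2) / (k_o * k_o)
    return k_o, omega
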