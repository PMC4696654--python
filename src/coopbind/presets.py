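"""Built-in simulation scenarios and synthetic-data utilities.

Each preset encodes one of the canonical study conditions of the two-site
binding analysis: a positively cooperative macromolecule (``fig3``), sweeps
of the cooperativity factor and of the intrinsic affinity (``fig4_main``,
``fig4_inset``), the equilibrium-equivalent negative-cooperativity /
two-different-sites pair (``fig5``, ``fig6``), and the hidden-site scenario
under strong negative cooperativity at moderate and at very high ligand
concentrations (``fig7a``, ``fig7b``).  Total macromolecule is 1 uM and all
dissociation coefficients are 1 s^-1 throughout; ligand grids are
log-spaced at 25 points per decade over the stated ranges.

``add_noise`` injects seeded Gaussian noise on binding densities for
fitting/recovery experiments; the simulations themselves are deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .kinetics import RateConstants, SimulationConfig
from .isotherms import ligand_grid

logger = logging.getLogger("coopbind")

__all__ = ["ScenarioPreset", "PresetError", "load_preset", "PRESET_IDS",
           "add_noise", "provenance_record"]


class PresetError(KeyError):
    """Unknown scenario preset id."""


@dataclass(frozen=True)
class ScenarioPreset:
    """A fully specified simulation scenario.

    ``rates`` is the primary rate set; ``rates_alt`` carries the matched
    two-different-sites parameterization for the model-comparison scenarios.
    ``sweep`` holds the (name, values) pair for parameter-sweep scenarios,
    where ``rates_for(v)`` builds the rate set at each swept value.
    """

    id: str
    description: str
    m_total: float
    l_totals: np.ndarray
    rates: RateConstants | None = None
    rates_alt: RateConstants | None = None
    k_o: float | None = None
    omega: float | None = None
    sweep: tuple[str, np.ndarray] | None = None
    rates_for: Callable[[float], RateConstants] | None = field(
        default=None, repr=False)
    grid_for: Callable[[float], np.ndarray] | None = field(
        default=None, repr=False)
    config: SimulationConfig = field(default_factory=SimulationConfig)


def _fig3() -> ScenarioPreset:
    return ScenarioPreset(
        id="fig3",
        description="positive cooperativity: K_o = 1 uM^-1, omega = 10",
        m_total=1.0, l_totals=ligand_grid(1.0),
        rates=RateConstants.cooperative(1.0, 10.0), k_o=1.0, omega=10.0)


def _coop_grid(k_o: float, omega: float, m_total: float = 1.0) -> np.ndarray:
    """Total-ligand grid for a cooperative sweep scenario.

    Spans two decades around BOTH intrinsic dissociation constants (1/k_o
    for the first binding step, 1/(omega k_o) for the second) in free
    ligand, and compensates each total for the ligand expected to be bound
    at equilibrium -- without this, tight binders (k_o m_total >> 1)
    deplete the free ligand and the isotherm never saturates.
    """
    from .isotherms import CooperativeTwoSite
    kds = (1.0 / k_o, 1.0 / (omega * k_o))
    free = ligand_grid(k_o, l_min=0.01 * min(kds), l_max=100.0 * max(kds))
    bound = m_total * CooperativeTwoSite(k_o, omega).binding_density(free)
    return free + bound


def _fig4_main() -> ScenarioPreset:
    omegas = np.logspace(-2, 2, 9)
    return ScenarioPreset(
        id="fig4_main",
        description="Hill coefficient vs interaction free energy: K_o = 1, "
                    "omega swept 0.01-100",
        m_total=1.0, l_totals=ligand_grid(1.0), k_o=1.0,
        sweep=("omega", omegas),
        rates_for=lambda w: RateConstants.cooperative(1.0, w),
        grid_for=lambda w: _coop_grid(1.0, w))


def _fig4_inset() -> ScenarioPreset:
    k_os = np.logspace(-2, 2, 9)
    return ScenarioPreset(
        id="fig4_inset",
        description="Hill coefficient vs association free energy: omega = 8, "
                    "K_o swept 0.01-100 uM^-1",
        m_total=1.0, l_totals=ligand_grid(1.0), omega=8.0,
        sweep=("k_o", k_os),
        rates_for=lambda k: RateConstants.cooperative(k, 8.0),
        grid_for=lambda k: _coop_grid(k, 8.0))


def _fig5() -> ScenarioPreset:
    return ScenarioPreset(
        id="fig5",
        description="equilibrium-equivalent pair: cooperative K_o = 0.55, "
                    "omega = 0.33058 vs sites K_o1 = 1, K_o2 = 0.1 "
                    "(off-rates 1 s^-1)",
        m_total=1.0,
        l_totals=ligand_grid(1.0, l_min=0.01, l_max=300.0),
        rates=RateConstants.cooperative(0.55, 0.33058),
        rates_alt=RateConstants.two_different_sites(1.0, 0.1),
        k_o=0.55, omega=0.33058)


def _fig6() -> ScenarioPreset:
    p = _fig5()
    return ScenarioPreset(
        id="fig6",
        description="pre-equilibrium comparison of the fig5 pair at "
                    "[L]0 = 5, 10, 25, 50, 100, 300 uM",
        m_total=1.0, l_totals=np.array([5.0, 10.0, 25.0, 50.0, 100.0, 300.0]),
        rates=p.rates, rates_alt=p.rates_alt, k_o=p.k_o, omega=p.omega)


def _fig7a() -> ScenarioPreset:
    return ScenarioPreset(
        id="fig7a",
        description="hidden site: K_o = 1 uM^-1, omega = 0.02, ligand "
                    "totals up to 6 uM",
        m_total=1.0, l_totals=ligand_grid(1.0, l_min=0.01, l_max=6.0),
        rates=RateConstants.cooperative(1.0, 0.02), k_o=1.0, omega=0.02)


def _fig7b() -> ScenarioPreset:
    return ScenarioPreset(
        id="fig7b",
        description="hidden site unmasked: same rates, ligand totals up to "
                    "300 mM (3e5 uM)",
        m_total=1.0, l_totals=ligand_grid(1.0, l_min=0.01, l_max=3.0e5),
        rates=RateConstants.cooperative(1.0, 0.02), k_o=1.0, omega=0.02)


_PRESETS: dict[str, Callable[[], ScenarioPreset]] = {
    "fig3": _fig3, "fig4_main": _fig4_main, "fig4_inset": _fig4_inset,
    "fig5": _fig5, "fig6": _fig6, "fig7a": _fig7a, "fig7b": _fig7b,
}

PRESET_IDS = tuple(sorted(_PRESETS))


def load_preset(preset_id: str) -> ScenarioPreset:
    """Return the named scenario preset; unknown ids raise
    :class:`PresetError` listing the valid choices."""
    try:
        return _PRESETS[preset_id]()
    except KeyError:
        raise PresetError(f"unknown preset {preset_id!r}; valid ids: "
                          f"{', '.join(PRESET_IDS)}") from None


def add_noise(values, sigma: float, seed: int):
    """Additive Gaussian noise on binding densities, reproducible per seed.

    ``sigma = 0`` returns the input unchanged (as a float array)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    arr = np.asarray(values, dtype=float)
    if sigma == 0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    return arr + rng.normal(0.0, sigma, size=arr.shape)


def provenance_record(preset: ScenarioPreset | None = None,
                      seed: int | None = None, **extra) -> dict:
    """JSON-serialisable record of run parameters for reproducibility."""
    from . import __version__
    rec: dict = {"package": "coopbind", "version": __version__, "seed": seed}
    if preset is not None:
        rec["preset"] = preset.id
        rec["description"] = preset.description
        rec["m_total_uM"] = preset.m_total
        rec["l_totals_uM"] = np.asarray(preset.l_totals).tolist()
        if preset.k_o is not None:
            rec["k_o_uM_inv"] = preset.k_o
        if preset.omega is not None:
            rec["omega"] = preset.omega
    rec.update(extra)
    json.dumps(rec)   # fail early if not serialisable
    return rec
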