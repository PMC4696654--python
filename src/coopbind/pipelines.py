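"""End-to-end workflows: simulate a scenario, build its isotherm, analyze.

These functions chain the lower-level modules the way the method is meant
to be run: integrate the time courses for a grid of total ligand
concentrations, harvest the equilibrium points into an isotherm, then hand
the isotherm to the Hill analysis or the fitting routines.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .kinetics import RateConstants, SimulationConfig, simulate_grid
from .isotherms import Isotherm, isotherm_from_timecourses, free_ligand_span
from .hill import analyze_isotherm, estimate_site_number
from .thermo import (ThermoContext, assoc_free_energy,
                     interaction_free_energy)
from .fitting import paired_timecourses, fit_isotherm, classify_kinetics
from .presets import ScenarioPreset, load_preset

logger = logging.getLogger("coopbind")

__all__ = ["simulate_isotherm", "preset_isotherm", "run_preset"]


def simulate_isotherm(rates: RateConstants, m_total: float,
                      l_totals: Sequence[float],
                      config: SimulationConfig | None = None,
                      meta: dict | None = None) -> Isotherm:
    """Equilibrium isotherm from one simulated time course per [L]0."""
    tcs = simulate_grid(rates, m_total, l_totals, config)
    return isotherm_from_timecourses(tcs, meta=meta)


def preset_isotherm(preset: str | ScenarioPreset,
                    alt: bool = False) -> Isotherm:
    """Simulated equilibrium isotherm of a scenario preset (``alt=True``
    selects the matched two-different-sites parameterization)."""
    p = load_preset(preset) if isinstance(preset, str) else preset
    rates = p.rates_alt if alt else p.rates
    if rates is None:
        raise ValueError(f"preset {p.id!r} has no "
                         f"{'alternative' if alt else 'primary'} rate set")
    return simulate_isotherm(rates, p.m_total, p.l_totals, p.config,
                             meta={"preset": p.id, "alt": alt})


def run_preset(preset_id: str, seed: int | None = None) -> dict:
    """Run a preset scenario end to end and return its headline numbers.

    The returned dictionary is JSON-serialisable (arrays as lists) and
    holds, per scenario: the isotherm, Hill analysis, fits, or discrepancy
    summaries that the scenario is about.
    """
    p = load_preset(preset_id)
    out: dict = {"preset": p.id, "description": p.description}

    if p.id in ("fig3", "fig7a", "fig7b"):
        iso = preset_isotherm(p)
        out["isotherm"] = {"free_l_uM": iso.free_ligand.tolist(),
                           "n_avg": iso.n_avg.tolist()}
        out["n_sites_estimate"] = estimate_site_number(iso)
        if p.id == "fig3":
            hr = analyze_isotherm(iso)
            out["hill"] = {"n_h": hr.n_h, "a0": hr.a0, "a1": hr.a1,
                           "a2": hr.a2, "a3": hr.a3, "operator": hr.operator}
            out["span_ratio"] = free_ligand_span(iso).ratio
        if p.id == "fig7a":
            fit = fit_isotherm(iso, model="hyperbola")
            out["hyperbola_fit"] = {"n_max": fit.params["n_max"],
                                    "k_uM_inv": fit.params["k"],
                                    "rss": fit.rss}
            hr = analyze_isotherm(iso)
            out["hill"] = {"n_h": hr.n_h, "operator": hr.operator}
        return out

    if p.id in ("fig4_main", "fig4_inset"):
        name, values = p.sweep
        ctx = ThermoContext()
        rows = []
        for v in values:
            rates = p.rates_for(v)
            grid = p.grid_for(v) if p.grid_for is not None else p.l_totals
            iso = simulate_isotherm(rates, p.m_total, grid, p.config,
                                    meta={"preset": p.id, name: float(v)})
            hr = analyze_isotherm(iso)
            row = {name: float(v), "n_h": hr.n_h}
            if name == "omega":
                row["dg_int_kj_mol"] = interaction_free_energy(v, ctx)
            else:
                row["dg_assoc_kj_mol"] = assoc_free_energy(v, 1.0, ctx)
            rows.append(row)
        out["sweep"] = rows
        return out

    if p.id == "fig5":
        iso_coop = preset_isotherm(p)
        iso_two = preset_isotherm(p, alt=True)
        out["isotherm_cooperative"] = {
            "free_l_uM": iso_coop.free_ligand.tolist(),
            "n_avg": iso_coop.n_avg.tolist()}
        out["isotherm_two_sites"] = {
            "free_l_uM": iso_two.free_ligand.tolist(),
            "n_avg": iso_two.n_avg.tolist()}
        delta = np.interp(iso_coop.free_ligand, iso_two.free_ligand,
                          iso_two.n_avg) - iso_coop.n_avg
        out["max_equilibrium_delta_n"] = float(np.max(np.abs(delta)))
        return out

    if p.id == "fig6":
        traces = paired_timecourses(p.k_o, p.omega, p.l_totals, p.m_total)
        out["traces"] = [{"l_total_uM": tr.l_total, "t_max_s": tr.t_max,
                          "delta_max": tr.delta_max} for tr in traces]
        return out

    raise AssertionError(f"unhandled preset {p.id!r}")
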