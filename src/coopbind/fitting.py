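"""Pre-equilibrium model discrimination and nonlinear fitting.

Negative cooperativity and two different site classes produce identical
equilibrium isotherms whenever the equivalence relations hold, but their
binding *time courses* differ.  This module simulates matched model pairs on
identical time grids (``paired_timecourses``), fits equilibrium isotherms
and kinetic time courses by nonlinear least squares (lmfit), selects models
by AICc or an extra-sum-of-squares F-test, and classifies single time
courses as mono- or bi-exponential -- the kinetic signature that unmasks a
hidden site at high ligand concentration.

Kinetic fits honour the experimental workflow: the two macroscopic
association constants measured at equilibrium are imposed exactly by
reparameterization (they eliminate two degrees of freedom), and only the
dissociation rate scales remain free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import lmfit
from scipy import stats

from .kinetics import (RateConstants, SimulationConfig, TimeCourse,
                       KineticsError, simulate_binding, _auto_step,
                       _slow_rate, _rk4_bound_at_times)
from .isotherms import Isotherm, IsothermError
from .thermo import equivalent_two_sites, EquivalenceError

logger = logging.getLogger("coopbind")

__all__ = [
    "DiscrepancyTrace", "FitResult", "FittingError",
    "paired_timecourses", "fit_isotherm", "fit_kinetics",
    "compare_fits", "classify_kinetics",
]


class FittingError(ValueError):
    """Fitting or discrimination failure."""


# --------------------------------------------------------------------------
# Matched-pair pre-equilibrium comparison
# --------------------------------------------------------------------------

@dataclass
class DiscrepancyTrace:
    """Difference trace delta_n(t) = <n>_coop(t) - <n>_diff_sites(t) for one
    total ligand concentration; ``delta_max`` is the signed value of largest
    magnitude and ``t_max`` its time."""

    l_total: float
    times: np.ndarray
    delta_n: np.ndarray
    t_max: float
    delta_max: float


def paired_timecourses(k_o: float, omega: float,
                       l_total_grid: Sequence[float], m_total: float = 1.0,
                       base_off_rate: float = 1.0,
                       config: SimulationConfig | None = None,
                       ) -> list[DiscrepancyTrace]:
    """Simulate the matched cooperative / two-different-sites pair.

    The two parameterizations are built so the equivalence relations hold
    exactly (all dissociation coefficients equal to ``base_off_rate``), then
    both models are integrated on identical step and recording grids for
    each total ligand concentration.  Requires omega <= 1 (otherwise no
    two-sites counterpart exists and the equivalence error propagates).
    """
    k_o1, k_o2 = equivalent_two_sites(k_o, omega)   # raises for omega > 1
    coop = RateConstants.cooperative(k_o, omega, base_off_rate)
    if k_o2 <= 0:
        raise EquivalenceError("omega must be > 0 and the resulting "
                               "K_o2 positive")
    two = RateConstants.two_different_sites(k_o1, k_o2, base_off_rate)
    base = config or SimulationConfig()
    traces = []
    for l0 in l_total_grid:
        h = min(_auto_step(coop, m_total, l0), _auto_step(two, m_total, l0))
        if base.step_size != "auto":
            h = float(base.step_size)
        slow = min(_slow_rate(coop, m_total, l0), _slow_rate(two, m_total, l0))
        rec = max(1, int(round(0.02 / (slow * h))))
        cfg = SimulationConfig(step_size=h, record_every=rec,
                               convergence_threshold=base.convergence_threshold,
                               max_time=base.max_time, window=base.window)
        tc_c = simulate_binding(coop, m_total, l0, cfg)
        tc_t = simulate_binding(two, m_total, l0, cfg)
        # the final record of each run sits at its own stopping time, so
        # compare only the common prefix of the shared recording grid
        n = min(tc_c.times.size, tc_t.times.size)
        mism = np.nonzero(~np.isclose(tc_c.times[:n], tc_t.times[:n],
                                      rtol=1e-12, atol=0.0))[0]
        if mism.size:
            n = int(mism[0])
        if n < 2:
            raise FittingError("paired time grids failed to align")
        delta = tc_c.n_avg[:n] - tc_t.n_avg[:n]
        i = int(np.argmax(np.abs(delta)))
        traces.append(DiscrepancyTrace(
            l_total=float(l0), times=tc_c.times[:n], delta_n=delta,
            t_max=float(tc_c.times[i]), delta_max=float(delta[i])))
    return traces


# --------------------------------------------------------------------------
# Fit results and model selection
# --------------------------------------------------------------------------

@dataclass
class FitResult:
    """Nonlinear least-squares fit summary.

    ``params`` holds point estimates, ``stderr`` the standard errors from
    the Jacobian (None where unavailable); ``aicc`` is the small-sample
    corrected Akaike information criterion."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float | None]
    rss: float
    aicc: float
    converged: bool
    n_obs: int
    n_free: int
    message: str = ""
    extras: dict = field(default_factory=dict)

    def __str__(self) -> str:
        pars = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return (f"FitResult({self.model}: {pars}; rss={self.rss:.3g}, "
                f"AICc={self.aicc:.2f}, converged={self.converged})")


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood up to constants; k counts the noise variance
    kk = k + 1
    if n - kk - 1 <= 0:
        return math.inf
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * kk + 2 * kk * (kk + 1) / (n - kk - 1)


def compare_fits(a: FitResult, b: FitResult,
                 method: str = "aicc", alpha: float = 0.01) -> FitResult:
    """Select between two fits of the same data.

    ``method="aicc"`` picks the lower AICc.  ``method="ftest"`` applies the
    extra-sum-of-squares F-test (the fits must be nested, ``a`` the simpler
    model) and keeps ``a`` unless the improvement is significant at
    ``alpha``.
    """
    if a.n_obs != b.n_obs:
        raise FittingError("fits describe different data sets")
    if method == "aicc":
        return a if a.aicc <= b.aicc else b
    if method == "ftest":
        simple, complex_ = (a, b) if a.n_free <= b.n_free else (b, a)
        df_s = simple.n_obs - simple.n_free
        df_c = complex_.n_obs - complex_.n_free
        if df_s <= df_c or df_c <= 0:
            raise FittingError("F-test requires nested fits with spare "
                               "degrees of freedom")
        if simple.rss <= complex_.rss:
            return simple
        f = ((simple.rss - complex_.rss) / (df_s - df_c)) / \
            (complex_.rss / df_c) if complex_.rss > 0 else math.inf
        p = 1.0 - stats.f.cdf(f, df_s - df_c, df_c)
        return complex_ if p < alpha else simple
    raise FittingError(f"unknown selection method {method!r}")


# --------------------------------------------------------------------------
# Isotherm fitting
# --------------------------------------------------------------------------

def _iso_arrays(iso) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(iso, Isotherm):
        return iso.free_ligand, iso.n_avg
    l, n = iso
    return np.asarray(l, dtype=float), np.asarray(n, dtype=float)


_ISO_MODELS = {
    "hyperbola": ("n_max", "k"),
    "single_site": ("k_o",),
    "identical_independent": ("k_o",),
    "cooperative": ("k_o", "omega"),
    "two_sites": ("k_o1", "k_o2"),
    "hill": ("n_max", "k", "n_h"),
}


def _iso_predict(model: str, p, l: np.ndarray) -> np.ndarray:
    x = l
    if model == "hyperbola":
        return p["n_max"] * p["k"] * x / (1.0 + p["k"] * x)
    if model == "single_site":
        return p["k_o"] * x / (1.0 + p["k_o"] * x)
    if model == "identical_independent":
        return 2.0 * p["k_o"] * x / (1.0 + p["k_o"] * x)
    if model == "cooperative":
        kx = p["k_o"] * x
        z = 1.0 + 2.0 * kx + p["omega"] * kx * kx
        return (2.0 * kx + 2.0 * p["omega"] * kx * kx) / z
    if model == "two_sites":
        x1, x2 = p["k_o1"] * x, p["k_o2"] * x
        return x1 / (1.0 + x1) + x2 / (1.0 + x2)
    if model == "hill":
        kx = p["k"] * np.power(x, p["n_h"])
        return p["n_max"] * kx / (1.0 + kx)
    raise FittingError(f"unknown isotherm model {model!r}; choose from "
                       f"{sorted(_ISO_MODELS)}")


def _iso_initial(model: str, l: np.ndarray, n: np.ndarray) -> dict[str, float]:
    n_max = float(n.max())
    half = 0.5 * n_max
    i = int(np.searchsorted(n, half))
    l_half = float(l[min(i, l.size - 1)])
    k0 = 1.0 / max(l_half, 1e-12)
    return {"n_max": max(n_max, 1e-3), "k": k0, "k_o": k0, "omega": 1.0,
            "k_o1": 2.0 * k0, "k_o2": 0.5 * k0, "n_h": 1.0}


def fit_isotherm(iso, model: str = "hyperbola",
                 fixed: dict[str, float] | None = None,
                 initial: dict[str, float] | None = None) -> FitResult:
    """Least-squares fit of a closed-form binding model to an isotherm.

    ``iso`` is an :class:`~coopbind.isotherms.Isotherm` or a ``(free_l,
    n_avg)`` pair of arrays (noisy data need not be monotone).  ``fixed``
    pins parameters; ``initial`` overrides the starting guesses.  Standard
    errors come from the Jacobian at the optimum.
    """
    l, n = _iso_arrays(iso)
    if model not in _ISO_MODELS:
        raise FittingError(f"unknown isotherm model {model!r}; choose from "
                           f"{sorted(_ISO_MODELS)}")
    names = _ISO_MODELS[model]
    fixed = fixed or {}
    n_free = sum(1 for nm in names if nm not in fixed)
    if l.size < 2 * n_free:
        raise FittingError(f"need >= {2 * n_free} points to fit {model} "
                           f"({n_free} free parameters)")
    init = _iso_initial(model, l, n)
    init.update(initial or {})
    pars = lmfit.Parameters()
    for nm in names:
        if nm in fixed:
            pars.add(nm, value=float(fixed[nm]), vary=False)
        else:
            pars.add(nm, value=float(init[nm]), min=1e-12)

    def resid(p):
        vals = {nm: p[nm].value for nm in names}
        return _iso_predict(model, vals, l) - n

    out = lmfit.minimize(resid, pars, method="leastsq")
    params = {nm: float(out.params[nm].value) for nm in names}
    stderr = {nm: (float(out.params[nm].stderr)
                   if out.params[nm].stderr is not None else None)
              for nm in names}
    rss = float(np.sum(np.asarray(out.residual) ** 2))
    return FitResult(model=model, params=params, stderr=stderr, rss=rss,
                     aicc=_aicc(rss, l.size, n_free),
                     converged=bool(out.success), n_obs=int(l.size),
                     n_free=n_free, message=str(out.message))


# --------------------------------------------------------------------------
# Constrained kinetic fitting
# --------------------------------------------------------------------------

def _rates_from_constraints(model: str, k1_macro: float, k2_macro: float,
                            off: dict[str, float]) -> RateConstants:
    """Build the full microscopic rate set from the two macroscopic
    association constants plus the free dissociation scales."""
    if model == "cooperative":
        k_o = 0.5 * k1_macro
        omega = 4.0 * k2_macro / k1_macro
        km, km_occ = off["km_empty"], off["km_occupied"]
        return RateConstants(
            k1=k_o * km, k2=k_o * km,
            k1_given_2=omega * k_o * km_occ, k2_given_1=omega * k_o * km_occ,
            km1=km, km2=km, km1_given_2=km_occ, km2_given_1=km_occ)
    if model == "two_sites":
        # K1m = Ko1 + Ko2, K2m = Ko1 Ko2 / (Ko1 + Ko2)
        disc = k1_macro * k1_macro - 4.0 * k1_macro * k2_macro
        if disc < 0:
            raise FittingError(
                "constraints are infeasible for the two-sites model: "
                f"K1={k1_macro:g}, K2={k2_macro:g} imply complex site "
                "constants")
        root = math.sqrt(disc)
        k_o1 = 0.5 * (k1_macro + root)
        k_o2 = 0.5 * (k1_macro - root)
        km1, km2 = off["km_site1"], off["km_site2"]
        return RateConstants(
            k1=k_o1 * km1, k2=k_o2 * km2,
            k1_given_2=k_o1 * km1, k2_given_1=k_o2 * km2,
            km1=km1, km2=km2, km1_given_2=km1, km2_given_1=km2)
    raise FittingError(f"unknown kinetic model {model!r}; choose "
                       "'cooperative' or 'two_sites'")


_KIN_FREE = {"cooperative": ("km_empty", "km_occupied"),
             "two_sites": ("km_site1", "km_site2")}


def _observations(tcs) -> list[tuple[np.ndarray, np.ndarray, float]]:
    obs = []
    for item in tcs:
        if isinstance(item, TimeCourse):
            obs.append((item.times, item.n_avg, item.l_total))
        else:
            t, n, l0 = item
            obs.append((np.asarray(t, dtype=float),
                        np.asarray(n, dtype=float), float(l0)))
    return obs


def predict_kinetics(rates: RateConstants, m_total: float, l_total: float,
                     times: np.ndarray) -> np.ndarray:
    """Model binding density <n>(t) at the requested times (fixed-step RK4
    with linear interpolation onto the time grid)."""
    h = _auto_step(rates, m_total, l_total)
    y0 = np.array([m_total, 0.0, 0.0, 0.0, l_total])
    order = np.argsort(times, kind="stable")
    ts = np.asarray(times, dtype=float)[order]
    bound = _rk4_bound_at_times(y0, rates.as_array(), h, ts)
    out = np.empty_like(bound)
    out[order] = bound
    return out / m_total


def fit_kinetics(tcs, model: str,
                 equilibrium_constraints: tuple[float, float],
                 m_total: float,
                 initial_off_rates: dict[str, float] | None = None,
                 ) -> FitResult:
    """Fit a kinetic binding model to observed <n>(t) curves under exact
    equilibrium constraints.

    ``tcs`` is a sequence of :class:`TimeCourse` objects or ``(times,
    n_avg, l_total)`` tuples sharing ``m_total``;
    ``equilibrium_constraints`` are the two macroscopic association
    constants (uM^-1) from the stage-1 isotherm analysis.  They are imposed
    by reparameterization -- the association coefficients are derived from
    the free dissociation scales -- so the constraints hold exactly at every
    iteration, and each model keeps two free parameters.
    """
    if model not in _KIN_FREE:
        raise FittingError(f"unknown kinetic model {model!r}; choose "
                           "'cooperative' or 'two_sites'")
    k1_macro, k2_macro = equilibrium_constraints
    if k1_macro <= 0 or k2_macro <= 0:
        raise FittingError("macroscopic constants must be positive")
    # fail fast on infeasible constraints (e.g. complex site constants)
    probe = dict.fromkeys(_KIN_FREE[model], 1.0)
    _rates_from_constraints(model, k1_macro, k2_macro, probe)

    obs = _observations(tcs)
    names = _KIN_FREE[model]
    init = dict.fromkeys(names, 1.0)
    init.update(initial_off_rates or {})
    pars = lmfit.Parameters()
    for nm in names:
        pars.add(nm, value=float(init[nm]), min=1e-10)

    def resid(p):
        off = {nm: p[nm].value for nm in names}
        rates = _rates_from_constraints(model, k1_macro, k2_macro, off)
        parts = [predict_kinetics(rates, m_total, l0, t) - n
                 for t, n, l0 in obs]
        return np.concatenate(parts)

    out = lmfit.minimize(resid, pars, method="leastsq")
    off = {nm: float(out.params[nm].value) for nm in names}
    rates = _rates_from_constraints(model, k1_macro, k2_macro, off)
    stderr = {nm: (float(out.params[nm].stderr)
                   if out.params[nm].stderr is not None else None)
              for nm in names}
    rss = float(np.sum(np.asarray(out.residual) ** 2))
    n_obs = sum(t.size for t, _, _ in obs)
    extras = {"rates": rates, "k1_macro": k1_macro, "k2_macro": k2_macro}
    return FitResult(model=model, params=off, stderr=stderr, rss=rss,
                     aicc=_aicc(rss, n_obs, len(names)),
                     converged=bool(out.success), n_obs=n_obs,
                     n_free=len(names), message=str(out.message),
                     extras=extras)


# --------------------------------------------------------------------------
# Mono- vs bi-exponential classification
# --------------------------------------------------------------------------

def classify_kinetics(times, n_avg, alpha: float = 0.01,
                      monotone_tol: float = 0.1) -> int:
    """Number of exponential phases (1 or 2) in a monotone binding trace.

    Fits A(1 - exp(-k t)) and the two-exponential extension, then applies
    the extra-sum-of-squares F-test: 2 is returned only when the second
    phase improves the fit significantly at ``alpha``.  Binding to a unique
    site under pseudo-first-order conditions is monoexponential, so a
    second phase flags an additional (possibly hidden) site.

    Traces that dip more than ``monotone_tol`` of their amplitude below
    their running maximum (overshoots, not mere noise jitter) are not
    association time courses and are rejected.
    """
    t = np.asarray(times, dtype=float)
    n = np.asarray(n_avg, dtype=float)
    if t.size < 8:
        raise FittingError("need >= 8 points to classify kinetics")
    span = max(n.max() - n.min(), 1e-300)
    if np.max(np.maximum.accumulate(n) - n) > monotone_tol * span:
        raise FittingError("non-monotone trace: classification supports "
                           "monotone association time courses only")
    amp = n[-1]
    # crude rate guess from the half-rise time
    i_half = int(np.searchsorted(n, 0.5 * amp))
    t_half = t[min(max(i_half, 1), t.size - 1)]
    k_guess = math.log(2.0) / max(t_half, 1e-30)

    p1 = lmfit.Parameters()
    p1.add("a", value=amp, min=0.0)
    p1.add("k", value=k_guess, min=1e-12)

    def r1(p):
        return p["a"].value * (1.0 - np.exp(-p["k"].value * t)) - n

    f1 = lmfit.minimize(r1, p1, method="leastsq")
    rss1 = float(np.sum(np.asarray(f1.residual) ** 2))
    if rss1 <= (1e-12 * span) ** 2 * t.size:
        return 1

    p2 = lmfit.Parameters()
    p2.add("a1", value=0.7 * amp, min=0.0)
    p2.add("k1", value=5.0 * k_guess, min=1e-12)
    p2.add("a2", value=0.3 * amp, min=0.0)
    p2.add("k2", value=0.2 * k_guess, min=1e-12)

    def r2(p):
        return (p["a1"].value * (1.0 - np.exp(-p["k1"].value * t))
                + p["a2"].value * (1.0 - np.exp(-p["k2"].value * t)) - n)

    f2 = lmfit.minimize(r2, p2, method="leastsq")
    rss2 = float(np.sum(np.asarray(f2.residual) ** 2))
    df1, df2 = t.size - 2, t.size - 4
    if rss2 >= rss1 or df2 <= 0:
        return 1
    f_stat = ((rss1 - rss2) / (df1 - df2)) / (rss2 / df2)
    p_val = 1.0 - stats.f.cdf(f_stat, df1 - df2, df2)
    return 2 if p_val < alpha else 1
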