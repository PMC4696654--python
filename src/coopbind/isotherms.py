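"""Closed-form equilibrium binding models and binding isotherms.

Every equilibrium model is expressed through its binding polynomial
(partition function) Z([L]); the binding density is the logarithmic
derivative <n> = dlnZ/dln[L].  For the two-site cooperative model

    Z = 1 + 2 K_o [L] + omega K_o^2 [L]^2,

for two different non-interacting sites

    Z = 1 + (K_o1 + K_o2) [L] + K_o1 K_o2 [L]^2,

and for a single site Z = 1 + K_o [L].  The Hill model is the
phenomenological two-parameter saturation curve theta = K L^nH / (1 + K L^nH).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .kinetics import TimeCourse, binding_density

logger = logging.getLogger("coopbind")

__all__ = [
    "SingleSite", "IdenticalIndependent", "CooperativeTwoSite",
    "TwoDifferentSites", "HillModel", "BindingModel", "Isotherm",
    "IsothermError", "SpanRangeError", "model_binding_density",
    "isotherm_from_timecourses", "isotherm_from_model", "ligand_grid",
    "free_ligand_span", "SpanResult",
]


class IsothermError(ValueError):
    """Invalid isotherm input or model parameters."""


class SpanRangeError(IsothermError):
    """The isotherm does not cover fractional saturations 0.1-0.9."""


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (math.isfinite(v) and v > 0):
            raise IsothermError(f"{name} must be strictly positive, got {v!r}")


# --------------------------------------------------------------------------
# Model variants
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleSite:
    """One binding site with intrinsic constant ``k_o`` (uM^-1)."""
    k_o: float
    n_sites: int = field(default=1, init=False)

    def __post_init__(self) -> None:
        _check_positive(k_o=self.k_o)

    def binding_density(self, l):
        l = _check_ligand(l)
        x = self.k_o * l
        return x / (1.0 + x)


@dataclass(frozen=True)
class IdenticalIndependent:
    """``n_sites`` identical, non-interacting sites (n_sites in {1, 2})."""
    k_o: float
    n_sites: int = 2

    def __post_init__(self) -> None:
        _check_positive(k_o=self.k_o)
        if self.n_sites not in (1, 2):
            raise IsothermError("n_sites must be 1 or 2")

    def binding_density(self, l):
        l = _check_ligand(l)
        x = self.k_o * l
        return self.n_sites * x / (1.0 + x)


@dataclass(frozen=True)
class CooperativeTwoSite:
    """Two identical sites with cooperativity factor ``omega``.

    omega = 1 reduces to identical independent sites; omega > 1 is positive
    and omega < 1 negative cooperativity.
    """
    k_o: float
    omega: float
    n_sites: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        _check_positive(k_o=self.k_o, omega=self.omega)

    def binding_density(self, l):
        l = _check_ligand(l)
        x = self.k_o * l
        z = 1.0 + 2.0 * x + self.omega * x * x
        return (2.0 * x + 2.0 * self.omega * x * x) / z


@dataclass(frozen=True)
class TwoDifferentSites:
    """Two independent sites with different intrinsic constants (uM^-1)."""
    k_o1: float
    k_o2: float
    n_sites: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        _check_positive(k_o1=self.k_o1, k_o2=self.k_o2)

    def binding_density(self, l):
        l = _check_ligand(l)
        x1 = self.k_o1 * l
        x2 = self.k_o2 * l
        return x1 / (1.0 + x1) + x2 / (1.0 + x2)


@dataclass(frozen=True)
class HillModel:
    """Phenomenological Hill saturation curve.

    ``k`` has units uM^-nH; ``binding_density`` returns n_sites * theta.
    """
    k: float
    n_h: float
    n_sites: int = 1

    def __post_init__(self) -> None:
        _check_positive(k=self.k, n_h=self.n_h)
        if self.n_sites not in (1, 2):
            raise IsothermError("n_sites must be 1 or 2")

    def theta(self, l):
        l = _check_ligand(l)
        x = self.k * np.power(l, self.n_h)
        return x / (1.0 + x)

    def binding_density(self, l):
        return self.n_sites * self.theta(l)


BindingModel = Union[SingleSite, IdenticalIndependent, CooperativeTwoSite,
                     TwoDifferentSites, HillModel]


def _check_ligand(l):
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise IsothermError("free ligand concentration must be non-negative")
    return l if l.ndim else float(l)


def model_binding_density(model: BindingModel, l):
    """Equilibrium binding density <n> of ``model`` at free ligand ``l`` (uM)."""
    return model.binding_density(l)


# --------------------------------------------------------------------------
# Isotherms
# --------------------------------------------------------------------------

@dataclass
class Isotherm:
    """Equilibrium (free ligand, binding density) pairs.

    ``free_ligand`` must be strictly increasing and ``n_avg`` non-decreasing
    within a small numerical tolerance; ``meta`` carries provenance (model
    parameters or simulation preset id).
    """

    free_ligand: np.ndarray
    n_avg: np.ndarray
    meta: dict = field(default_factory=dict)

    _MONO_TOL = 1e-9

    def __post_init__(self) -> None:
        self.free_ligand = np.asarray(self.free_ligand, dtype=float)
        self.n_avg = np.asarray(self.n_avg, dtype=float)
        if self.free_ligand.shape != self.n_avg.shape or self.free_ligand.ndim != 1:
            raise IsothermError("free_ligand and n_avg must be 1-D arrays of "
                                "equal length")
        if np.any(np.diff(self.free_ligand) <= 0):
            raise IsothermError("free_ligand must be strictly increasing")
        if np.any(self.n_avg < -self._MONO_TOL) or np.any(self.n_avg > 2 + 1e-6):
            raise IsothermError("n_avg must lie in [0, 2]")
        if np.any(np.diff(self.n_avg) < -self._MONO_TOL * max(1.0, self.n_avg.max())):
            raise IsothermError("n_avg must be non-decreasing in free_ligand")

    def __len__(self) -> int:
        return self.free_ligand.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"free_l_uM": self.free_ligand,
                             "n_avg": self.n_avg})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "Isotherm":
        df = pd.read_csv(path)
        return cls(df["free_l_uM"].to_numpy(), df["n_avg"].to_numpy(),
                   meta=dict(meta or {}, source=str(path)))


def isotherm_from_timecourses(tcs: Sequence[TimeCourse],
                              meta: dict | None = None) -> Isotherm:
    """Assemble an equilibrium isotherm, one point per converged time course.

    All courses must share rate constants and total macromolecule; a
    non-converged course raises an error naming its total ligand.
    """
    if not tcs:
        raise IsothermError("no time courses supplied")
    ref = tcs[0]
    for tc in tcs:
        if not tc.converged:
            raise IsothermError(f"time course at L0={tc.l_total:g} uM did "
                                "not converge; extend max_time")
        if tc.rates != ref.rates or not math.isclose(tc.m_total, ref.m_total):
            raise IsothermError("time courses mix rate constants or m_total")
    points = sorted((tc.equilibrium_state.l,
                     binding_density(tc.equilibrium_state, tc.m_total))
                    for tc in tcs)
    l = np.array([p[0] for p in points])
    n = np.array([p[1] for p in points])
    # simulation round-off can leave microscopic non-monotonicity
    n = np.maximum.accumulate(np.clip(n, 0.0, None))
    return Isotherm(l, n, meta=dict(meta or {}, m_total=ref.m_total))


def isotherm_from_model(model: BindingModel, l_grid) -> Isotherm:
    """Sample a closed-form model on a free-ligand grid."""
    l = np.asarray(l_grid, dtype=float)
    return Isotherm(l, model.binding_density(l),
                    meta={"model": repr(model)})


def ligand_grid(k_o: float, decades: float = 2.0, per_decade: int = 25,
                l_max: float | None = None, l_min: float | None = None,
                kind: str = "log") -> np.ndarray:
    """Ligand-concentration grid around the dissociation constant 1/k_o.

    The default spans ``decades`` orders of magnitude below and above the
    dissociation constant, log-spaced at ``per_decade`` points per decade;
    ``kind="linear"`` gives evenly spaced concentrations over the same range.
    Explicit ``l_min``/``l_max`` override the span.
    """
    kd = 1.0 / k_o
    lo = kd * 10.0 ** (-decades) if l_min is None else l_min
    hi = kd * 10.0 ** decades if l_max is None else l_max
    if not 0 < lo < hi:
        raise IsothermError("ligand grid bounds must satisfy 0 < lo < hi")
    if kind == "log":
        n = int(round(math.log10(hi / lo) * per_decade)) + 1
        return np.logspace(math.log10(lo), math.log10(hi), n)
    if kind == "linear":
        n = int(round(math.log10(hi / lo) * per_decade)) + 1
        return np.linspace(lo, hi, n)
    raise IsothermError(f"unknown grid kind {kind!r}")


# --------------------------------------------------------------------------
# Characteristic free-ligand span
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpanResult:
    """Ratio of free-ligand concentrations at 10% and 90% saturation."""
    l_10: float
    l_90: float

    @property
    def ratio(self) -> float:
        return self.l_90 / self.l_10

    @property
    def log10_span(self) -> float:
        return math.log10(self.ratio)


def free_ligand_span(obj: BindingModel | Isotherm,
                     n_sites: float | None = None) -> SpanResult:
    """Characteristic free-ligand span L(theta=0.9) / L(theta=0.1).

    For a single class of sites the span is 81 (1.908 log units); positive
    cooperativity narrows it and negative cooperativity widens it.  For an
    :class:`Isotherm` the saturation curve is interpolated monotonically
    (PCHIP in log L); ``n_sites`` then sets the plateau used for theta
    (default: the asymptote estimate from :mod:`coopbind.hill`).
    """
    if isinstance(obj, Isotherm):
        return _span_isotherm(obj, n_sites)
    return _span_model(obj)


def _span_model(model: BindingModel) -> SpanResult:
    n_tot = float(model.n_sites)

    def theta(l):
        return float(model.binding_density(l)) / n_tot

    out = []
    for target in (0.1, 0.9):
        lo, hi = 1e-12, 1e12
        # bracket on a log scale; models are monotone in L
        out.append(brentq(lambda x: theta(math.exp(x)) - target,
                          math.log(lo), math.log(hi), xtol=1e-13))
    return SpanResult(l_10=math.exp(out[0]), l_90=math.exp(out[1]))


def _span_isotherm(iso: Isotherm, n_sites: float | None) -> SpanResult:
    if n_sites is None:
        from .hill import estimate_site_number
        n_sites = estimate_site_number(iso)
    theta = iso.n_avg / n_sites
    pos = iso.free_ligand > 0
    x = np.log(iso.free_ligand[pos])
    th = theta[pos]
    if th.min() > 0.1 or th.max() < 0.9:
        raise SpanRangeError(
            f"isotherm spans saturation [{th.min():.3g}, {th.max():.3g}]; "
            "0.1-0.9 required -- extend the ligand range")
    # strictly increasing theta needed for interpolation; drop flat ties
    keep = np.concatenate([[True], np.diff(th) > 0])
    interp = PchipInterpolator(x[keep], th[keep])
    out = []
    for target in (0.1, 0.9):
        out.append(brentq(lambda v: float(interp(v)) - target,
                          x[keep][0], x[keep][-1], xtol=1e-12))
    return SpanResult(l_10=math.exp(out[0]), l_90=math.exp(out[1]))
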