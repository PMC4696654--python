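"""Wyman Hill plot construction and Hill-coefficient extraction.

The Hill coefficient is the extremal slope of the Hill plot
y = ln(<n>/(N - <n>)) versus x = ln[L], estimated the way an experimenter
would: the plateau N is read off the isotherm asymptote, a third-order
polynomial is least-squares fitted to the points in the transition region
(fractional saturation 0.1-0.9), and its derivative is evaluated over that
region's x-interval.  The reported n_H is the derivative extremum deviating
most from 1: a maximum for positive and a minimum for negative
cooperativity.  For a macromolecule with two identical interacting sites the
midsaturation slope has the closed form 2 / (1 + omega^-1/2), which the
fitted value tracks to within a few percent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .isotherms import Isotherm, IsothermError

logger = logging.getLogger("coopbind")

__all__ = [
    "HillPlotData", "HillResult", "HillAnalysisError", "PlateauError",
    "InsufficientDataError", "estimate_site_number", "wyman_hill_plot",
    "hill_coefficient", "analyze_isotherm", "midsaturation_hill_slope",
]


class HillAnalysisError(ValueError):
    """Hill-plot analysis failure."""


class PlateauError(HillAnalysisError):
    """Isotherm has not plateaued; extend the ligand range."""


class InsufficientDataError(HillAnalysisError):
    """Fewer than the minimum number of transition-region points."""


@dataclass
class HillPlotData:
    """Hill-plot coordinates with the transition region flagged.

    ``x`` is ln(free ligand / uM), ``y`` is ln(<n>/(N - <n>)); only points
    with 0 < <n> < N are retained.  ``transition_mask`` marks points with
    fractional saturation in [0.1, 0.9].
    """

    x: np.ndarray
    y: np.ndarray
    n_sites: float
    transition_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.x) <= 0):
            raise HillAnalysisError("Hill-plot x must be strictly increasing")


@dataclass(frozen=True)
class HillResult:
    """Cubic-fit Hill coefficient.

    ``a0..a3`` are the coefficients of the cubic y(x) fitted to the
    transition region, ``x_extremum`` the location (ln uM) at which the
    derivative extremum was taken, and ``operator`` whether that extremum
    was the maximum or the minimum of the fitted slope.
    """

    n_h: float
    a0: float
    a1: float
    a2: float
    a3: float
    x_extremum: float
    operator: str
    n_points_fit: int


def estimate_site_number(iso: Isotherm, tail_points: int = 5,
                         plateau_tol: float = 0.05) -> float:
    """Apparent number of binding sites: the isotherm's asymptotic plateau.

    The plateau is estimated by linear extrapolation of <n> against 1/[L]
    over the last ``tail_points`` points (intercept at 1/[L] -> 0), without
    rounding -- a blind analysis reports the apparent site number the data
    supports, which under strong negative cooperativity is near 1 even
    though the macromolecule has two sites.  Requires the isotherm to have
    roughly plateaued: the last three points must agree within
    ``plateau_tol`` relative (default 5%, loose enough for a slowly
    saturating tail), otherwise a :class:`PlateauError` asks for a wider
    ligand range.
    """
    if len(iso) < max(3, tail_points):
        raise InsufficientDataError("too few isotherm points for a plateau "
                                    "estimate")
    n = iso.n_avg
    tail3 = n[-3:]
    if tail3.min() <= 0 or (tail3.max() - tail3.min()) / tail3.max() > plateau_tol:
        raise PlateauError(
            "isotherm has not plateaued (last three points differ by "
            f"{(tail3.max() - tail3.min()) / max(tail3.max(), 1e-300):.2%}); "
            "extend the ligand range")
    inv_l = 1.0 / iso.free_ligand[-tail_points:]
    slope, intercept = np.polyfit(inv_l, n[-tail_points:], 1)
    n_est = float(intercept)
    if n_est < n[-1]:
        # extrapolation must not undercut the data; fall back to last point
        n_est = float(n[-1])
    return n_est


def wyman_hill_plot(iso: Isotherm, n_sites: float,
                    transition: tuple[float, float] = (0.1, 0.9),
                    min_points: int = 5) -> HillPlotData:
    """Hill-plot coordinates of an isotherm for a given plateau ``n_sites``.

    Points with <n> <= 0 or <n> >= n_sites are dropped (with a log notice);
    fewer than ``min_points`` transition-region points is an error.
    """
    if n_sites <= 0:
        raise HillAnalysisError("n_sites must be positive")
    n = iso.n_avg
    keep = (n > 0) & (n < n_sites) & (iso.free_ligand > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("Hill plot: dropped %d point(s) with <n> outside "
                    "(0, N=%g)", dropped, n_sites)
    x = np.log(iso.free_ligand[keep])
    nk = n[keep]
    y = np.log(nk / (n_sites - nk))
    theta = nk / n_sites
    mask = (theta >= transition[0]) & (theta <= transition[1])
    if int(mask.sum()) < min_points:
        raise InsufficientDataError(
            f"only {int(mask.sum())} transition-region points "
            f"(saturation {transition[0]}-{transition[1]}); "
            f">= {min_points} required")
    return HillPlotData(x=x, y=y, n_sites=float(n_sites),
                        transition_mask=mask)


def hill_coefficient(hp: HillPlotData) -> HillResult:
    """Hill coefficient from a cubic fit of the transition region.

    A least-squares cubic y = a3 x^3 + a2 x^2 + a1 x + a0 is fitted to the
    transition-region points; its derivative is evaluated over the fitted
    x-interval (interior critical point if inside, else the boundaries) and
    the extremum deviating most from 1 is reported.  A tie within 1e-6
    reports exactly 1 (no cooperativity resolved).
    """
    x = hp.x[hp.transition_mask]
    y = hp.y[hp.transition_mask]
    if x.size < 5:
        raise InsufficientDataError("need >= 5 transition-region points")
    if np.ptp(x) <= 0:
        raise HillAnalysisError("degenerate fit: collinear x values")
    # fit in centred coordinates for conditioning, then shift back
    x0 = x.mean()
    c3, c2, c1, c0 = np.polyfit(x - x0, y, 3)
    poly = np.polynomial.Polynomial([c0, c1, c2, c3])(
        np.polynomial.Polynomial([-x0, 1.0]))
    a0, a1, a2, a3 = poly.coef
    deriv = poly.deriv()
    candidates = [x.min(), x.max()]
    if a3 != 0:
        x_vertex = -a2 / (3.0 * a3)
        if x.min() < x_vertex < x.max():
            candidates.append(x_vertex)
    values = [float(deriv(c)) for c in candidates]
    i_max = int(np.argmax(values))
    i_min = int(np.argmin(values))
    d_max, d_min = values[i_max], values[i_min]
    if abs((d_max - 1.0) - (1.0 - d_min)) < 1e-6:
        n_h, x_ext, op = 1.0, float(candidates[i_max]), "max"
    elif abs(d_max - 1.0) >= abs(d_min - 1.0):
        n_h, x_ext, op = d_max, float(candidates[i_max]), "max"
    else:
        n_h, x_ext, op = d_min, float(candidates[i_min]), "min"
    return HillResult(n_h=float(n_h), a0=float(a0), a1=float(a1),
                      a2=float(a2), a3=float(a3), x_extremum=x_ext,
                      operator=op, n_points_fit=int(x.size))


def analyze_isotherm(iso: Isotherm,
                     n_sites: float | str = "auto") -> HillResult:
    """Full Hill analysis: plateau estimate, Wyman plot, cubic fit."""
    n = (estimate_site_number(iso) if n_sites == "auto" else float(n_sites))
    return hill_coefficient(wyman_hill_plot(iso, n))


def midsaturation_hill_slope(omega: float) -> float:
    """Exact Hill-plot slope at half saturation for two identical sites
    with cooperativity factor ``omega``: 2 / (1 + omega^-1/2)."""
    if omega <= 0:
        raise HillAnalysisError("omega must be positive")
    return 2.0 / (1.0 + omega ** -0.5)
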