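"""Deterministic mass-action kinetics of ligand binding to a two-site macromolecule.

The microscopic scheme has four macromolecule states -- both sites empty
(M00), ligand on site 1 only (M10), ligand on site 2 only (M01), both sites
occupied (M11) -- plus the free ligand L.  Eight rate coefficients connect
adjacent states: association coefficients ``k1``, ``k2`` (binding to an empty
macromolecule), ``k1_given_2``, ``k2_given_1`` (binding to a singly occupied
macromolecule; the parenthesised index is the site that is already occupied),
and the matching dissociation coefficients ``km*``.

Units are micromolar (uM) for concentrations, seconds for time, uM^-1 s^-1
for association and s^-1 for dissociation coefficients.

Time courses are obtained with a fixed-step classic 4th-order Runge-Kutta
integrator, run until the relative concentration change of every species
stays below a convergence threshold (default 1e-5, i.e. 10^-3 %) over a
trailing window of check intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

logger = logging.getLogger("coopbind")

__all__ = [
    "RateConstants",
    "SystemState",
    "SimulationConfig",
    "TimeCourse",
    "KineticsError",
    "CycleClosureError",
    "StepSizeError",
    "EquilibriumNotReachedError",
    "derivatives",
    "integrate",
    "simulate_binding",
    "detect_equilibrium",
    "binding_density",
]


class KineticsError(ValueError):
    """Base class for kinetic-model errors."""


class CycleClosureError(KineticsError):
    """The two binding paths M00 -> M11 give different overall constants."""


class StepSizeError(KineticsError):
    """Integration produced a negative-concentration excursion even after
    repeated step halving."""


class EquilibriumNotReachedError(KineticsError):
    """The convergence criterion was never met on the given time course."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RateConstants:
    """The eight microscopic rate coefficients of the two-site scheme.

    Parameters
    ----------
    k1, k2 : float
        Association to site 1 / site 2 of an empty macromolecule (uM^-1 s^-1).
    k1_given_2, k2_given_1 : float
        Association to the remaining empty site when the other site is
        occupied (uM^-1 s^-1).
    km1, km2, km1_given_2, km2_given_1 : float
        The corresponding dissociation coefficients (s^-1).

    Unless ``allow_cycle_violation`` is set, the constants must satisfy
    detailed balance: the overall equilibrium constant of the path
    empty -> site1 -> both must equal that of empty -> site2 -> both.
    """

    k1: float
    k2: float
    k1_given_2: float
    k2_given_1: float
    km1: float
    km2: float
    km1_given_2: float
    km2_given_1: float
    allow_cycle_violation: bool = False

    _CYCLE_RTOL = 1e-6

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k1_given_2", "k2_given_1",
                     "km1", "km2", "km1_given_2", "km2_given_1"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise KineticsError(f"rate coefficient {name} must be strictly "
                                    f"positive and finite, got {v!r}")
        if not self.allow_cycle_violation and not self.cycle_closed():
            raise CycleClosureError(
                "thermodynamic cycle closure violated: "
                f"path via site 1 gives {self._path1():g}, "
                f"path via site 2 gives {self._path2():g}; pass "
                "allow_cycle_violation=True to explore nonequilibrium schemes")

    def _path1(self) -> float:
        return (self.k1 / self.km1) * (self.k2_given_1 / self.km2_given_1)

    def _path2(self) -> float:
        return (self.k2 / self.km2) * (self.k1_given_2 / self.km1_given_2)

    def cycle_closed(self, rtol: float = _CYCLE_RTOL) -> bool:
        a, b = self._path1(), self._path2()
        return abs(a - b) <= rtol * max(abs(a), abs(b))

    @classmethod
    def cooperative(cls, k_o: float, omega: float,
                    off_rate: float = 1.0) -> "RateConstants":
        """Two identical sites with cooperativity factor ``omega``.

        Empty-site association is ``k_o * off_rate`` so that the intrinsic
        constant is ``k_o`` (uM^-1); binding of the second ligand is
        ``omega``-fold faster, with every dissociation coefficient equal to
        ``off_rate`` (the convention used for all the built-in scenarios).
        """
        kon = k_o * off_rate
        return cls(k1=kon, k2=kon,
                   k1_given_2=omega * kon, k2_given_1=omega * kon,
                   km1=off_rate, km2=off_rate,
                   km1_given_2=off_rate, km2_given_1=off_rate)

    @classmethod
    def two_different_sites(cls, k_o1: float, k_o2: float,
                            off_rate: float = 1.0) -> "RateConstants":
        """Two independent sites with intrinsic constants ``k_o1``, ``k_o2``."""
        return cls(k1=k_o1 * off_rate, k2=k_o2 * off_rate,
                   k1_given_2=k_o1 * off_rate, k2_given_1=k_o2 * off_rate,
                   km1=off_rate, km2=off_rate,
                   km1_given_2=off_rate, km2_given_1=off_rate)

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k1_given_2, self.k2_given_1,
                         self.km1, self.km2, self.km1_given_2,
                         self.km2_given_1])

    @property
    def max_on(self) -> float:
        return max(self.k1, self.k2, self.k1_given_2, self.k2_given_1)

    @property
    def min_on(self) -> float:
        return min(self.k1, self.k2, self.k1_given_2, self.k2_given_1)

    @property
    def max_off(self) -> float:
        return max(self.km1, self.km2, self.km1_given_2, self.km2_given_1)

    @property
    def min_off(self) -> float:
        return min(self.km1, self.km2, self.km1_given_2, self.km2_given_1)


@dataclass(frozen=True)
class SystemState:
    """Concentrations of the five species at time ``t`` (uM, s)."""

    t: float
    m00: float
    m10: float
    m01: float
    m11: float
    l: float

    def __post_init__(self) -> None:
        for name in ("m00", "m10", "m01", "m11", "l"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise KineticsError(f"concentration {name} must be finite and "
                                    f"non-negative, got {v!r}")

    @property
    def m_total(self) -> float:
        return self.m00 + self.m10 + self.m01 + self.m11

    @property
    def l_total(self) -> float:
        return self.l + self.m10 + self.m01 + 2.0 * self.m11

    def as_array(self) -> np.ndarray:
        return np.array([self.m00, self.m10, self.m01, self.m11, self.l])


#: order of species columns everywhere in this package
SPECIES = ("m00", "m10", "m01", "m11", "l")


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for the fixed-step RK4 integration.

    ``step_size`` defaults to ``"auto"``: 0.01 divided by the fastest total
    rate scale ``max(k_on) * max(L0, M0) + max(k_off)``.  The convergence
    criterion requires the relative change of every species to stay below
    ``convergence_threshold`` over ``window`` consecutive check intervals;
    the check interval is auto-scaled to the slowest kinetic timescale.
    ``record_every`` decimates the stored output ("auto": one record per
    check interval).
    """

    step_size: float | str = "auto"
    convergence_threshold: float = 1e-5   # 10^-3 percent, per check interval
    max_time: float | str = "auto"
    record_every: int | str = "auto"
    window: int = 10

    def __post_init__(self) -> None:
        if self.step_size != "auto":
            if not (isinstance(self.step_size, (int, float))
                    and self.step_size > 0):
                raise KineticsError("step_size must be positive or 'auto'")
        if not 0 < self.convergence_threshold < 1:
            raise KineticsError("convergence_threshold must be in (0, 1)")
        if self.max_time != "auto" and self.max_time <= 0:
            raise KineticsError("max_time must be positive or 'auto'")
        if self.record_every != "auto" and int(self.record_every) < 1:
            raise KineticsError("record_every must be >= 1 or 'auto'")


@dataclass
class TimeCourse:
    """A recorded integration of the two-site scheme.

    ``states`` is an (n_records, 5) array in :data:`SPECIES` order with
    strictly increasing ``times``; ``converged`` reports whether the
    windowed convergence criterion was met before ``max_time``.
    """

    rates: RateConstants
    m_total: float
    l_total: float
    times: np.ndarray
    states: np.ndarray
    converged: bool
    config: SimulationConfig = field(default_factory=SimulationConfig)

    @property
    def equilibrium_state(self) -> SystemState:
        """Final recorded state; only meaningful when ``converged``."""
        return self.state_at(-1)

    def state_at(self, i: int) -> SystemState:
        m00, m10, m01, m11, l = self.states[i]
        return SystemState(t=float(self.times[i]), m00=m00, m10=m10,
                           m01=m01, m11=m11, l=l)

    @property
    def n_avg(self) -> np.ndarray:
        """Binding density <n>(t) along the recorded course."""
        return ((self.states[:, 1] + self.states[:, 2]
                 + 2.0 * self.states[:, 3]) / self.m_total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "m00_uM": self.states[:, 0],
            "m10_uM": self.states[:, 1],
            "m01_uM": self.states[:, 2],
            "m11_uM": self.states[:, 3],
            "l_uM": self.states[:, 4],
            "n_avg": self.n_avg,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# --------------------------------------------------------------------------
# Right-hand side of the mass-action ODE system
# --------------------------------------------------------------------------

def derivatives(state: SystemState, rates: RateConstants) -> np.ndarray:
    """Rates of change (uM/s) of (m00, m10, m01, m11, l) under mass action.

    The macromolecule derivatives sum to zero, and the ligand-conservation
    combination dl + dm10 + dm01 + 2*dm11 is zero.
    """
    return rhs(state.as_array(), rates.as_array())


def rhs(y: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Vectorised RHS; ``y`` has species on the first axis."""
    m00, m10, m01, m11, l = y
    k1, k2, k1g2, k2g1, km1, km2, km1g2, km2g1 = k
    dm00 = km1 * m10 + km2 * m01 - (k1 + k2) * l * m00
    dm10 = k1 * l * m00 + km2g1 * m11 - (km1 + k2g1 * l) * m10
    dm01 = k2 * l * m00 + km1g2 * m11 - (km2 + k1g2 * l) * m01
    dm11 = (k1g2 * m01 + k2g1 * m10) * l - (km1g2 + km2g1) * m11
    dl = (km1 * m10 + km2 * m01 + (km2g1 + km1g2) * m11
          - ((k1 + k2) * m00 + k2g1 * m10 + k1g2 * m01) * l)
    return np.array([dm00, dm10, dm01, dm11, dl])


# --------------------------------------------------------------------------
# Fixed-step RK4 kernels (numba)
# --------------------------------------------------------------------------

@njit(cache=True)
def _rk4_rhs(y, k, out):
    m00, m10, m01, m11, l = y[0], y[1], y[2], y[3], y[4]
    k1, k2, k1g2, k2g1, km1, km2, km1g2, km2g1 = (
        k[0], k[1], k[2], k[3], k[4], k[5], k[6], k[7])
    out[0] = km1 * m10 + km2 * m01 - (k1 + k2) * l * m00
    out[1] = k1 * l * m00 + km2g1 * m11 - (km1 + k2g1 * l) * m10
    out[2] = k2 * l * m00 + km1g2 * m11 - (km2 + k1g2 * l) * m01
    out[3] = (k1g2 * m01 + k2g1 * m10) * l - (km1g2 + km2g1) * m11
    out[4] = (km1 * m10 + km2 * m01 + (km2g1 + km1g2) * m11
              - ((k1 + k2) * m00 + k2g1 * m10 + k1g2 * m01) * l)


@njit(cache=True)
def _rk4_step(y, k, h, k1v, k2v, k3v, k4v, yt):
    _rk4_rhs(y, k, k1v)
    for i in range(5):
        yt[i] = y[i] + 0.5 * h * k1v[i]
    _rk4_rhs(yt, k, k2v)
    for i in range(5):
        yt[i] = y[i] + 0.5 * h * k2v[i]
    _rk4_rhs(yt, k, k3v)
    for i in range(5):
        yt[i] = y[i] + h * k3v[i]
    _rk4_rhs(yt, k, k4v)
    for i in range(5):
        y[i] += (h / 6.0) * (k1v[i] + 2.0 * k2v[i] + 2.0 * k3v[i] + k4v[i])


@njit(cache=True)
def _rk4_run(y0, k, h, rec_every, chk_every, threshold, window,
             max_steps, neg_tol, atol):
    """Integrate until windowed convergence, max_steps, or a negative
    excursion below -neg_tol.  Returns (times, states, n_rec, status) with
    status 0 = hit max_steps, 1 = converged, 2 = negative excursion."""
    n_rec_max = max_steps // rec_every + 2
    times = np.empty(n_rec_max)
    states = np.empty((n_rec_max, 5))
    y = y0.copy()
    k1v = np.empty(5); k2v = np.empty(5); k3v = np.empty(5)
    k4v = np.empty(5); yt = np.empty(5)
    times[0] = 0.0
    states[0] = y
    n_rec = 1
    prev_chk = y.copy()
    run = 0
    status = 0
    step = 0
    while step < max_steps:
        _rk4_step(y, k, h, k1v, k2v, k3v, k4v, yt)
        step += 1
        bad = False
        for i in range(5):
            if y[i] < -neg_tol or not (y[i] == y[i]) or y[i] > 1e30:
                bad = True
            elif y[i] < 0.0:
                y[i] = 0.0
        if bad:
            status = 2
            break
        if step % rec_every == 0:
            times[n_rec] = step * h
            states[n_rec] = y
            n_rec += 1
        if step % chk_every == 0:
            ok = True
            for i in range(5):
                if abs(y[i] - prev_chk[i]) > threshold * (abs(prev_chk[i])
                                                          + atol):
                    ok = False
            run = run + 1 if ok else 0
            prev_chk[:] = y
            if run >= window:
                status = 1
                break
    if (step % rec_every) != 0 or status == 2:
        times[n_rec] = step * h
        states[n_rec] = y
        n_rec += 1
    return times[:n_rec], states[:n_rec], n_rec, status


@njit(cache=True)
def _rk4_bound_at_times(y0, k, h, ts):
    """Integrate with fixed step h and return the bound-ligand concentration
    m10 + m01 + 2*m11 linearly interpolated at the requested times."""
    out = np.empty(ts.shape[0])
    y = y0.copy()
    k1v = np.empty(5); k2v = np.empty(5); k3v = np.empty(5)
    k4v = np.empty(5); yt = np.empty(5)
    j = 0
    t = 0.0
    b_prev = y[1] + y[2] + 2.0 * y[3]
    while j < ts.shape[0] and ts[j] <= 0.0:
        out[j] = b_prev
        j += 1
    t_end = ts[ts.shape[0] - 1]
    while j < ts.shape[0] and t < t_end:
        _rk4_step(y, k, h, k1v, k2v, k3v, k4v, yt)
        for i in range(5):
            if y[i] < 0.0:
                y[i] = 0.0
        t_new = t + h
        b_new = y[1] + y[2] + 2.0 * y[3]
        while j < ts.shape[0] and ts[j] <= t_new + 1e-12 * h:
            w = (ts[j] - t) / h
            if w > 1.0:
                w = 1.0
            out[j] = (1.0 - w) * b_prev + w * b_new
            j += 1
        t = t_new
        b_prev = b_new
    return out


# --------------------------------------------------------------------------
# Integration driver
# --------------------------------------------------------------------------

def _auto_step(rates: RateConstants, m_total: float, l_total: float) -> float:
    scale = rates.max_on * max(l_total, m_total) + rates.max_off
    return 0.01 / scale


def _slow_rate(rates: RateConstants, m_total: float, l_total: float) -> float:
    """Conservative estimate of the slowest relaxation rate (1/s)."""
    return rates.min_off + rates.min_on * max(l_total - 2.0 * m_total, 0.0)


def integrate(initial: SystemState, rates: RateConstants,
              config: SimulationConfig | None = None) -> TimeCourse:
    """Integrate the mass-action system from ``initial`` with classic RK4.

    Linear conservation of total macromolecule and total ligand holds at
    every step to near machine precision.  On a negative-concentration
    excursion beyond -1e-9 of the concentration scale the step is halved
    and the run retried; persistent failure raises :class:`StepSizeError`.
    Non-convergence within ``max_time`` is flagged (``converged=False``),
    never silent.
    """
    config = config or SimulationConfig()
    m_total = initial.m_total
    l_total = initial.l_total
    conc_scale = max(m_total, l_total, 1e-30)

    h = (_auto_step(rates, m_total, l_total)
         if config.step_size == "auto" else float(config.step_size))
    slow = _slow_rate(rates, m_total, l_total)
    t_max = (400.0 / slow if config.max_time == "auto"
             else float(config.max_time))
    y0 = initial.as_array()
    k = rates.as_array()
    neg_tol = 1e-9 * conc_scale
    atol = 1e-12 * conc_scale

    for attempt in range(8):
        chk_every = max(1, int(round(1.0 / (slow * h))))
        if config.record_every == "auto":
            rec_every = chk_every
        else:
            rec_every = int(config.record_every)
        max_steps = max(int(math.ceil(t_max / h)),
                        chk_every * (config.window + 1))
        times, states, n_rec, status = _rk4_run(
            y0, k, h, rec_every, chk_every, config.convergence_threshold,
            config.window, max_steps, neg_tol, atol)
        if status != 2:
            break
        logger.warning("negative-concentration excursion at step size %g; "
                       "retrying with halved step", h)
        h *= 0.5
    else:
        raise StepSizeError("negative-concentration excursion persisted "
                            "after repeated step halving")
    if status == 2:
        raise StepSizeError(f"negative-concentration excursion at step "
                            f"size {h:g}")
    if status == 0:
        logger.warning("time course (L0=%g uM) did not converge within "
                       "max_time=%g s", l_total, t_max)
    return TimeCourse(rates=rates, m_total=m_total, l_total=l_total,
                      times=times, states=states, converged=(status == 1),
                      config=replace(config, step_size=h))


def simulate_binding(rates: RateConstants, m_total: float, l_total: float,
                     config: SimulationConfig | None = None) -> TimeCourse:
    """Integrate from the standard initial condition: all macromolecule
    empty (m00 = M0) and all ligand free (l = L0)."""
    if m_total <= 0:
        raise KineticsError("m_total must be positive")
    if l_total < 0:
        raise KineticsError("l_total must be non-negative")
    initial = SystemState(t=0.0, m00=m_total, m10=0.0, m01=0.0, m11=0.0,
                          l=l_total)
    return integrate(initial, rates, config)


def simulate_grid(rates: RateConstants, m_total: float,
                  l_totals: Sequence[float],
                  config: SimulationConfig | None = None) -> list[TimeCourse]:
    """One time course per total-ligand concentration."""
    return [simulate_binding(rates, m_total, l0, config) for l0 in l_totals]


# --------------------------------------------------------------------------
# Equilibrium detection and binding density
# --------------------------------------------------------------------------

def detect_equilibrium(tc: TimeCourse, threshold: float | None = None,
                       window: int | None = None) -> SystemState:
    """First recorded state at which equilibrium is established.

    Scans the recorded course for the earliest state preceded by ``window``
    consecutive inter-record intervals in which the relative change of every
    species stayed below ``threshold`` (defaults taken from the course's
    configuration; the window is capped at the number of intervals).  States
    numerically identical to the detected one are collapsed to the earliest,
    so a constant course returns its first state.  Raises
    :class:`EquilibriumNotReachedError` if the criterion is never met; a
    threshold of zero is unattainable because the comparison is strict.
    """
    if tc.times.size == 0:
        raise KineticsError("empty time course")
    threshold = (tc.config.convergence_threshold if threshold is None
                 else threshold)
    window = tc.config.window if window is None else window
    states = tc.states
    atol = 1e-12 * max(tc.m_total, tc.l_total, 1e-30)
    below = np.all(np.abs(np.diff(states, axis=0))
                   < threshold * (np.abs(states[:-1]) + atol), axis=1)
    w = max(1, min(window, below.size))
    run = 0
    for i in range(below.size):
        run = run + 1 if below[i] else 0
        if run >= w:
            j = i + 1
            while j > 0 and np.all(np.abs(states[j - 1] - states[j]) <= atol):
                j -= 1
            return tc.state_at(j)
    raise EquilibriumNotReachedError(
        f"equilibrium criterion (threshold={threshold:g}) never met on the "
        f"time course (L0={tc.l_total:g} uM)")


def binding_density(state: SystemState, m_total: float) -> float:
    """Average number of bound ligands per macromolecule,
    (m10 + m01 + 2*m11) / M0."""
    if m_total <= 0:
        raise KineticsError("m_total must be positive")
    return (state.m10 + state.m01 + 2.0 * state.m11) / m_total
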