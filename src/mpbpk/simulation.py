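"""Solver orchestration and derived PK metrics (AUC, terminal slope, clearance).

The stiff system is integrated piecewise between IV-bolus events with
``scipy.integrate.solve_ivp`` (LSODA); each bolus is an instantaneous
increment of the plasma antibody concentration.  Output grids are
log-dense after each dose so both the distribution and terminal phases
are resolved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .compound import dose_to_amount
from .core import A_P, ModelParams, PKProfile, initial_state, make_rhs

__all__ = ["DoseSchedule", "simulate", "auc", "terminal_clearance", "SolverError"]


class SolverError(RuntimeError):
    """Raised when the stiff integrator fails to advance."""


@dataclass(frozen=True)
class DoseSchedule:
    """IV bolus events: sorted (time h, amount nmol) pairs."""

    events: tuple

    def __post_init__(self) -> None:
        ev = tuple((float(t), float(a)) for t, a in self.events)
        if any(t < 0 for t, _ in ev):
            raise ValueError("dose times must be non-negative")
        if any(a < 0 for _, a in ev):
            raise ValueError("dose amounts must be non-negative")
        object.__setattr__(self, "events", tuple(sorted(ev)))

    @classmethod
    def iv_bolus(cls, amount_nmol: float, time_h: float = 0.0) -> "DoseSchedule":
        return cls(events=((time_h, amount_nmol),))

    @classmethod
    def from_mg_per_kg(cls, dose_mg_per_kg, body_weight_kg: float, MW_Da: float,
                      times_h=(0.0,)) -> "DoseSchedule":
        doses = np.broadcast_to(np.atleast_1d(dose_mg_per_kg), np.shape(times_h))
        return cls(events=tuple(
            (t, dose_to_amount(d, body_weight_kg, MW_Da)) for t, d in zip(times_h, doses)
        ))


def _default_grid(t0: float, t1: float, n: int = 200) -> np.ndarray:
    """Log-dense grid over one dosing phase (includes both endpoints)."""
    span = t1 - t0
    g = np.geomspace(1e-4, 1.0, n - 1)
    return np.concatenate([[t0], t0 + span * g])


def simulate(
    params: ModelParams,
    schedule: DoseSchedule,
    t_grid: np.ndarray | None = None,
    *,
    t_end: float | None = None,
    method: str = "LSODA",
) -> PKProfile:
    """Integrate the model over a dosing schedule and return a :class:`PKProfile`.

    ``t_grid`` must cover all dose events; when omitted, a log-dense grid
    with at least 200 points per dosing phase is constructed up to
    ``t_end``.  Bolus events are applied as instantaneous plasma
    increments; the state is continuous everywhere else.
    """
    events = schedule.events
    if t_grid is None:
        if t_end is None:
            raise ValueError("provide t_grid or t_end")
        bounds = [t for t, _ in events] + [float(t_end)]
        segs = [_default_grid(a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
        t_grid = np.unique(np.concatenate(segs)) if segs else np.array([0.0, float(t_end)])
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be sorted")
    if events and (events[0][0] < t_grid[0] or events[-1][0] > t_grid[-1]):
        raise ValueError("t_grid must cover all dose events")

    rhs = make_rhs(params)
    p = params.prepare()
    y = initial_state(params, 0.0)
    t_now = float(t_grid[0])
    for t_ev, amount in events:
        if t_ev == t_now:
            y = y.copy()
            y[A_P] += amount / p.V_p
    out_t, out_y = [], []
    remaining = [(t, a) for t, a in events if t > t_now]
    checkpoints = sorted({t for t, _ in remaining} | {float(t_grid[-1])})
    for t_next in checkpoints:
        mask = (t_grid >= t_now) & (t_grid <= t_next)
        t_eval = np.unique(np.concatenate([[t_now], t_grid[mask], [t_next]]))
        if t_next > t_now:
            sol = solve_ivp(rhs, (t_now, t_next), y, method=method, t_eval=t_eval,
                            rtol=params.rtol, atol=params.atol)
            if not sol.success:
                last = sol.t[-1] if len(sol.t) else t_now
                raise SolverError(f"integration failed at t={last:g} h: {sol.message}")
            keep = np.isin(sol.t, t_grid[mask])
            out_t.append(sol.t[keep])
            out_y.append(sol.y[:, keep].T)
            y = sol.y[:, -1].copy()
            t_now = t_next
        for t_ev, amount in remaining:
            if t_ev == t_next:
                y[A_P] += amount / p.V_p
    t_all = np.concatenate(out_t) if out_t else np.asarray([t_grid[0]])
    y_all = np.vstack(out_y) if out_y else y[None, :]
    # collapse duplicate segment boundaries
    t_all, idx = np.unique(t_all, return_index=True)
    y_all = y_all[idx]
    return PKProfile(t_h=t_all, states=y_all, params=params,
                     doses_nmol=tuple(a for _, a in events))


def auc(profile: PKProfile, observable: str, t0: float | None = None,
        t1: float | None = None) -> float:
    """Trapezoidal exposure (nM*h) of an observable over [t0, t1]."""
    t = profile.t_h
    c = profile.observable(observable)
    t0 = t[0] if t0 is None else float(t0)
    t1 = t[-1] if t1 is None else float(t1)
    if not (t[0] <= t0 < t1 <= t[-1]):
        raise ValueError(f"[{t0}, {t1}] outside simulated grid [{t[0]}, {t[-1]}]")
    tt = np.unique(np.concatenate([[t0], t[(t > t0) & (t < t1)], [t1]]))
    cc = np.interp(tt, t, c)
    return float(np.trapezoid(cc, tt))


def terminal_clearance(
    profile: PKProfile,
    V_p_L: float | None = None,
    body_weight_kg: float | None = None,
    terminal_window: tuple[float, float] | None = None,
) -> dict:
    """Terminal elimination rate and linear clearance from the plasma log-slope.

    ``kel`` is minus the least-squares slope of ln(C_plasma) vs t over the
    terminal window (default: the last 30% of the simulated span);
    ``CL = kel * V_p`` and ``CL_per_kg = kel * V_p / BW``.
    """
    t = profile.t_h
    c = profile.observable("plasma")
    if terminal_window is None:
        terminal_window = (t[-1] - 0.3 * (t[-1] - t[0]), t[-1])
    lo, hi = terminal_window
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise ValueError("terminal window must contain at least 3 points")
    if np.any(c[mask] <= 0):
        raise ValueError("non-positive plasma concentrations in terminal window")
    kel = -np.polyfit(t[mask], np.log(c[mask]), 1)[0]
    V_p = profile.params.physiology.V_p_L if V_p_L is None else V_p_L
    bw = profile.params.physiology.body_weight_kg if body_weight_kg is None else body_weight_kg
    return {"kel_per_h": float(kel), "CL_L_per_h": float(kel * V_p),
            "CL_L_per_h_per_kg": float(kel * V_p / bw)}
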