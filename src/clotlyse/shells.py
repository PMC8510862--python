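"""Greedy per-step fitting of the time-varying reaction depth κ(t).

The two lysis regimes are explained by reactions deepening from the fiber
surface into the bulk.  Rather than prescribing κ(t), it is fitted: at every
Δt step the lysis equations are advanced once for each candidate depth
κ ∈ {0, …, κ_max(R_f)} and the value whose predicted percent lysis at
t + Δt is closest (squared error) to the target curve is committed.  The
optimization is deliberately sequential (one-step lookahead, no global
smoothing); ties break to the smallest κ.  The target is a normalized
turbidity curve re-interpreted as percent lysis and resampled onto the
simulation grid.

``aggregate_phi`` reproduces the regime-normalized summary of the fitted
shell fraction φ = κ_opt/κ_max: each run is split into slow-lysis,
fast-lysis and end-of-lysis regions, time is normalized to [0, 1] within
each region, and φ is pooled into 10 bins per region (median, quartiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ClotlyseError
from .formation import BindingRates, ClotState
from .geometry import kappa_max
from .lysis import (
    DT_DEFAULT,
    IL,
    LysisTrajectory,
    ClotConstants,
    euler_step,
    initial_lysis_vector,
    porosity,
    update_radius,
    EXHAUSTION,
)
from .turbidity import NormalizedTrace


def resample_target(
    nt: NormalizedTrace,
    dt: float = DT_DEFAULT,
    start_min: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate an NT curve onto the simulation grid.

    Returns ``(t_s, percent)`` with t in seconds measured from
    ``start_min`` (default: the curve's global minimum, i.e. lysis start)
    and NT rescaled to percent lysis, offset so the target starts at 0.
    """
    t_min = np.asarray(nt.time, dtype=float)
    y = np.asarray(nt.nt, dtype=float)
    if start_min is None:
        start_min = float(t_min[np.argmin(y)])
    t_end_s = (t_min[-1] - start_min) * 60.0
    if t_end_s <= 0:
        raise ClotlyseError("target curve ends before lysis start")
    grid = np.arange(0.0, t_end_s + 0.5 * dt, dt)
    vals = np.interp(start_min + grid / 60.0, t_min, y)
    vals = vals - vals[0]
    return grid, 100.0 * np.clip(vals, 0.0, None)


@dataclass
class ShellSchedule:
    """Fitted κ(t): per-step optimal and available shells plus fit error."""

    t: np.ndarray  # s
    kappa_opt: np.ndarray  # int
    kappa_max: np.ndarray  # int
    sq_err: np.ndarray  # per-step squared error on percent lysis

    @property
    def phi(self) -> np.ndarray:
        """Fraction of shells κ_opt/κ_max (1 where no shell is available)."""
        out = np.ones_like(self.kappa_opt, dtype=float)
        nz = self.kappa_max > 0
        out[nz] = self.kappa_opt[nz] / self.kappa_max[nz]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "kappa_opt": self.kappa_opt,
                "kappa_max": self.kappa_max,
                "phi": self.phi,
                "sq_err": self.sq_err,
            }
        )


def optimal_kappa_step(
    y: np.ndarray,
    target_next: float,
    dt: float,
    rates: BindingRates,
    constants: ClotConstants,
) -> tuple[int, np.ndarray, float]:
    """One greedy step: try every κ ∈ {0..κ_max}, commit the best.

    Returns ``(kappa, y_next, squared_error)`` where the error compares the
    candidate's percent lysis at t+Δt with ``target_next`` (percent).  Ties
    break to the smallest κ (most conservative depth).
    """
    rf = update_radius(min(y[IL], constants.cfr0), constants)
    kmax = kappa_max(rf, constants.geometry.r0)
    best = None
    for kap in range(kmax + 1):
        y_next = euler_step(y, kap, rates, constants, dt)
        pct = 100.0 * y_next[IL] / constants.cfr0
        err = (pct - target_next) ** 2
        if best is None or err < best[2]:
            best = (kap, y_next, err)
        elif err > best[2]:
            # dL/dt is nondecreasing in κ, so the error is unimodal in κ:
            # once it grows past the best we are done.  Ties keep the
            # earlier (smaller) κ.
            break
    kap, y_next, err = best
    return kap, y_next, err


def fit_shell_schedule(
    clot: ClotState,
    target: tuple[np.ndarray, np.ndarray],
    rates: BindingRates | None = None,
    constants: ClotConstants | None = None,
    dt: float = DT_DEFAULT,
) -> tuple[ShellSchedule, LysisTrajectory, float]:
    """Fit κ(t) so simulated percent lysis tracks the target curve.

    ``target`` is ``(t_s, percent)`` on the Δt grid (see
    :func:`resample_target`).  The loop repeats the greedy step until all
    fibrin is consumed or the target ends.  Returns the schedule, the
    committed trajectory, and the time-averaged squared error.
    """
    rates = rates or BindingRates()
    constants = constants or ClotConstants.from_clot_state(clot)
    t_grid, tgt = target
    if len(t_grid) < 2:
        raise ClotlyseError("target must contain at least 2 grid points")
    y = initial_lysis_vector(clot, constants)

    ts, kopts, kmaxs, errs = [], [], [], []
    rec_l, rec_rf, rec_eps, rec_sp = [], [], [], []
    exhausted = False

    def record(y, rf):
        rec_l.append(y[IL])
        rec_rf.append(rf)
        rec_eps.append(porosity(rf, constants))
        rec_sp.append(y[1:].copy())

    for i in range(len(t_grid) - 1):
        rf = update_radius(min(y[IL], constants.cfr0), constants)
        kmax = kappa_max(rf, constants.geometry.r0)
        kap, y, err = optimal_kappa_step(y, tgt[i + 1], dt, rates, constants)
        ts.append(t_grid[i])
        kopts.append(kap)
        kmaxs.append(kmax)
        errs.append(err)
        record(y, update_radius(min(y[IL], constants.cfr0), constants))
        if y[IL] >= EXHAUSTION * constants.cfr0:
            exhausted = True
            break

    schedule = ShellSchedule(
        t=np.array(ts),
        kappa_opt=np.array(kopts, dtype=int),
        kappa_max=np.array(kmaxs, dtype=int),
        sq_err=np.array(errs),
    )
    traj = LysisTrajectory(
        t=np.array(ts) + dt,
        l=np.array(rec_l),
        rf=np.array(rec_rf),
        eps=np.array(rec_eps),
        kappa=schedule.kappa_opt,
        species=np.array(rec_sp),
        cfr0=constants.cfr0,
        rf0=constants.rf0,
        exhausted=exhausted,
    )
    mse = float(np.mean(schedule.sq_err))
    return schedule, traj, mse


def policy_mse(
    clot: ClotState,
    policy,
    target: tuple[np.ndarray, np.ndarray],
    rates: BindingRates | None = None,
    constants: ClotConstants | None = None,
    dt: float = DT_DEFAULT,
) -> float:
    """Time-averaged squared error of a fixed policy against the target."""
    from .lysis import run_fibrinolysis

    rates = rates or BindingRates()
    constants = constants or ClotConstants.from_clot_state(clot)
    t_grid, tgt = target
    traj = run_fibrinolysis(
        clot, policy, rates=rates, constants=constants, dt=dt, t_max=float(t_grid[-1])
    )
    sim = np.interp(t_grid, traj.t, traj.percent)
    # same estimator as the fitted schedule: squared error per advanced step
    return float(np.mean((sim[1:] - tgt[1:]) ** 2))


@dataclass
class RegimeAggregation:
    """Shell-fraction summary over normalized regime time (3 × 10 bins)."""

    regions: tuple[str, ...] = ("slow", "fast", "end")
    n_bins: int = 10
    median: dict = field(default_factory=dict)  # region -> array(n_bins)
    q1: dict = field(default_factory=dict)
    q3: dict = field(default_factory=dict)
    n_samples: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for reg in self.regions:
            for b in range(self.n_bins):
                rows.append(
                    {
                        "region": reg,
                        "bin": b,
                        "phi_median": self.median[reg][b],
                        "phi_q1": self.q1[reg][b],
                        "phi_q3": self.q3[reg][b],
                        "n": self.n_samples[reg][b],
                    }
                )
        return pd.DataFrame(rows)


def aggregate_phi(
    schedules: list[ShellSchedule],
    boundaries: list[tuple[float, float, float]],
    n_bins: int = 10,
) -> RegimeAggregation:
    """Pool shell fractions over normalized regime time.

    ``boundaries`` gives, per schedule, the (SLT, TLT, end-of-lysis) times
    in seconds measured from lysis start.  Within each region
    [0, SLT], [SLT, TLT], [TLT, end] the time is normalized to [0, 1] and φ
    values pooled into ``n_bins`` bins; medians and quartiles are taken over
    the pooled samples.  Schedules with inconsistent boundaries are skipped.
    """
    agg = RegimeAggregation(n_bins=n_bins)
    pooled: dict[str, list[list[float]]] = {
        reg: [[] for _ in range(n_bins)] for reg in agg.regions
    }
    import warnings as _warnings

    for sched, (slt, tlt, end) in zip(schedules, boundaries):
        if not (0 < slt < tlt <= end):
            _warnings.warn(
                f"skipping schedule with inconsistent boundaries ({slt}, {tlt}, {end})"
            )
            continue
        phi = sched.phi
        t = sched.t
        for reg, (a, b) in zip(agg.regions, [(0.0, slt), (slt, tlt), (tlt, end)]):
            mask = (t >= a) & (t < b)
            if not np.any(mask):
                continue
            u = (t[mask] - a) / (b - a)  # normalized time in [0, 1)
            bins = np.minimum((u * n_bins).astype(int), n_bins - 1)
            for bi, ph in zip(bins, phi[mask]):
                pooled[reg][bi].append(ph)

    for reg in agg.regions:
        med = np.full(n_bins, np.nan)
        q1 = np.full(n_bins, np.nan)
        q3 = np.full(n_bins, np.nan)
        ns = np.zeros(n_bins, dtype=int)
        for b in range(n_bins):
            vals = pooled[reg][b]
            ns[b] = len(vals)
            if vals:
                med[b], q1[b], q3[b] = (
                    float(np.median(vals)),
                    float(np.percentile(vals, 25)),
                    float(np.percentile(vals, 75)),
                )
        agg.median[reg], agg.q1[reg], agg.q3[reg], agg.n_samples[reg] = med, q1, q3, ns
    return agg
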