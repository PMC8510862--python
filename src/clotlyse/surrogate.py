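"""Surrogate lysis model: regime-specific random shell fractions.

The fitted shell schedules show the shell fraction φ = κ_opt/κ_max rising
from near-surface values in the slow regime to near-bulk values in the fast
regime.  The surrogate model exploits that structure to predict lysis
without any experimental curve: the regime is decided by the normalized
fiber radius R̃_f = R_f/R_f0 (slow while R̃_f > 0.9, fast below) and at each
step φ is drawn from the corresponding empirical distribution of mean
per-run shell fractions.  The slow and fast lysis times fall out of the
same radius thresholds: SLT = first crossing of R̃_f ≤ 0.9, FLT = (first
crossing of R̃_f ≤ 0.6) − SLT.

Distributions are stored as raw samples and drawn uniformly with
replacement — no kernel smoothing, the smallest assumption set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import ClotlyseError
from .formation import BindingRates, ClotState
from .geometry import kappa_max
from .lysis import (
    DT_DEFAULT,
    EXHAUSTION,
    IL,
    ClotConstants,
    LysisTrajectory,
    initial_lysis_vector,
    euler_step,
    porosity,
    update_radius,
)
from .shells import ShellSchedule

R_TILDE_SLOW = 0.9  # slow regime while R̃f above this
R_TILDE_FAST = 0.6  # fast regime ends (for timing) at this crossing


@dataclass
class PhiDistributions:
    """Empirical samples of the mean shell fraction per regime."""

    slow: np.ndarray
    fast: np.ndarray
    r_tilde_slow: float = R_TILDE_SLOW
    r_tilde_fast: float = R_TILDE_FAST

    def __post_init__(self) -> None:
        self.slow = np.atleast_1d(np.asarray(self.slow, dtype=float))
        self.fast = np.atleast_1d(np.asarray(self.fast, dtype=float))
        for name, arr in (("slow", self.slow), ("fast", self.fast)):
            if arr.size == 0:
                raise ClotlyseError(f"empty {name}-regime phi distribution")
            if np.any((arr < 0) | (arr > 1)):
                raise ClotlyseError(f"{name}-regime phi values outside [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "slow_phi": self.slow.tolist(),
                    "fast_phi": self.fast.tolist(),
                    "r_tilde_slow": self.r_tilde_slow,
                    "r_tilde_fast": self.r_tilde_fast,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "PhiDistributions":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            slow=np.array(d["slow_phi"]),
            fast=np.array(d["fast_phi"]),
            r_tilde_slow=d.get("r_tilde_slow", R_TILDE_SLOW),
            r_tilde_fast=d.get("r_tilde_fast", R_TILDE_FAST),
        )


def build_phi_distributions(
    schedules: list[ShellSchedule],
    boundaries: list[tuple[float, float, float]],
) -> PhiDistributions:
    """One mean-φ sample per fitted run per regime.

    ``boundaries`` holds per-schedule (SLT, TLT, end) seconds from lysis
    start, as in :func:`clotlyse.shells.aggregate_phi`.  Runs with an empty
    regime are excluded from that regime's distribution (with a warning).
    """
    import warnings

    slow, fast = [], []
    for sched, (slt, tlt, _end) in zip(schedules, boundaries):
        phi, t = sched.phi, sched.t
        m_slow = t < slt
        m_fast = (t >= slt) & (t < tlt)
        if np.any(m_slow):
            slow.append(float(np.mean(phi[m_slow])))
        else:
            warnings.warn("schedule with empty slow regime excluded")
        if np.any(m_fast):
            fast.append(float(np.mean(phi[m_fast])))
        else:
            warnings.warn("schedule with empty fast regime excluded")
    if not slow or not fast:
        raise ClotlyseError("no schedule contributed to one of the regimes")
    return PhiDistributions(slow=np.array(slow), fast=np.array(fast))


def run_surrogate(
    clot: ClotState,
    dists: PhiDistributions,
    seed: int,
    rates: BindingRates | None = None,
    constants: ClotConstants | None = None,
    dt: float = DT_DEFAULT,
    t_max: float = 36000.0,
    redraw_every: int = 1,
    record_every: int = 1,
) -> tuple[LysisTrajectory, float, float]:
    """Surrogate lysis run; returns (trajectory, SLT, FLT) in seconds.

    Each step computes R̃_f; while above ``r_tilde_slow`` the shell fraction
    is drawn from the slow distribution, otherwise from the fast one, and
    κ = round(φ·κ_max) clamped to [0, κ_max].  ``redraw_every`` controls the
    draw cadence in steps (default: every step); the draw also refreshes
    whenever the regime switches.  The radius is nonincreasing, so the
    switch happens at most once per run.  SLT/FLT are NaN if the respective
    threshold is never crossed before exhaustion or ``t_max``.
    """
    rates = rates or BindingRates()
    constants = constants or ClotConstants.from_clot_state(clot)
    rng = np.random.default_rng(seed)
    y = initial_lysis_vector(clot, constants)
    g = constants.geometry

    n_steps = int(round(t_max / dt))
    rec_t, rec_l, rec_rf, rec_eps, rec_k, rec_sp = [], [], [], [], [], []
    slt = float("nan")
    flt_end = float("nan")
    exhausted = False
    phi = None
    in_slow = True

    def record(t, y, rf, kap):
        rec_t.append(t)
        rec_l.append(y[IL])
        rec_rf.append(rf)
        rec_eps.append(porosity(rf, constants))
        rec_k.append(kap)
        rec_sp.append(y[1:].copy())

    t = 0.0
    record(t, y, constants.rf0, 0)
    for i in range(n_steps):
        rf = update_radius(min(y[IL], constants.cfr0), constants)
        r_tilde = rf / constants.rf0
        now_slow = r_tilde > dists.r_tilde_slow
        if np.isnan(slt) and not now_slow:
            slt = t
        if np.isnan(flt_end) and r_tilde <= dists.r_tilde_fast:
            flt_end = t
        if phi is None or i % redraw_every == 0 or now_slow != in_slow:
            pool = dists.slow if now_slow else dists.fast
            phi = float(rng.choice(pool))
        in_slow = now_slow
        kmax = kappa_max(rf, g.r0)
        kap = int(np.clip(round(phi * kmax), 0, kmax))
        y = euler_step(y, kap, rates, constants, dt)
        t = (i + 1) * dt
        if y[IL] >= EXHAUSTION * constants.cfr0:
            y[IL] = min(y[IL], constants.cfr0)
            record(t, y, update_radius(y[IL], constants), kap)
            exhausted = True
            break
        if (i + 1) % record_every == 0:
            record(t, y, update_radius(min(y[IL], constants.cfr0), constants), kap)

    traj = LysisTrajectory(
        t=np.array(rec_t),
        l=np.array(rec_l),
        rf=np.array(rec_rf),
        eps=np.array(rec_eps),
        kappa=np.array(rec_k, dtype=int),
        species=np.array(rec_sp),
        cfr0=constants.cfr0,
        rf0=constants.rf0,
        exhausted=exhausted,
    )
    flt = flt_end - slt if not (np.isnan(slt) or np.isnan(flt_end)) else float("nan")
    return traj, slt, flt


def surrogate_timescale_summary(
    clot: ClotState,
    dists: PhiDistributions,
    seeds: list[int] | np.ndarray,
    **kwargs,
) -> dict:
    """Median and quartiles of SLT/FLT over repeated seeded surrogate runs."""
    import warnings

    slts, flts = [], []
    for s in seeds:
        _, slt, flt = run_surrogate(clot, dists, int(s), **kwargs)
        slts.append(slt)
        flts.append(flt)
    slts, flts = np.asarray(slts), np.asarray(flts)
    if np.all(np.isnan(slts)):
        warnings.warn("no run crossed the slow-regime radius threshold; "
                      "timescales reported as NaN")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return _summary_dict(slts, flts)


def _summary_dict(slts: np.ndarray, flts: np.ndarray) -> dict:
    return {
        "slt_median": float(np.nanmedian(slts)),
        "flt_median": float(np.nanmedian(flts)),
        "slt_q1": float(np.nanpercentile(slts, 25)),
        "slt_q3": float(np.nanpercentile(slts, 75)),
        "flt_q1": float(np.nanpercentile(flts, 25)),
        "flt_q3": float(np.nanpercentile(flts, 75)),
        "n": len(slts),
    }
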