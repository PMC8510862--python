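"""Plasmin-mediated fiber degradation with a pluggable shell policy.

Bound plasmin cleaves the fibrin exposed in the κ outer protofibril layers
of each fiber.  The cumulative lysed fibrin L(t) integrates a
Michaelis–Menten rate,

    dL/dt = γ · k_Pn2 · [Pn_b] · Θ_Pn / (K_PnM + Θ_Pn),

with γ the solubilization factor (fibrin released to plasma per cleavage).
Because fibers shed material from the outside at constant internal density,
the radius and clot porosity follow L in closed form:

    R_f²(t) = R_f0² · (1 − L/C_fr0),      ε = 1 − (1 − ε0)·(R_f/R_f0)².

During lysis, bound concentrations are defined per fibrin-phase volume.
Free and bound phases couple through s = (1 − ε)/ε; the conserved quantity
for each species is the published mass relation  [i] + s·[i]_b = [i]_0
(up to PAI-1 inhibition and Pg → Pn conversion), which the right-hand side
preserves exactly: the fluid phase exchanges the adsorption/desorption
fluxes, and shrinking fibrin volume returns bound material to the fluid
through the ds/dt term.

The shell count κ may be fixed (surface κ=0, full bulk, any constant) or a
time schedule; the per-step optimal-κ fitting lives in ``shells``.
Integration is fixed-step explicit Euler on the Δt = 0.1 s grid used by the
schedule optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import InvalidStateError
from .formation import BindingRates, BindingState, ClotState
from .geometry import FiberGeometry, exposed_fraction, fibrin_phase_concentration_uM, kappa_max

DT_DEFAULT = 0.1  # s, the simulation grid
EXHAUSTION = 1.0 - 1e-6  # stop when L >= EXHAUSTION * cfr0 (avoids ε → 1 blowup)

# state-vector layout for the lysis ODE
# [l, tpa, tpa_b, pg, pg_b, pai1, pn, pn_b]
IL, ITPA, ITPAB, IPG, IPGB, IPAI, IPN, IPNB = range(8)
N_LYSIS = 8


@dataclass
class ClotConstants:
    """Geometric and solubilization constants of one clot undergoing lysis."""

    cfr0: float  # fibrin in fibers at lysis start, µM whole-volume
    rf0: float  # initial fiber radius, nm
    gamma: float = 0.1  # solubilization factor, fibrin released per cleavage
    geometry: FiberGeometry = field(default_factory=FiberGeometry)
    eps0: float | None = None  # initial porosity; derived from cfr0 if None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1] (0 = no solubilization)")
        #: fibrin monomer concentration within the fibrin phase (µM); constant
        #: during lysis because fibers shrink at constant internal density.
        self.c_fibrin_phase = fibrin_phase_concentration_uM(self.geometry)
        if self.eps0 is None:
            self.eps0 = 1.0 - self.cfr0 / self.c_fibrin_phase
        if not (0.0 < self.eps0 < 1.0):
            raise ValueError(f"initial porosity {self.eps0} outside (0, 1)")

    @classmethod
    def from_clot_state(cls, clot: ClotState, gamma: float = 0.1) -> "ClotConstants":
        return cls(cfr0=clot.cfr0_uM, rf0=clot.rf0, gamma=gamma, geometry=clot.geometry)


def lysis_rate(pn_b: float, theta_pn: float, constants: ClotConstants, rates: BindingRates) -> float:
    """Michaelis–Menten cleavage rate γ·k_Pn2·[Pn_b]·Θ_Pn/(K_PnM + Θ_Pn).

    Both arguments in fibrin-phase µM; zero when either is zero.
    """
    if pn_b <= 0.0 or theta_pn <= 0.0:
        return 0.0
    return constants.gamma * rates.k_pn2 * pn_b * theta_pn / (rates.K_pn_M + theta_pn)


def update_radius(l: float, constants: ClotConstants) -> float:
    """Fiber radius after cumulative lysis ``l``: rf² = rf0²·(1 − l/cfr0)."""
    if l < 0 or l > constants.cfr0 * (1 + 1e-12):
        raise InvalidStateError(f"lysed fibrin {l} outside [0, cfr0={constants.cfr0}]")
    frac = max(0.0, 1.0 - l / constants.cfr0)
    return constants.rf0 * math.sqrt(frac)


def porosity(rf: float, constants: ClotConstants) -> float:
    """Clot porosity ε = 1 − (1 − ε0)·(rf/rf0)²; ε → 1 at complete lysis."""
    if constants.rf0 <= 0:
        return 1.0
    return 1.0 - (1.0 - constants.eps0) * (rf / constants.rf0) ** 2


@dataclass
class LysisState:
    """Snapshot of the lysis system at one time point."""

    t: float  # s
    l: float  # cumulative lysed fibrin, µM whole-volume
    rf: float  # nm
    eps: float
    kappa: int
    binding: BindingState  # bound species per fibrin-phase volume
    theta_tpa: float = 0.0  # fibrin-phase µM
    theta_pg: float = 0.0
    theta_pn: float = 0.0


def lysis_rhs(
    y: np.ndarray,
    kappa: int,
    rates: BindingRates,
    constants: ClotConstants,
) -> np.ndarray:
    """Time derivative of [L, tPA, tPA_b, Pg, Pg_b, PAI-1, Pn, Pn_b].

    Fluid species are whole-fluid µM, bound species fibrin-phase µM.  The
    geometry (rf, ε, Θ) is algebraic in L.  Free plasmin is inert: it
    accumulates from Pn_b desorption and never rebinds.
    """
    c = constants
    g = c.geometry
    l = min(y[IL], c.cfr0)
    rf = update_radius(l, c)
    eps = porosity(rf, c)
    s = (1.0 - eps) / eps

    kap = min(kappa, kappa_max(rf, g.r0))
    frac = exposed_fraction(rf, kap, g.r0, g.p0) if rf > 0 else 0.0
    theta_tpa = g.q_tpa * c.c_fibrin_phase * frac
    theta_pg = g.q_pg * c.c_fibrin_phase * frac
    theta_pn = g.q_pn * c.c_fibrin_phase * frac

    tpa, tpa_b = y[ITPA], y[ITPAB]
    pg, pg_b = y[IPG], y[IPGB]
    pai1, pn_b = y[IPAI], y[IPNB]
    r = rates

    j_tpa = r.kf_tpa * tpa * (theta_tpa - tpa_b) - r.kr_tpa * tpa_b
    j_pg = r.kf_pg * pg * (theta_pg - pg_b - pn_b) - r.kr_pg * pg_b
    act = r.k_tpa_pg2 * tpa_b * pg_b / (r.K_tpa_pg_M + pg_b) if pg_b > 0 else 0.0
    inhib = r.ki_tpa_pai * tpa * pai1

    dl = (1.0 - eps) * lysis_rate(pn_b, theta_pn, c, r) if rf > 0 else 0.0

    # ds/dt < 0 as lysis proceeds; −(ds/dt)·[i]_b returns bound material on
    # dissolved fibrin to the fluid, keeping [i] + s·[i]_b conserved.
    deps = (1.0 - c.eps0) * dl / c.cfr0
    release = deps / (eps * eps)

    dy = np.empty(N_LYSIS)
    dy[IL] = dl
    dy[ITPA] = -s * j_tpa + release * tpa_b - inhib
    dy[ITPAB] = j_tpa
    dy[IPG] = -s * j_pg + release * pg_b
    dy[IPGB] = j_pg - act
    dy[IPAI] = -inhib
    dy[IPN] = s * r.kr_pn * pn_b + release * pn_b
    dy[IPNB] = act - r.kr_pn * pn_b
    return dy


def euler_step(
    y: np.ndarray,
    kappa: int,
    rates: BindingRates,
    constants: ClotConstants,
    dt: float,
) -> np.ndarray:
    """One conservative explicit Euler step of the lysis system.

    Bound species and L advance by their rates; fluid species are then
    updated from the discrete forms of the mass relations, so that
    [i] + s·[i]_b (minus inhibited/converted amounts) is preserved to
    machine precision regardless of the step size — a plain Euler step of
    :func:`lysis_rhs` would drift O(Δt) through the moving s = (1−ε)/ε
    coupling.
    """
    c = constants
    g = c.geometry
    l = min(y[IL], c.cfr0)
    rf = update_radius(l, c)
    eps = porosity(rf, c)
    s = (1.0 - eps) / eps

    kap = min(kappa, kappa_max(rf, g.r0))
    frac = exposed_fraction(rf, kap, g.r0, g.p0) if rf > 0 else 0.0
    theta_tpa = g.q_tpa * c.c_fibrin_phase * frac
    theta_pg = g.q_pg * c.c_fibrin_phase * frac
    theta_pn = g.q_pn * c.c_fibrin_phase * frac

    tpa, tpa_b = y[ITPA], y[ITPAB]
    pg, pg_b = y[IPG], y[IPGB]
    pai1, pn, pn_b = y[IPAI], y[IPN], y[IPNB]
    r = rates

    j_tpa = r.kf_tpa * tpa * (theta_tpa - tpa_b) - r.kr_tpa * tpa_b
    j_pg = r.kf_pg * pg * (theta_pg - pg_b - pn_b) - r.kr_pg * pg_b
    act = r.k_tpa_pg2 * tpa_b * pg_b / (r.K_tpa_pg_M + pg_b) if pg_b > 0 else 0.0
    inhib = r.ki_tpa_pai * tpa * pai1
    desorb_pn = r.kr_pn * pn_b
    dl = (1.0 - eps) * lysis_rate(pn_b, theta_pn, c, r) if rf > 0 else 0.0

    l1 = min(l + dt * dl, c.cfr0)
    rf1 = update_radius(l1, c)
    eps1 = porosity(rf1, c)
    s1 = (1.0 - eps1) / eps1
    ds = s1 - s  # <= 0: shrinking fibrin returns bound material to the fluid

    out = np.empty(N_LYSIS)
    out[IL] = l1
    out[ITPAB] = tpa_b + dt * j_tpa
    out[IPGB] = pg_b + dt * (j_pg - act)
    out[IPNB] = pn_b + dt * (act - desorb_pn)
    out[ITPA] = tpa - dt * s1 * j_tpa - ds * tpa_b - dt * inhib
    out[IPG] = pg - dt * s1 * j_pg - ds * pg_b
    out[IPN] = pn + dt * s1 * desorb_pn - ds * pn_b
    out[IPAI] = pai1 - dt * inhib
    return np.maximum(out, 0.0)


# ---------------------------------------------------------------------------
# policies

PolicyFn = Callable[[float, float, int], int]  # (t, rf, kappa_max) -> kappa


def make_policy(policy) -> PolicyFn:
    """Resolve a policy spec to a callable (t, rf, κ_max) → κ.

    Accepted: 'surface' (κ=0), 'bulk' (κ=κ_max), an integer (fixed κ,
    clamped to the shrinking κ_max), a callable, or a (time_s, kappa) array
    schedule interpolated with previous-value semantics.
    """
    if callable(policy):
        return policy
    if policy == "surface":
        return lambda t, rf, kmax: 0
    if policy == "bulk":
        return lambda t, rf, kmax: kmax
    if isinstance(policy, (int, np.integer)):
        k = int(policy)
        if k < 0:
            raise ValueError("fixed kappa must be >= 0")
        return lambda t, rf, kmax: min(k, kmax)
    if isinstance(policy, (tuple, list)) and len(policy) == 2:
        times, kappas = (np.asarray(policy[0], float), np.asarray(policy[1], float))
        def schedule(t, rf, kmax):
            i = np.searchsorted(times, t, side="right") - 1
            i = max(0, min(i, len(kappas) - 1))
            return min(int(round(kappas[i])), kmax)
        return schedule
    raise ValueError(f"unrecognized shell policy: {policy!r}")


@dataclass
class LysisTrajectory:
    """Recorded lysis time course on the fixed Δt grid."""

    t: np.ndarray  # s
    l: np.ndarray  # µM whole-volume
    rf: np.ndarray  # nm
    eps: np.ndarray
    kappa: np.ndarray  # shells used at each step
    species: np.ndarray  # (n, 7): tpa, tpa_b, pg, pg_b, pai1, pn, pn_b
    cfr0: float
    rf0: float
    exhausted: bool

    @property
    def percent(self) -> np.ndarray:
        return 100.0 * self.l / self.cfr0

    @property
    def rf_norm(self) -> np.ndarray:
        """Normalized radius R̃_f = rf/rf0."""
        return self.rf / self.rf0

    def total_lysis_time(self) -> float:
        """Time of fibrin exhaustion (s); NaN if the run hit t_max first."""
        return float(self.t[-1]) if self.exhausted else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "t_s": self.t,
                "l_uM": self.l,
                "percent": self.percent,
                "rf_nm": self.rf,
                "eps": self.eps,
                "kappa": self.kappa,
            }
        )
        for i, name in enumerate(["tpa", "tpa_b", "pg", "pg_b", "pai1", "pn", "pn_b"]):
            df[name] = self.species[:, i]
        return df


def initial_lysis_vector(clot: ClotState, constants: ClotConstants) -> np.ndarray:
    """Lysis state at t=0 from an end-of-clotting snapshot.

    Whole-volume bound concentrations from the formation stage are converted
    to fibrin-phase units by dividing by the fibrin volume fraction (1−ε0).
    """
    b = clot.binding
    phase = 1.0 - constants.eps0
    if phase <= 0:
        raise InvalidStateError("no fibrin phase at lysis start")
    y0 = np.zeros(N_LYSIS)
    y0[ITPA] = b.tpa
    y0[ITPAB] = b.tpa_b / phase
    y0[IPG] = b.pg
    y0[IPGB] = b.pg_b / phase
    y0[IPAI] = b.pai1
    y0[IPN] = b.pn
    y0[IPNB] = b.pn_b / phase
    return y0


def run_fibrinolysis(
    clot: ClotState,
    policy="surface",
    rates: BindingRates | None = None,
    constants: ClotConstants | None = None,
    dt: float = DT_DEFAULT,
    t_max: float = 36000.0,
    record_every: int = 1,
    substeps: int = 1,
) -> LysisTrajectory:
    """Fixed-step lysis integration under a shell policy.

    Explicit Euler on the Δt grid (optionally ``substeps`` internal Euler
    sub-steps per grid step for stiff binding parameters).  κ_max is
    recomputed from the current radius every step; the run stops at fibrin
    exhaustion (L ≥ (1−1e-6)·C_fr0) or ``t_max``.
    """
    rates = rates or BindingRates()
    constants = constants or ClotConstants.from_clot_state(clot)
    pol = make_policy(policy)
    y = initial_lysis_vector(clot, constants)
    g = constants.geometry

    n_steps = int(round(t_max / dt))
    rec_t, rec_l, rec_rf, rec_eps, rec_k, rec_sp = [], [], [], [], [], []
    exhausted = False

    def record(t, y, kap):
        rec_t.append(t)
        rec_l.append(y[IL])
        rf = update_radius(min(y[IL], constants.cfr0), constants)
        rec_rf.append(rf)
        rec_eps.append(porosity(rf, constants))
        rec_k.append(kap)
        rec_sp.append(y[1:].copy())

    t = 0.0
    rf = constants.rf0
    kap = pol(t, rf, kappa_max(rf, g.r0))
    record(t, y, kap)
    h = dt / substeps
    for i in range(n_steps):
        rf = update_radius(min(y[IL], constants.cfr0), constants)
        kap = pol(t, rf, kappa_max(rf, g.r0))
        for _ in range(substeps):
            y = euler_step(y, kap, rates, constants, h)
        t = (i + 1) * dt
        if y[IL] >= EXHAUSTION * constants.cfr0:
            y[IL] = min(y[IL], constants.cfr0)
            record(t, y, kap)
            exhausted = True
            break
        if (i + 1) % record_every == 0:
            record(t, y, kap)

    if not exhausted and rec_t[-1] < t:
        record(t, y, kap)
    return LysisTrajectory(
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


def synthetic_clot_state(
    cfr0_uM: float = 2.0,
    rf0: float = 50.0,
    tpa_b: float = 0.0,
    pg_b: float = 0.0,
    pn_b: float = 1e-3,
    tpa: float = 0.0,
    pg: float = 0.0,
    pai1: float = 0.0,
    geometry: FiberGeometry | None = None,
) -> ClotState:
    """Construct a clot state directly, bypassing the formation model.

    Intended for lysis-model studies where the initial bound-protein load is
    prescribed rather than produced by polymerization (bound concentrations
    are whole-volume µM, as the formation model reports them).
    """
    from .formation import PolymerizationState

    geom = geometry or FiberGeometry()
    return ClotState(
        poly=PolymerizationState(),
        binding=BindingState(tpa=tpa, tpa_b=tpa_b, pg=pg, pg_b=pg_b, pai1=pai1, pn_b=pn_b),
        rf0=rf0,
        theta_tpa=0.0,
        theta_pg=0.0,
        cfr0_uM=cfr0_uM,
        frac_incorporated=float("nan"),
        geometry=geom,
    )
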