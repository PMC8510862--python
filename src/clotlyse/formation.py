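"""Fibrin polymerization coupled to protein binding during clot formation.

The polymerization model follows the classic kinetic scheme: thrombin-driven
conversion of fibrinogen ``fa`` to monomer ``f1`` (rate kA), stepwise
monomer addition building oligomers ``f2..f10`` (kPI), protofibril creation
once the 11-monomer threshold is reached, protofibril elongation by monomer
addition (kPG), protofibril–protofibril association into fibers (kFI),
protofibril addition to fibers (kFG) and fiber–fiber aggregation (kFA).
Bookkeeping species track the protofibrils incorporated into fibers
(``fntot``) and the fibrin content of protofibrils (``cfn``) and fibers
(``cfr``).  All polymerization concentrations are molecules·L⁻¹ because the
published rate constants are printed in L·molecules⁻¹·s⁻¹.

While fibers assemble, tPA and Pg adsorb reversibly onto them (binding-site
capacity Θ recomputed from the instantaneous fiber geometry), bound tPA
activates bound Pg to bound plasmin by Michaelis–Menten kinetics, and PAI-1
irreversibly inhibits free tPA.  The binding subsystem runs in µM.  The
final state — bound protein concentrations, fiber radius R_f0, fibrin
incorporated into fibers — is the initial condition for the lysis model.

Total fibrin  M = fa + f1 + Σ_j j·f_j + cfn + cfr  is conserved exactly by
the scheme (the oligomer chain telescopes); the test-suite checks this
against a stoichiometry-matrix oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from . import units
from .conditions import ExperimentCondition
from .errors import InvalidStateError, SolverError
from .geometry import (
    FiberGeometry,
    exposed_fraction,
    fiber_radius,
    kappa_max,
)

MAX_OLIGOMER = 10  # protofibrils form at 11 monomers: f1 + f10 -> protofibril


@dataclass
class PolymerizationRates:
    """Kinetic constants of the polymerization scheme.

    kA in s⁻¹; the rest in L·molecules⁻¹·s⁻¹.  Defaults are the best-ranked
    set from the published grid search.  (kPG appears in the source table
    with a positive exponent, a typographical sign loss; the physically
    meaningful value 1e-15 is used.)
    """

    kA: float = 0.02
    kPI: float = 1e-17
    kPG: float = 1e-15
    kFI: float = 1e-18
    kFG: float = 1e-16
    kFA: float = 1e-18
    oligomer_threshold: int = 11

    def __post_init__(self) -> None:
        if self.oligomer_threshold != MAX_OLIGOMER + 1:
            raise NotImplementedError(
                "only the 11-monomer protofibril threshold is implemented"
            )
        for name in ("kA", "kPI", "kPG", "kFI", "kFG", "kFA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BindingRates:
    """Adsorption/desorption, activation and inhibition constants (µM, s)."""

    kf_pg: float = 1.087e-4  # µM⁻¹ s⁻¹
    kr_pg: float = 5.435e-5  # s⁻¹
    kf_tpa: float = 1.148e-4  # µM⁻¹ s⁻¹
    kr_tpa: float = 6.658e-5  # s⁻¹
    k_tpa_pg2: float = 0.2  # s⁻¹  (kcat of bound-Pg activation by bound tPA)
    K_tpa_pg_M: float = 0.02  # µM
    k_pn2: float = 25.0  # s⁻¹  (kcat of bound-plasmin fibrin cleavage)
    K_pn_M: float = 250.0  # µM
    kr_pn: float = 5.435e-5  # s⁻¹
    ki_tpa_pai: float = 25.0  # µM⁻¹ s⁻¹


@dataclass
class PolymerizationState:
    """Concentrations (molecules·L⁻¹) of the polymerization species."""

    fa: float = 0.0
    f1: float = 0.0
    fj: np.ndarray = field(default_factory=lambda: np.zeros(MAX_OLIGOMER - 1))
    fn: float = 0.0
    fr: float = 0.0
    fntot: float = 0.0
    cfn: float = 0.0
    cfr: float = 0.0

    def __post_init__(self) -> None:
        self.fj = np.asarray(self.fj, dtype=float)
        if self.fj.shape != (MAX_OLIGOMER - 1,):
            raise InvalidStateError(f"fj must hold sizes 2..{MAX_OLIGOMER}")

    def validate(self) -> None:
        vec = self.to_vector()
        if np.any(vec < 0):
            raise InvalidStateError("negative polymerization concentration")

    def total_fibrin(self) -> float:
        """Conserved total: fa + f1 + Σ j·fj + cfn + cfr (molecules/L)."""
        sizes = np.arange(2, MAX_OLIGOMER + 1)
        return float(self.fa + self.f1 + np.dot(sizes, self.fj) + self.cfn + self.cfr)

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.fa, self.f1], self.fj, [self.fn, self.fr, self.fntot, self.cfn, self.cfr]]
        )

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "PolymerizationState":
        n = MAX_OLIGOMER - 1
        return cls(
            fa=float(y[0]),
            f1=float(y[1]),
            fj=np.array(y[2 : 2 + n]),
            fn=float(y[2 + n]),
            fr=float(y[3 + n]),
            fntot=float(y[4 + n]),
            cfn=float(y[5 + n]),
            cfr=float(y[6 + n]),
        )


N_POLY = 2 + (MAX_OLIGOMER - 1) + 5  # 16 polymerization components


@dataclass
class BindingState:
    """Free/bound protein concentrations in µM (pn only used during lysis)."""

    tpa: float = 0.0
    tpa_b: float = 0.0
    pg: float = 0.0
    pg_b: float = 0.0
    pai1: float = 0.0
    pn_b: float = 0.0
    pn: float = 0.0

    def validate(self) -> None:
        for name in ("tpa", "tpa_b", "pg", "pg_b", "pai1", "pn_b", "pn"):
            if getattr(self, name) < 0:
                raise InvalidStateError(f"negative concentration: {name}")


def polymerization_rhs(
    state: PolymerizationState, rates: PolymerizationRates
) -> PolymerizationState:
    """Time derivatives of the polymerization species.

    The oligomer chain loses two monomers per dimerization (one as the
    ``f1`` reactant, one through the j = 1 term of the sum) and one per
    elongation step; protofibril creation deposits 11 monomers at once into
    the protofibril fibrin pool ``cfn``.  The fiber–fiber aggregation term
    kFA·fr² feeds ``fntot`` exactly as the scheme is published.
    """
    state.validate()
    kA, kPI, kPG = rates.kA, rates.kPI, rates.kPG
    kFI, kFG, kFA = rates.kFI, rates.kFG, rates.kFA
    fa, f1, fj = state.fa, state.f1, state.fj
    fn, fr = state.fn, state.fr

    sum_f = f1 + float(np.sum(fj))  # Σ_{j=1..10} f_j
    dfa = -kA * fa
    df1 = kA * fa - kPI * f1 * (f1 + sum_f) - kPG * f1 * fn
    # d f_j = kPI f1 (f_{j-1} − f_j), j = 2..10 with f_1 as the chain head
    prev = np.concatenate([[f1], fj[:-1]])
    dfj = kPI * f1 * (prev - fj)
    f10 = fj[-1]
    dfn = kPI * f1 * f10 - 2.0 * kFI * fn * fn - kFG * fr * fn
    dfr = kFI * fn * fn - kFA * fr * fr
    dfntot = 2.0 * kFI * fn * fn + kFG * fr * fn + kFA * fr * fr
    dcfn = (
        (MAX_OLIGOMER + 1) * kPI * f1 * f10
        + kPG * f1 * fn
        - 2.0 * kFI * fn * state.cfn
        - kFG * fr * state.cfn
    )
    dcfr = 2.0 * kFI * fn * state.cfn + kFG * fr * state.cfn
    return PolymerizationState(dfa, df1, dfj, dfn, dfr, dfntot, dcfn, dcfr)


def binding_rhs(
    bstate: BindingState,
    theta_tpa: float,
    theta_pg: float,
    rates: BindingRates,
) -> BindingState:
    """Time derivatives of the protein binding subsystem (µM/s).

    Mass-action adsorption onto free sites (Θ − bound), first-order
    desorption, Michaelis–Menten activation of bound Pg by bound tPA,
    irreversible PAI-1 inhibition of free tPA, and bound plasmin competing
    with Pg for the same sites.
    """
    r = rates
    tpa, tpa_b = bstate.tpa, bstate.tpa_b
    pg, pg_b, pn_b = bstate.pg, bstate.pg_b, bstate.pn_b
    pai1 = bstate.pai1

    free_tpa_sites = theta_tpa - tpa_b
    free_pg_sites = theta_pg - pg_b - pn_b
    inhib = r.ki_tpa_pai * tpa * pai1
    j_tpa = r.kf_tpa * tpa * free_tpa_sites - r.kr_tpa * tpa_b
    j_pg = r.kf_pg * pg * free_pg_sites - r.kr_pg * pg_b
    act = r.k_tpa_pg2 * tpa_b * pg_b / (r.K_tpa_pg_M + pg_b) if pg_b > 0 else 0.0

    return BindingState(
        tpa=-j_tpa - inhib,
        tpa_b=j_tpa,
        pg=-j_pg,
        pg_b=j_pg - act,
        pai1=-inhib,
        pn_b=act - r.kr_pn * pn_b,
        pn=0.0,
    )


@dataclass
class ClotState:
    """End-of-clotting snapshot handed to the fibrinolysis model."""

    poly: PolymerizationState
    binding: BindingState
    rf0: float  # nm
    theta_tpa: float  # µM, whole-volume
    theta_pg: float  # µM, whole-volume
    cfr0_uM: float  # fibrin in fibers, µM whole-volume
    frac_incorporated: float  # fibrin in fibers / total fibrin
    geometry: FiberGeometry = field(default_factory=FiberGeometry)
    tpa_inhibited: float = 0.0  # accumulated tPA·PAI-1 complex, µM
    t_clot: float = 1000.0  # s

    def as_dict(self) -> dict:
        d = asdict(self)
        d["poly"]["fj"] = list(self.poly.fj)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClotState":
        with open(path) as fh:
            d = json.load(fh)
        d["poly"] = PolymerizationState(**d["poly"])
        d["binding"] = BindingState(**d["binding"])
        d["geometry"] = FiberGeometry(**d["geometry"])
        return cls(**d)


def _theta_uM(poly_vec: np.ndarray, geom: FiberGeometry, kappa: int, q: float) -> float:
    """Whole-volume site concentration (µM) for the current polymer state.

    Θ = q · [fibrin in fibers] · (exposed fraction of the cross-section):
    only the fibrin monomers in the κ outer protofibril layers present
    binding sites.
    """
    n = MAX_OLIGOMER - 1
    fn_tot, cfr = poly_vec[4 + n], poly_vec[6 + n]
    fr = poly_vec[3 + n]
    if cfr <= 0 or fn_tot <= 0 or fr <= 0:
        return 0.0
    rf = fiber_radius(fn_tot, fr, geom.p0)
    kap = min(kappa, kappa_max(rf, geom.r0))
    frac = exposed_fraction(rf, kap, geom.r0, geom.p0)
    return units.molecules_per_L_to_uM(q * cfr * frac)


def run_clot_formation(
    condition: ExperimentCondition | None = None,
    poly_rates: PolymerizationRates | None = None,
    bind_rates: BindingRates | None = None,
    geometry: FiberGeometry | None = None,
    t_clot: float = 1000.0,
    kappa: int = 0,
    rtol: float = 1e-8,
    molecular_weights: dict[str, float] | None = None,
    dense_output: bool = False,
):
    """Integrate polymerization + binding from t = 0 to ``t_clot`` seconds.

    During formation only adsorption onto the exposed layers is considered;
    by default κ = 0 (surface), consistent with reactions starting at the
    fiber surface.  Θ is recomputed continuously from the current fiber
    content and radius inside the right-hand side.

    Returns a :class:`ClotState`.  With ``dense_output=True`` returns
    ``(ClotState, scipy OdeSolution)`` for inspection of the transient.
    """
    condition = condition or ExperimentCondition()
    poly_rates = poly_rates or PolymerizationRates()
    bind_rates = bind_rates or BindingRates()
    geom = geometry or FiberGeometry()

    fa0 = units.mg_ml_to_molecules_per_L(condition.fibrinogen, "fibrinogen", molecular_weights)
    tpa0 = units.ug_ml_to_uM(condition.tpa, "tpa", molecular_weights)
    pg0 = units.ug_ml_to_uM(condition.pg, "pg", molecular_weights)
    pai0 = units.ug_ml_to_uM(condition.pai1, "pai1", molecular_weights)

    y0 = np.zeros(N_POLY + 7)
    y0[0] = fa0
    y0[N_POLY + 0] = tpa0
    y0[N_POLY + 2] = pg0
    y0[N_POLY + 4] = pai0
    # y[N_POLY + 5] = pn_b, y[N_POLY + 6] = inhibited-tPA accumulator

    r = bind_rates

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        poly = PolymerizationState.from_vector(np.maximum(y[:N_POLY], 0.0))
        dpoly = polymerization_rhs(poly, poly_rates)
        th_tpa = _theta_uM(y, geom, kappa, geom.q_tpa)
        th_pg = _theta_uM(y, geom, kappa, geom.q_pg)
        b = BindingState(
            tpa=max(y[N_POLY], 0.0),
            tpa_b=max(y[N_POLY + 1], 0.0),
            pg=max(y[N_POLY + 2], 0.0),
            pg_b=max(y[N_POLY + 3], 0.0),
            pai1=max(y[N_POLY + 4], 0.0),
            pn_b=max(y[N_POLY + 5], 0.0),
        )
        db = binding_rhs(b, th_tpa, th_pg, r)
        inhib_rate = r.ki_tpa_pai * b.tpa * b.pai1
        return np.concatenate(
            [
                dpoly.to_vector(),
                [db.tpa, db.tpa_b, db.pg, db.pg_b, db.pai1, db.pn_b, inhib_rate],
            ]
        )

    atol = np.empty(N_POLY + 7)
    atol[:N_POLY] = max(fa0, 1.0) * 1e-12
    atol[N_POLY:] = 1e-16
    sol = solve_ivp(
        rhs,
        (0.0, t_clot),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=dense_output,
    )
    if not sol.success:
        raise SolverError(f"clot-formation integration failed: {sol.message}")

    yf = np.maximum(sol.y[:, -1], 0.0)
    poly = PolymerizationState.from_vector(yf[:N_POLY])
    binding = BindingState(
        tpa=yf[N_POLY],
        tpa_b=yf[N_POLY + 1],
        pg=yf[N_POLY + 2],
        pg_b=yf[N_POLY + 3],
        pai1=yf[N_POLY + 4],
        pn_b=yf[N_POLY + 5],
    )
    rf0 = fiber_radius(poly.fntot, poly.fr, geom.p0) if poly.fr > 0 else 0.0
    state = ClotState(
        poly=poly,
        binding=binding,
        rf0=rf0,
        theta_tpa=_theta_uM(yf, geom, kappa, geom.q_tpa),
        theta_pg=_theta_uM(yf, geom, kappa, geom.q_pg),
        cfr0_uM=units.molecules_per_L_to_uM(poly.cfr),
        frac_incorporated=poly.cfr / fa0 if fa0 > 0 else 0.0,
        geometry=geom,
        tpa_inhibited=float(yf[N_POLY + 6]),
        t_clot=t_clot,
    )
    if dense_output:
        return state, sol
    return state


def bound_tpa_percent(state: ClotState, tpa0_uM: float) -> float:
    """100 · [tPA_b] / [tPA]₀ at the end of clotting."""
    return 100.0 * state.binding.tpa_b / tpa0_uM
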