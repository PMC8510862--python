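"""Fiber cross-section geometry: radius, shells, and binding-site counts.

A fibrin fiber is modeled as a cylindrical bundle of protofibrils packed at
areal density ``p0`` (protofibrils per nm² of cross-section).  Reactions may
involve only the outer ``kappa`` protofibril layers ("shells") of the fiber:
κ = 0 is the bare surface annulus, κ = R_f/r0 the entire bulk.  The number
of protofibrils in the κ outer layers follows from integrating the packing
density over the annulus [R_f − κ·r0, R_f + r0]:

    m(R_f, κ) = π·p0·(2·r0·R_f·(1 + κ) + r0²·(1 − κ²))

Binding-site capacities Θ for tPA/Pg/plasmin scale with the fibrin content
of those exposed layers times the per-monomer site count q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidStateError

#: protofibril packing density in the fiber cross-section, protofibrils/nm²
P0_DEFAULT = 0.01116
#: protofibril radius, nm (not printed with the model; standard value)
R0_DEFAULT = 5.0
#: monomers per nm of protofibril: two half-staggered strands per 22.5 nm repeat
LAMBDA_P_DEFAULT = 2.0 / 22.5

Q_TPA = 1.5  # tPA binding sites per fibrin monomer
Q_PG = 2.4  # Pg binding sites per fibrin monomer
Q_PN_DEFAULT = 1.0  # plasmin substrate sites per exposed monomer (model choice)


@dataclass(frozen=True)
class FiberGeometry:
    """Packing and site parameters of the fiber cross-section model."""

    p0: float = P0_DEFAULT  # protofibrils / nm²
    r0: float = R0_DEFAULT  # nm
    lambda_p: float = LAMBDA_P_DEFAULT  # monomers / nm / protofibril
    q_tpa: float = Q_TPA
    q_pg: float = Q_PG
    q_pn: float = Q_PN_DEFAULT


def fiber_radius(fntot: float, fr: float, p0: float = P0_DEFAULT) -> float:
    """Average fiber radius in nm from protofibril content.

    ``fntot/fr`` is the mean number of protofibrils per fiber; dividing by
    the packing density and π gives the cross-section area, hence
    R_f = sqrt(fntot / (fr·π·p0)).
    """
    if fntot < 0:
        raise InvalidStateError("fntot must be >= 0")
    if fntot == 0:
        return 0.0
    if fr <= 0:
        raise InvalidStateError("fiber radius undefined: fr = 0 with fntot > 0")
    return math.sqrt((fntot / fr) / (math.pi * p0))


def kappa_max(rf: float, r0: float = R0_DEFAULT) -> int:
    """Number of available shells: ceil(R_f / r0)."""
    return int(math.ceil(rf / r0)) if rf > 0 else 0


def shell_protofibril_count(
    rf: float, kappa: float, r0: float = R0_DEFAULT, p0: float = P0_DEFAULT
) -> float:
    """Protofibrils in the κ outer layers of a fiber of radius ``rf``.

    Annulus integral of the packing density over [max(rf − κ·r0, 0), rf + r0]:

        m = π·p0·((rf + r0)² − max(rf − κ·r0, 0)²)

    which expands to the closed form π·p0·(2·r0·rf·(1+κ) + r0²·(1−κ²))
    whenever κ·r0 ≤ rf; beyond that the inner boundary has reached the fiber
    axis and m equals the whole cross-section π·p0·(rf + r0)².
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    inner = max(rf - kappa * r0, 0.0)
    return math.pi * p0 * ((rf + r0) ** 2 - inner**2)


def exposed_fraction(
    rf: float, kappa: float, r0: float = R0_DEFAULT, p0: float = P0_DEFAULT
) -> float:
    """Fraction of a fiber's protofibrils lying in the κ outer layers.

    Both numerator and denominator come from the annulus integral:
    m(rf, κ) / m(rf, κ_max) with m(rf, κ_max) = π·p0·(rf + r0)².  Bounded in
    (0, 1] by construction, smooth in rf, and exactly 1 for full-bulk κ.
    """
    if rf <= 0:
        return 1.0
    m = shell_protofibril_count(rf, kappa, r0, p0)
    m_total = math.pi * p0 * (rf + r0) ** 2
    return m / m_total


def binding_sites(
    cfr: float,
    fntot: float,
    fr: float,
    m: float,
    q: float,
    literal: bool = False,
) -> float:
    """Concentration of accessible binding sites, in the units of ``cfr``.

    ``cfr/fntot`` is the number of fibrin monomers per protofibril in the
    fibers, so ``(cfr/fntot)·m·q`` counts sites per fiber over the exposed
    layers.  Multiplying by the fiber number concentration ``fr`` returns a
    site concentration — equivalently Θ = q·cfr·min(1, m·fr/fntot), the
    exposed fraction of all fibrin.  With ``literal=True`` the raw
    sites-per-fiber count ``(cfr/fntot)·m·q`` is returned instead (the
    un-normalized textbook form, kept for comparison).
    """
    if cfr < 0 or fntot < 0:
        raise InvalidStateError("cfr and fntot must be >= 0")
    if cfr == 0:
        return 0.0
    if fntot == 0:
        raise InvalidStateError("inconsistent state: cfr > 0 with fntot = 0")
    if literal:
        return (cfr / fntot) * m * q
    exposed_fraction = min(1.0, m * fr / fntot)
    return q * cfr * exposed_fraction


def fibrin_phase_concentration_uM(geom: FiberGeometry) -> float:
    """Fibrin monomer concentration inside the fibrin phase, in µM.

    Fibers lyse by shedding outer shells at constant internal density, so
    the within-phase monomer concentration p0·λ_p (monomers per nm³) is a
    constant of the lysis.  1 L = 1e24 nm³.
    """
    from .units import molecules_per_L_to_uM

    per_nm3 = geom.p0 * geom.lambda_p
    return molecules_per_L_to_uM(per_nm3 * 1e24)
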