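"""Unit conversions between laboratory and model concentration units.

The polymerization equations use molecules per litre (their rate constants
are printed in L·molecules⁻¹·s⁻¹) while the protein binding equations use
µM.  Lab protocols state fibrinogen in mg·mL⁻¹ and the fibrinolytic
proteins in µg·mL⁻¹.  All conversions route through molar concentration
using per-species molecular weights.

Molecular weights are literature standards (kDa): fibrinogen 340, tPA 68,
plasminogen 92, PAI-1 43.  They can be overridden per call.
"""

from __future__ import annotations

from .errors import UnitConversionError

N_AVOGADRO = 6.02214076e23  # molecules per mol

#: Default molecular weights in kDa (= kg/mol = g/mmol = mg/µmol).
MOLECULAR_WEIGHTS_KDA: dict[str, float] = {
    "fibrinogen": 340.0,
    "tpa": 68.0,
    "pg": 92.0,
    "pai1": 43.0,
}


def _mw(species: str, molecular_weights: dict[str, float] | None) -> float:
    table = MOLECULAR_WEIGHTS_KDA if molecular_weights is None else molecular_weights
    try:
        return float(table[species])
    except KeyError:
        raise UnitConversionError(
            f"no molecular weight for species {species!r}; known: {sorted(table)}"
        ) from None


def mg_ml_to_uM(value: float, species: str, molecular_weights: dict[str, float] | None = None) -> float:
    """mg·mL⁻¹ → µM.  mg/mL equals g/L; dividing by MW (g/mol) gives mol/L."""
    mw_g_mol = _mw(species, molecular_weights) * 1e3
    return value / mw_g_mol * 1e6


def uM_to_mg_ml(value: float, species: str, molecular_weights: dict[str, float] | None = None) -> float:
    mw_g_mol = _mw(species, molecular_weights) * 1e3
    return value * 1e-6 * mw_g_mol


def ug_ml_to_uM(value: float, species: str, molecular_weights: dict[str, float] | None = None) -> float:
    """µg·mL⁻¹ → µM (µg/mL = mg/L)."""
    return mg_ml_to_uM(value * 1e-3, species, molecular_weights)


def uM_to_ug_ml(value: float, species: str, molecular_weights: dict[str, float] | None = None) -> float:
    return uM_to_mg_ml(value, species, molecular_weights) * 1e3


def uM_to_molecules_per_L(value: float) -> float:
    return value * 1e-6 * N_AVOGADRO


def molecules_per_L_to_uM(value: float) -> float:
    return value / N_AVOGADRO * 1e6


def mg_ml_to_molecules_per_L(value: float, species: str, molecular_weights: dict[str, float] | None = None) -> float:
    return uM_to_molecules_per_L(mg_ml_to_uM(value, species, molecular_weights))
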