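"""Experimental conditions for the turbidimetric clot-lysis assay.

The reference assay mixes fibrinogen, plasminogen (Pg), tissue plasminogen
activator (tPA) and PAI-1 at varying concentrations, clots with excess
thrombin, and follows turbidity over time.  ``table1_conditions`` returns
the 19 published condition rows (one concentration varied at a time around
the control case), 74 usable replicate experiments in total.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ExperimentCondition:
    """One assay condition: concentrations in lab units plus replicate count."""

    fibrinogen: float = 3.0  # mg/mL
    tpa: float = 0.001  # µg/mL
    pai1: float = 0.01  # µg/mL
    pg: float = 13.0  # µg/mL
    n_replicates: int = 1
    label: str = "control"

    def __post_init__(self) -> None:
        for name in ("fibrinogen", "tpa", "pai1", "pg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


CONTROL = ExperimentCondition(3.0, 0.001, 0.01, 13.0, 18, "control")

# (fibrinogen mg/mL, tPA µg/mL, PAI-1 µg/mL, Pg µg/mL, usable replicates)
_TABLE1_ROWS = [
    (3.0, 0.0005, 0.01, 13.0, 4),
    (3.0, 0.001, 0.01, 13.0, 18),  # control case
    (3.0, 0.002, 0.01, 13.0, 4),
    (3.0, 0.004, 0.01, 13.0, 4),
    (3.0, 0.008, 0.01, 13.0, 4),
    (3.0, 0.001, 0.0025, 13.0, 4),
    (3.0, 0.001, 0.005, 13.0, 4),
    (3.0, 0.001, 0.02, 13.0, 4),
    (3.0, 0.001, 0.04, 13.0, 2),
    (3.0, 0.001, 0.01, 2.6, 3),
    (3.0, 0.001, 0.01, 5.2, 4),
    (3.0, 0.001, 0.01, 26.0, 4),
    (3.0, 0.001, 0.01, 52.0, 4),
    (0.8, 0.001, 0.01, 13.0, 2),
    (1.0, 0.001, 0.01, 13.0, 2),
    (2.0, 0.001, 0.01, 13.0, 2),
    (4.0, 0.001, 0.01, 13.0, 2),
    (5.0, 0.001, 0.01, 13.0, 1),
    (6.0, 0.001, 0.01, 13.0, 2),
]


def table1_conditions() -> list[ExperimentCondition]:
    """The 19 published assay conditions; replicate counts sum to 74."""
    out = []
    for i, (fg, tpa, pai1, pg, n) in enumerate(_TABLE1_ROWS, start=1):
        label = "control" if i == 2 else f"cond{i:02d}"
        out.append(ExperimentCondition(fg, tpa, pai1, pg, n, label))
    return out
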