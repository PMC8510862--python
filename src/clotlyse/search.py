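"""Polymerization-parameter selection and variance-based sensitivity.

The six polymerization constants are largely unknown, so candidate sets are
screened in three stages:

1. ``evaluate_grid`` — run clot formation (1000 s) for each candidate set at
   fibrinogen 1–4 mg·mL⁻¹ (control protein levels) and keep sets whose
   simulated fiber diameters fall in a measured acceptance window at every
   concentration and which incorporate ≥ 80% of the fibrinogen into fibers.
2. ``max_error``/``rank_score`` — score surviving sets against lysis curves:
   per experiment, store the maximal |simulated − target| percent-lysis
   deviation up to the total lysis time, rank sets by it (ascending,
   average ranks on ties), and sum ranks over experiments.  With S sets and
   E experiments the worst possible summed rank is S·E (always last);
   scores are normalized by it, so they live in [1/S, 1].
3. ``sobol_sensitivity`` — first-, second- and total-order Sobol indices of
   any model output with respect to the parameters, using the Saltelli
   sampling scheme on a Sobol' low-discrepancy sequence (log-uniform
   parameter ranges by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .conditions import ExperimentCondition
from .errors import ClotlyseError, SolverError
from .formation import PolymerizationRates, run_clot_formation

PARAM_NAMES = ("kA", "kPI", "kPG", "kFI", "kFG", "kFA")

#: Log-spaced decade ranges bracketing the published best set; the original
#: discretization is configuration territory, these are overridable defaults.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "kA": (2e-3, 2e-1),
    "kPI": (1e-18, 1e-16),
    "kPG": (1e-16, 1e-14),
    "kFI": (1e-19, 1e-17),
    "kFG": (1e-17, 1e-15),
    "kFA": (1e-19, 1e-17),
}


@dataclass
class ParameterGrid:
    """Cartesian product of per-parameter value lists."""

    values: dict[str, list[float]]

    def __post_init__(self) -> None:
        for name in self.values:
            if name not in PARAM_NAMES:
                raise ClotlyseError(f"unknown polymerization parameter {name!r}")
            if any(v <= 0 for v in self.values[name]):
                raise ClotlyseError(f"{name} values must be > 0")

    @property
    def size(self) -> int:
        n = 1
        for v in self.values.values():
            n *= len(v)
        return n

    def __iter__(self):
        names = list(self.values)
        for combo in itertools.product(*(self.values[n] for n in names)):
            params = dict(zip(names, combo))
            yield PolymerizationRates(**params)


@dataclass
class GridFilters:
    """Acceptance window for the grid screen.

    ``diameter_window_nm`` is a measured (min, max) on the simulated fiber
    diameter 2·R_f0; it is a required input because the reference
    measurements are laboratory data, not model constants.
    """

    diameter_window_nm: tuple[float, float]
    min_incorporation: float = 0.80
    fibrinogen_mg_ml: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)


def evaluate_grid(
    grid: ParameterGrid,
    filters: GridFilters,
    condition: ExperimentCondition | None = None,
    t_clot: float = 1000.0,
) -> tuple[list[PolymerizationRates], pd.DataFrame]:
    """Screen candidate sets by fiber diameter and fibrinogen incorporation.

    Each set runs clot formation at every fibrinogen concentration in the
    filter (other concentrations from ``condition``, default control).  A
    set survives if, at every concentration, 2·R_f0 falls inside the window
    and the incorporated fraction is ≥ the threshold.  Solver failures are
    recorded and exclude the set.  Returns (survivors, diagnostics table).
    """
    base = condition or ExperimentCondition()
    lo, hi = filters.diameter_window_nm
    survivors: list[PolymerizationRates] = []
    rows = []
    for idx, rates in enumerate(grid):
        ok = True
        for fg in filters.fibrinogen_mg_ml:
            cond = ExperimentCondition(
                fibrinogen=fg, tpa=base.tpa, pai1=base.pai1, pg=base.pg, label=base.label
            )
            try:
                cs = run_clot_formation(cond, poly_rates=rates, t_clot=t_clot)
            except SolverError as exc:
                rows.append(
                    {"set": idx, "fibrinogen": fg, "diameter_nm": np.nan,
                     "incorporated": np.nan, "ok": False, "error": str(exc)}
                )
                ok = False
                break
            diam = 2.0 * cs.rf0
            inc = cs.frac_incorporated
            passed = (lo <= diam <= hi) and inc >= filters.min_incorporation
            rows.append(
                {"set": idx, "fibrinogen": fg, "diameter_nm": diam,
                 "incorporated": inc, "ok": passed, "error": ""}
            )
            if not passed:
                ok = False
                break
        if ok:
            survivors.append(rates)
    return survivors, pd.DataFrame(rows)


def max_error(
    t_sim: np.ndarray,
    y_sim: np.ndarray,
    t_ref: np.ndarray,
    y_ref: np.ndarray,
    up_to: float,
) -> float:
    """Maximal |simulated − reference| up to the total lysis time.

    Series on different grids are first linearly resampled onto the
    simulated grid; both must share a scale (percent or fraction).  The
    maximum is a conservative deviation measure: a lysis curve cannot dip
    back toward the reference after overshooting, so a single large
    deviation is meaningful.
    """
    mask = np.asarray(t_sim) <= up_to
    if not np.any(mask):
        raise ClotlyseError("no simulated samples at or before the truncation time")
    ref = np.interp(np.asarray(t_sim)[mask], np.asarray(t_ref), np.asarray(y_ref))
    return float(np.max(np.abs(np.asarray(y_sim)[mask] - ref)))


@dataclass
class RankScore:
    """Summed-rank scores for S parameter sets over E experiments."""

    ranks: np.ndarray  # (S, E), average ranks on ties, NaN errors ranked last
    summed: np.ndarray  # (S,)
    normalized: np.ndarray  # summed / (S·E), in [1/S, 1]
    best_index: int

    @property
    def worst_possible(self) -> float:
        s, e = self.ranks.shape
        return float(s * e)


def rank_score(errors: np.ndarray) -> RankScore:
    """Rank-based scoring of an (S sets × E experiments) error matrix.

    Per experiment, sets are ranked by error ascending (average rank on
    ties; NaN ranks last).  The score of a set is its summed rank over
    experiments, normalized by the worst possible summed rank S·E, which
    penalizes large errors by order statistics regardless of magnitude.
    """
    err = np.asarray(errors, dtype=float)
    if err.ndim != 2 or err.size == 0:
        raise ClotlyseError("errors must be a non-empty S×E matrix")
    filled = np.where(np.isnan(err), np.inf, err)
    ranks = np.vstack(
        [rankdata(filled[:, j], method="average") for j in range(err.shape[1])]
    ).T
    summed = ranks.sum(axis=1)
    s, e = err.shape
    normalized = summed / (s * e)
    return RankScore(
        ranks=ranks,
        summed=summed,
        normalized=normalized,
        best_index=int(np.argmin(summed)),
    )


# ---------------------------------------------------------------------------
# Sobol sensitivity (Saltelli scheme)

@dataclass
class SobolResult:
    """Variance-based sensitivity indices for one scalar model output."""

    names: tuple[str, ...]
    s1: np.ndarray  # first order
    st: np.ndarray  # total order
    s2: np.ndarray | None  # (d, d) second order, upper triangle
    s1_ci: np.ndarray | None = None  # 95% bootstrap half-widths
    st_ci: np.ndarray | None = None
    n_base: int = 0
    seed: int = 0
    n_failed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.names, "S1": self.s1, "ST": self.st}
        )


def saltelli_sample(
    ranges: dict[str, tuple[float, float]],
    n: int,
    seed: int,
    log_scale: bool = True,
    second_order: bool = True,
) -> np.ndarray:
    """Saltelli cross-sampling design on a scrambled Sobol' sequence.

    Returns a matrix of shape (n·(2d+2), d) for second-order estimation or
    (n·(d+2), d) without, ordered as [A; B; A_B^(1..d); (B_A^(1..d))].
    Parameters are mapped from the unit cube to ``ranges`` (log-uniform by
    default, matching decade-spanning kinetic constants).
    """
    names = list(ranges)
    d = len(names)
    sampler = qmc.Sobol(2 * d, scramble=True, rng=np.random.default_rng(seed))
    base = sampler.random(n)
    a, b = base[:, :d], base[:, d:]
    blocks = [a, b]
    for i in range(d):
        ab = a.copy()
        ab[:, i] = b[:, i]
        blocks.append(ab)
    if second_order:
        for i in range(d):
            ba = b.copy()
            ba[:, i] = a[:, i]
            blocks.append(ba)
    unit = np.vstack(blocks)
    lo = np.array([ranges[k][0] for k in names])
    hi = np.array([ranges[k][1] for k in names])
    if log_scale:
        return np.exp(np.log(lo) + unit * (np.log(hi) - np.log(lo)))
    return lo + unit * (hi - lo)


def sobol_indices_from_outputs(
    f: np.ndarray, d: int, n: int, second_order: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Saltelli/Jansen estimators from the stacked block outputs."""
    fa, fb = f[:n], f[n : 2 * n]
    fab = np.stack([f[(2 + i) * n : (3 + i) * n] for i in range(d)], axis=1)
    var = np.var(np.concatenate([fa, fb]), ddof=1)
    if var == 0:
        raise ClotlyseError("model output has zero variance over the sample")
    s1 = np.array([np.mean(fb * (fab[:, i] - fa)) for i in range(d)]) / var
    st = np.array([0.5 * np.mean((fa - fab[:, i]) ** 2) for i in range(d)]) / var
    s2 = None
    if second_order:
        fba = np.stack(
            [f[(2 + d + i) * n : (3 + d + i) * n] for i in range(d)], axis=1
        )
        s2 = np.full((d, d), np.nan)
        for i in range(d):
            for j in range(i + 1, d):
                vij = np.mean(fba[:, i] * fab[:, j]) - np.mean(fa * fb)
                s2[i, j] = vij / var - s1[i] - s1[j]
    return s1, st, s2


def sobol_sensitivity(
    model,
    ranges: dict[str, tuple[float, float]] | None = None,
    n: int = 1024,
    seed: int = 7,
    log_scale: bool = True,
    second_order: bool = True,
    n_bootstrap: int = 100,
) -> SobolResult:
    """Sobol indices of ``model(params: dict) -> float`` over ``ranges``.

    ``n`` is the base sample size (powers of two keep the Sobol' sequence
    balanced); the model runs n·(2d+2) times with second-order indices,
    n·(d+2) without.  Failing model evaluations (exceptions or NaN) discard
    the whole cross-sample row to keep the estimators paired; the count is
    reported.  95% bootstrap half-widths are attached for S1 and ST.
    """
    ranges = ranges or DEFAULT_RANGES
    names = tuple(ranges)
    d = len(names)
    x = saltelli_sample(ranges, n, seed, log_scale, second_order)
    outs = np.empty(x.shape[0])
    for i, row in enumerate(x):
        params = dict(zip(names, row))
        try:
            outs[i] = float(model(params))
        except Exception:
            outs[i] = np.nan

    blocks = 2 * d + 2 if second_order else d + 2
    per_row = outs.reshape(blocks, n).T  # row = one cross-sample
    good = ~np.any(np.isnan(per_row), axis=1)
    n_failed = int(np.sum(~good))
    kept = per_row[good]
    n_eff = kept.shape[0]
    if n_eff < 8:
        raise ClotlyseError("too many failed model evaluations for Sobol analysis")
    f = kept.T.reshape(-1)
    s1, st, s2 = sobol_indices_from_outputs(f, d, n_eff, second_order)

    s1_ci = st_ci = None
    if n_bootstrap:
        rng = np.random.default_rng(seed + 1)
        s1_bs = np.empty((n_bootstrap, d))
        st_bs = np.empty((n_bootstrap, d))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n_eff, n_eff)
            fb_ = kept[idx].T.reshape(-1)
            s1_bs[b], st_bs[b], _ = sobol_indices_from_outputs(
                fb_, d, n_eff, second_order=False
            )
        s1_ci = 1.96 * s1_bs.std(axis=0)
        st_ci = 1.96 * st_bs.std(axis=0)

    return SobolResult(
        names=names, s1=s1, st=st, s2=s2, s1_ci=s1_ci, st_ci=st_ci,
        n_base=n, seed=seed, n_failed=n_failed,
    )


def formation_output_model(output: str = "tpa_b", condition: ExperimentCondition | None = None,
                           t_clot: float = 1000.0):
    """Model closure for Sobol analysis of the clot-formation stage.

    ``output`` selects bound tPA concentration ('tpa_b', µM) or the initial
    fiber radius ('rf0', nm).
    """
    cond = condition or ExperimentCondition()

    def model(params: dict) -> float:
        rates = PolymerizationRates(**params)
        cs = run_clot_formation(cond, poly_rates=rates, t_clot=t_clot)
        if output == "tpa_b":
            return cs.binding.tpa_b
        if output == "rf0":
            return cs.rf0
        raise ClotlyseError(f"unknown output {output!r}")

    return model
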