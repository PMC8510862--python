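"""Synthetic turbidity assays with known ground-truth timescales.

No public dataset accompanies the turbidimetric assay, so every analysis
path in the package is exercised on generated traces with the same
statistical structure: an eight-channel device sampling once per minute,
a sigmoidal clotting descent reaching the turbidity minimum at CFT, a
linear slow-lysis ramp (ending near NT ≈ 0.1, where the slow regime is
observed to end), and a fast sigmoidal rise whose maximal derivative marks
the total lysis time, plus additive Gaussian sensor noise.

Two generators are provided:

* :func:`generate_phenomenological` — a piecewise-analytic curve with fully
  configurable (CFT, SLT, FLT, slope); ground truth is returned alongside,
  making detector round-trips exact by construction.
* :func:`generate_mechanistic` — the forward kinetic models (clot formation
  then shell-policy lysis) mapped affinely from fibrin-in-fibers to
  intensity; ground truth is the simulation's own regime geometry.

The fast-rise steepness is tied to the Δ = 0.005 regime-boundary threshold:
the logistic's deviation from the extended slow-regime line crosses Δ
exactly at the configured SLT, so the backward-scan detector's boundary is
the generator's boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .conditions import ExperimentCondition, table1_conditions  # noqa: F401 (re-export)
from .errors import ConfigError
from .turbidity import DELTA_DEFAULT, END_OF_LYSIS_NT, LysisTimescales, TurbidityTrace


@dataclass
class SyntheticAssayConfig:
    """Shape and noise parameters of a phenomenological assay curve.

    Defaults reproduce the published across-condition means: CFT 19 min,
    SLT 73 min, FLT 67 min, with the slow ramp ending at NT = 0.1.
    """

    baseline: float = 1000.0  # intensity before clotting, sensor units
    delta_turbidity: float = 700.0  # max − min intensity span
    cft: float = 19.0  # min
    slt: float = 73.0  # min
    flt: float = 67.0  # min
    slow_slope: float | None = None  # NT/min; default nt_end_slow/slt
    nt_end_slow: float = 0.1  # NT level where the slow regime ends
    noise_sd: float = 0.005  # fraction of delta_turbidity
    duration: float | None = None  # min; default covers end of lysis
    n_channels: int = 8
    seed: int = 0
    delta_threshold: float = DELTA_DEFAULT  # ties fast-rise onset to Δ

    def __post_init__(self) -> None:
        if min(self.cft, self.slt, self.flt) <= 0:
            raise ConfigError("cft, slt and flt must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 1 <= self.n_channels <= 8:
            raise ConfigError("the device has 1..8 channels")
        if self.slow_slope is None:
            self.slow_slope = self.nt_end_slow / self.slt
        if self.slow_slope <= 0:
            raise ConfigError("slow_slope must be positive")

    # derived geometry -----------------------------------------------------
    @property
    def t_slow_end(self) -> float:
        return self.cft + self.slt

    @property
    def t_tlt(self) -> float:
        return self.cft + self.slt + self.flt

    def fast_amplitude(self) -> float:
        line_at_tc = self.slow_slope * (self.t_tlt - self.cft)
        return max(1.15 * (1.0 - line_at_tc), 0.2)

    def fast_rise_window(self) -> tuple[float, float, float]:
        """(t_on, T, a): onset, duration and amplitude of the fast rise.

        The rise is a·S((t−t_on)/T) with the cubic smoothstep
        S(x) = 3x² − 2x³: identically zero before onset (so it cannot bias
        the slow-regime line fit), maximal slope at the midpoint t_on + T/2,
        which is placed at the TLT.  The onset is chosen so the deviation
        from the extended slow-regime line reaches the Δ threshold exactly
        at the configured SLT, making the backward-scan boundary the
        generator's boundary.
        """
        a = self.fast_amplitude()
        # solve a·S(x*) = Δ for the small root: x²(3 − 2x) = Δ/a
        q = self.delta_threshold / a
        x = math.sqrt(q / 3.0)
        for _ in range(3):
            x = math.sqrt(q / (3.0 - 2.0 * x))
        t_on = (self.t_slow_end - 2.0 * x * self.t_tlt) / (1.0 - 2.0 * x)
        t_on = max(t_on, self.cft)
        T = 2.0 * (self.t_tlt - t_on)
        return t_on, T, a

    def total_duration(self) -> float:
        if self.duration is not None:
            return self.duration
        t_on, T, _ = self.fast_rise_window()
        return t_on + T + 15.0


def nt_shape(cfg: SyntheticAssayConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free NT(t) for the piecewise assay model (t in minutes)."""
    t = np.asarray(t, dtype=float)
    nt = np.empty_like(t)
    s = cfg.slow_slope
    t_on, T, a = cfg.fast_rise_window()

    # clotting descent: smooth half-cosine from 1 to 0, minimum exactly at CFT
    m_des = t < cfg.cft
    nt[m_des] = 0.5 * (1.0 + np.cos(np.pi * t[m_des] / cfg.cft))
    # lysis: linear slow ramp plus a smoothstep fast rise centred at the TLT
    m_lys = ~m_des
    line = s * (t[m_lys] - cfg.cft)
    x = np.clip((t[m_lys] - t_on) / T, 0.0, 1.0)
    rise = a * (3.0 * x**2 - 2.0 * x**3)
    nt[m_lys] = np.minimum(line + rise, 1.0)
    return nt


def ground_truth(cfg: SyntheticAssayConfig) -> LysisTimescales:
    """Exact timescales of the noise-free shape (minutes; offsets from CFT)."""
    t = np.arange(0.0, cfg.total_duration() + 1.0)
    nt = nt_shape(cfg, t)
    after = t >= cfg.t_tlt
    reached = after & (nt >= END_OF_LYSIS_NT)
    end = float(t[reached][0]) if np.any(reached) else float("nan")
    r_sl = cfg.slt / (cfg.slt + cfg.flt)
    return LysisTimescales(
        cft=cfg.cft,
        slt=cfg.slt,
        flt=cfg.flt,
        tlt=cfg.slt + cfg.flt,
        end_of_lysis=end,
        slow_slope=cfg.slow_slope,
        r_sl=r_sl,
        r_fl=1.0 - r_sl,
        delta_turbidity=cfg.delta_turbidity,
        channel_id="truth",
    )


def generate_phenomenological(
    cfg: SyntheticAssayConfig,
) -> tuple[list[TurbidityTrace], LysisTimescales]:
    """Generate noisy per-channel traces plus the shared ground truth.

    Intensity maps NT affinely: baseline at NT = 1, baseline − Δturbidity at
    the clotting minimum.  One master seed spawns independent per-channel
    noise streams; the underlying curve is identical across channels.
    """
    t = np.arange(0.0, cfg.total_duration() + 1.0)  # 1-minute sampling
    nt = nt_shape(cfg, t)
    base_intensity = cfg.baseline - cfg.delta_turbidity * (1.0 - nt)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_channels)
    traces = []
    for ch in range(cfg.n_channels):
        rng = np.random.default_rng(streams[ch])
        noise = rng.normal(0.0, cfg.noise_sd * cfg.delta_turbidity, size=t.shape)
        traces.append(TurbidityTrace(t, base_intensity + noise, f"ch{ch}"))
    return traces, ground_truth(cfg)


def generate_batch(
    n: int,
    base_cfg: SyntheticAssayConfig | None = None,
    seed: int = 0,
    cft_range: tuple[float, float] = (10.0, 40.0),
    slt_range: tuple[float, float] = (30.0, 150.0),
    flt_range: tuple[float, float] = (30.0, 120.0),
) -> list[tuple[list[TurbidityTrace], LysisTimescales, SyntheticAssayConfig]]:
    """A batch of single-channel assays with randomized regime durations.

    The slow slope follows the observed structure (the slow regime ends near
    a fixed NT level), so 1/slope is proportional to SLT across the batch.
    """
    base = base_cfg or SyntheticAssayConfig()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cfg = replace(
            base,
            cft=float(rng.uniform(*cft_range)),
            slt=float(rng.uniform(*slt_range)),
            flt=float(rng.uniform(*flt_range)),
            slow_slope=None,
            duration=None,
            n_channels=1,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        traces, truth = generate_phenomenological(cfg)
        out.append((traces, truth, cfg))
    return out


def generate_mechanistic(
    condition: ExperimentCondition | None = None,
    policy="surface-bulk",
    noise_sd: float = 0.005,
    seed: int = 0,
    baseline: float = 1000.0,
    delta_turbidity: float = 700.0,
    dt: float = 0.1,
    t_max: float = 36000.0,
    clot_state=None,
    r_tilde_switch: float = 0.9,
    include_formation: bool = False,
    gamma: float = 0.1,
):
    """Forward-model trace: clot formation, then lysis under a shell policy.

    ``policy='surface-bulk'`` uses κ = 0 while R̃_f > ``r_tilde_switch`` and
    full bulk after — the mechanism proposed for the slow→fast transition.
    Any policy accepted by :func:`clotlyse.lysis.make_policy` works too.
    Intensity is affine in fibrin-in-fibers, sampled at 1 minute with seeded
    Gaussian noise.  By default the trace starts at the clotting minimum
    (lysis onset at t = 0): the kinetic model polymerizes in a few minutes
    (clotting is then held to its nominal 1000 s), which at 1-minute
    sampling is a near-step the smoothing filter cannot follow.
    ``include_formation=True`` prepends the descent anyway.
    Returns (trace, lysis trajectory, clot state).
    """
    from .formation import N_POLY, run_clot_formation
    from .lysis import ClotConstants, run_fibrinolysis

    condition = condition or ExperimentCondition()
    if clot_state is None:
        clot_state, sol = run_clot_formation(condition, dense_output=True)
        t_form = np.arange(0.0, clot_state.t_clot + 1.0, 60.0)
        # fibrin in fibers (cfr) is the last polymerization component
        cfr_form = np.array([max(sol.sol(tv)[N_POLY - 1], 0.0) for tv in t_form])
    else:
        t_form = np.array([0.0])
        cfr_form = np.array([0.0])
    constants = ClotConstants.from_clot_state(clot_state, gamma=gamma)

    if policy == "surface-bulk":
        def pol(t, rf, kmax):
            return 0 if rf / constants.rf0 > r_tilde_switch else kmax
    else:
        pol = policy

    traj = run_fibrinolysis(
        clot_state, pol, constants=constants, dt=dt, t_max=t_max,
        record_every=max(1, int(round(60.0 / dt))),
    )

    # fibrin-in-fibers over the whole record, µM, on the 1-minute grid
    from .units import molecules_per_L_to_uM

    fibrin_lysis = constants.cfr0 - traj.l
    if include_formation:
        fibrin_form = np.array([molecules_per_L_to_uM(v) for v in cfr_form])
        t_all = np.concatenate([t_form, t_form[-1] + traj.t[1:]]) / 60.0  # min
        fibrin = np.concatenate([fibrin_form, fibrin_lysis[1:]])
    else:
        t_all = traj.t / 60.0  # minutes from lysis onset
        fibrin = fibrin_lysis
    cfr_max = max(constants.cfr0, 1e-30)

    intensity = baseline - delta_turbidity * fibrin / cfr_max
    rng = np.random.default_rng(seed)
    intensity = intensity + rng.normal(0.0, noise_sd * delta_turbidity, size=t_all.shape)
    trace = TurbidityTrace(t_all, intensity, condition.label)
    return trace, traj, clot_state
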