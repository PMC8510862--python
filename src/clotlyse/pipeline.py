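"""End-to-end orchestration: synthesis → analysis → models → comparison.

``run_pipeline`` wires the modules into one reproducible run driven by a
single config mapping (typically loaded from YAML).  Stages, in dependency
order:

* ``synth``     — generate phenomenological assay traces per condition;
* ``analyze``   — turbidity analysis of every channel;
* ``formation`` — clot formation per condition (initial state for lysis);
* ``lysis``     — fixed-policy lysis runs (surface and bulk variants);
* ``shells``    — fit the optimal shell schedule against each NT target;
* ``surrogate`` — surrogate runs using the fitted φ distributions;
* ``report``    — per-condition table of model errors and timescales.

Every stochastic stage derives its stream from the master seed; rerunning
with the same config produces identical artifacts.  The manifest records
the config hash, seeds, artifact paths and per-stage status.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conditions import ExperimentCondition
from .errors import ClotlyseError
from .formation import run_clot_formation
from .lysis import ClotConstants, run_fibrinolysis
from .shells import fit_shell_schedule, policy_mse, resample_target
from .surrogate import build_phi_distributions, run_surrogate
from .synthetic import SyntheticAssayConfig, generate_phenomenological
from .turbidity import analyze_trace, preprocess

DEFAULT_STAGES = ("synth", "analyze", "formation", "lysis", "shells", "surrogate", "report")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured stages; returns the manifest (with report).

    ``config`` keys: ``seed`` (int), ``stages`` (list), ``conditions``
    (list of dicts for :class:`SyntheticAssayConfig` overrides, one per
    synthetic condition), ``keep_every``, ``t_max_lysis``.  A stage failure
    marks the stage in the manifest and skips its dependents.
    """
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_hash": config_hash(config),
        "seed": seed,
        "version": __version__,
        "stages": {},
        "artifacts": {},
    }
    ctx: dict = {}

    def run_stage(name, fn):
        if name not in stages:
            manifest["stages"][name] = {"status": "skipped"}
            return
        blocked = [s for s, st in manifest["stages"].items() if st["status"] == "failed"]
        if blocked:
            manifest["stages"][name] = {"status": "blocked", "by": blocked}
            return
        t0 = time.perf_counter()
        try:
            fn()
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
        except ClotlyseError as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}

    # --- synth ------------------------------------------------------------
    def synth():
        cond_cfgs = config.get("conditions", [{}])
        ss = np.random.SeedSequence(seed).spawn(len(cond_cfgs))
        assays = []
        for i, overrides in enumerate(cond_cfgs):
            overrides = dict(overrides)
            label = overrides.pop("label", f"cond{i}")
            cfg = SyntheticAssayConfig(
                **{**overrides, "seed": int(ss[i].generate_state(1)[0] % 2**31)}
            )
            traces, truth = generate_phenomenological(cfg)
            assays.append({"config": cfg, "traces": traces, "truth": truth,
                           "label": label})
        ctx["assays"] = assays

    # --- analyze ----------------------------------------------------------
    def analyze():
        keep_every = int(config.get("keep_every", 3))
        rows = []
        for assay in ctx["assays"]:
            results = []
            for tr in assay["traces"]:
                ts = analyze_trace(tr, keep_every=keep_every)
                results.append(ts)
                rows.append({"condition": assay["label"], **ts.as_dict()})
            assay["timescales"] = results
            assay["nt"] = [preprocess(tr, keep_every) for tr in assay["traces"]]
        df = pd.DataFrame(rows)
        ctx["analysis"] = df
        if out:
            p = out / "timescales.csv"
            df.to_csv(p, index=False)
            manifest["artifacts"]["timescales"] = str(p)

    # --- formation --------------------------------------------------------
    def formation():
        cond = ExperimentCondition(**config.get("experiment_condition", {}))
        ctx["clot"] = run_clot_formation(cond, t_clot=float(config.get("t_clot", 1000.0)))
        if out:
            p = out / "clot_state.json"
            ctx["clot"].to_json(p)
            manifest["artifacts"]["clot_state"] = str(p)

    # --- lysis (fixed-policy variants) -------------------------------------
    def lysis():
        t_max = float(config.get("t_max_lysis", 36000.0))
        cc = ClotConstants.from_clot_state(ctx["clot"])
        ctx["constants"] = cc
        ctx["lysis"] = {
            pol: run_fibrinolysis(ctx["clot"], pol, constants=cc, t_max=t_max,
                                  record_every=10)
            for pol in ("surface", "bulk")
        }

    # --- shells -----------------------------------------------------------
    def shells():
        cc = ctx["constants"]
        fits = []
        for assay in ctx["assays"]:
            nt = assay["nt"][0]
            target = resample_target(nt)
            sched, traj, mse = fit_shell_schedule(ctx["clot"], target, constants=cc)
            ts = assay["timescales"][0]
            boundary = (ts.slt * 60.0, ts.tlt * 60.0, (ts.end_of_lysis - ts.cft) * 60.0)
            fits.append({"label": assay["label"], "schedule": sched, "traj": traj,
                         "mse": mse, "target": target, "boundary": boundary})
        ctx["fits"] = fits

    # --- surrogate --------------------------------------------------------
    def surrogate():
        fits = ctx["fits"]
        dists = build_phi_distributions(
            [f["schedule"] for f in fits], [f["boundary"] for f in fits]
        )
        ctx["dists"] = dists
        t_max = float(config.get("t_max_lysis", 36000.0))
        rng = np.random.default_rng(seed + 1)
        runs = []
        for rep in range(int(config.get("surrogate_reps", 10))):
            traj, slt, flt = run_surrogate(
                ctx["clot"], dists, seed=int(rng.integers(2**31)),
                constants=ctx["constants"], t_max=t_max, record_every=10,
            )
            runs.append({"slt_s": slt, "flt_s": flt})
        ctx["surrogate"] = runs
        if out:
            p = out / "phi_distributions.json"
            dists.to_json(p)
            manifest["artifacts"]["phi_distributions"] = str(p)

    # --- report -----------------------------------------------------------
    def report():
        rows = []
        for f in ctx.get("fits", []):
            row = {"condition": f["label"], "fitted_mse": f["mse"]}
            for pol in ("surface", "bulk"):
                row[f"{pol}_mse"] = policy_mse(
                    ctx["clot"], pol, f["target"], constants=ctx["constants"]
                )
            rows.append(row)
        df = pd.DataFrame(rows)
        ctx["report"] = df
        manifest["report"] = df.to_dict(orient="records")
        if ctx.get("surrogate"):
            manifest["surrogate_timescales"] = ctx["surrogate"]
        if out:
            p = out / "report.csv"
            df.to_csv(p, index=False)
            manifest["artifacts"]["report"] = str(p)

    run_stage("synth", synth)
    run_stage("analyze", analyze)
    run_stage("formation", formation)
    run_stage("lysis", lysis)
    run_stage("shells", shells)
    run_stage("surrogate", surrogate)
    run_stage("report", report)

    if out:
        p = out / "manifest.json"
        with open(p, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    manifest["_context"] = ctx
    return manifest
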