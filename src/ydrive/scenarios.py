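"""Scenario registry and runner: reproducible figure/table data as CSV + JSON.

A :class:`ScenarioConfig` fully specifies one computation — model variant,
parameters, optional seasonal forcing, engine, and an optional sweep axis —
and :func:`run_scenario` materializes it as CSV artifacts plus a JSON
manifest (parameters, versions, seed, runtime).  Deterministic engines are
idempotent: rerunning a scenario from its manifest reproduces the CSVs
byte for byte (numbers are formatted at 10 significant digits).

The built-in registry covers the package's standard outputs: the baseline
elimination trajectory, rescue-probability sweeps over the mutation supply
``uN0``/``vN0``, the growth rate ``R_m``, the drive strength ``m`` and the
fitness ``w`` for both resistance models, (w, R_m) suppression grids,
seasonal release-time scans and amplitude averages, and a stochastic
duration ensemble.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .equilibria import m_crit, suppression_grid
from .genotypes import GenotypeSystem, VARIANTS
from .model_core import cumulative_birth_integrals, initial_state, simulate_trajectory
from .params import ModelParams, SeasonalForcing, calibrate_gamma0
from .rescue import release_time_scan, rescue_summary
from .ssa import SSAConfig, ssa_ensemble

__all__ = ["ScenarioConfig", "run_scenario", "registry", "load_config",
           "validate_config"]

logger = logging.getLogger("ydrive.scenarios")

ENGINES = ("deterministic", "branching", "ssa")


@dataclass
class ScenarioConfig:
    scenario_id: str
    variant: str = "drive"
    engine: str = "deterministic"
    params: dict = field(default_factory=dict)       # ModelParams overrides
    forcing: dict | None = None                       # {a, T}
    t_release: float = 0.0
    sweep: dict | None = None                         # {param, values}
    grid: dict | None = None                          # {w_values, R_m_values}
    n_runs: int = 1000
    seed: int = 0
    horizon: float = 400.0
    description: str = ""

    def model_params(self, **over) -> ModelParams:
        kw = dict(self.params)
        kw.update(over)
        return ModelParams(**kw)


def validate_config(cfg: ScenarioConfig) -> list[str]:
    """Return a list of schema problems (empty when valid)."""
    errors = []
    if cfg.variant not in VARIANTS:
        errors.append(f"variant: {cfg.variant!r} not in {VARIANTS}")
    if cfg.engine not in ENGINES:
        errors.append(f"engine: {cfg.engine!r} not in {ENGINES}")
    if cfg.engine in ("branching",) and cfg.variant not in ("modelI", "modelII"):
        errors.append(f"engine 'branching' requires modelI/modelII, got {cfg.variant!r}")
    try:
        cfg.model_params()
    except (ValueError, TypeError) as exc:
        errors.append(f"params: {exc}")
    if cfg.forcing is not None:
        a = cfg.forcing.get("a", 0.0)
        if not 0.0 <= a < 1.0:
            errors.append(f"forcing.a: must be in [0, 1), got {a}")
        if cfg.forcing.get("T", 18.25) <= 0:
            errors.append("forcing.T: must be positive")
    if cfg.sweep is not None:
        if "param" not in cfg.sweep or "values" not in cfg.sweep:
            errors.append("sweep: needs 'param' and 'values'")
    if cfg.n_runs < 1:
        errors.append(f"n_runs: must be >= 1, got {cfg.n_runs}")
    if cfg.horizon <= 0:
        errors.append(f"horizon: must be positive, got {cfg.horizon}")
    return errors


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a scenario from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ScenarioConfig(**data)


def _fmt_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda x: float(f"{x:.10g}"))
    return out


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    _fmt_frame(df).to_csv(path, index=False, float_format="%.10g")


def _forcing_from(cfg: ScenarioConfig, params: ModelParams) -> SeasonalForcing | None:
    if cfg.forcing is None:
        return None
    return calibrate_gamma0(cfg.forcing.get("a", 0.0),
                            cfg.forcing.get("T", 18.25), params)


def _run_deterministic(cfg: ScenarioConfig, out_dir: Path) -> list[str]:
    params = cfg.model_params()
    if cfg.grid is not None:
        mutation = params.u if cfg.variant == "modelI" else params.v
        df = suppression_grid(cfg.grid["w_values"], cfg.grid["R_m_values"],
                              params.m, mutation, cfg.variant)
        path = out_dir / f"{cfg.scenario_id}_grid.csv"
        _write_csv(df, path)
        return [path.name]
    system = GenotypeSystem.build(cfg.variant, params)
    forcing = _forcing_from(cfg, params)
    y0 = initial_state(params, system, forcing, t_release=cfg.t_release)
    if forcing is not None:
        forcing = forcing.with_phase(cfg.t_release)
    traj = simulate_trajectory(y0, params, system, forcing, horizon=cfg.horizon)
    path = out_dir / f"{cfg.scenario_id}_trajectory.csv"
    _write_csv(traj.to_frame(), path)
    artifacts = [path.name]
    if traj.outcome == "eliminated" and cfg.variant == "drive":
        integ = cumulative_birth_integrals(traj)
        jpath = out_dir / f"{cfg.scenario_id}_birth_integrals.json"
        jpath.write_text(json.dumps(
            {k: v for k, v in integ.items()}, indent=2, default=float))
        artifacts.append(jpath.name)
    return artifacts


def _run_branching(cfg: ScenarioConfig, out_dir: Path) -> list[str]:
    rows = []
    sweep = cfg.sweep or {"param": None, "values": [None]}
    forcing_rows = None
    for val in sweep["values"]:
        over = {}
        if sweep["param"] == "amplitude":
            params = cfg.model_params()
            forcing = calibrate_gamma0(val, (cfg.forcing or {}).get("T", 18.25), params)
            scan = release_time_scan(params, forcing, cfg.variant,
                                     n_release=12, horizon=cfg.horizon)
            rows.append({"amplitude": val,
                         "peak_trough_ratio": _peak_trough(forcing),
                         "P1_avg": scan.attrs["P1_avg"]})
            continue
        if sweep["param"] is not None:
            over[sweep["param"]] = val
        params = cfg.model_params(**over)
        if cfg.forcing is not None and cfg.forcing.get("a", 0.0) > 0.0:
            forcing = _forcing_from(cfg, params)
            scan = release_time_scan(params, forcing, cfg.variant,
                                     n_release=24, horizon=cfg.horizon)
            forcing_rows = scan
            continue
        s = rescue_summary(params, cfg.variant, horizon=cfg.horizon)
        row = {"P_Mut": s.P_Mut, "P1": s.P1, "P_Con": s.P_Con}
        if sweep["param"] is not None:
            row = {sweep["param"]: val, **row}
        rows.append(row)
    artifacts = []
    if rows:
        path = out_dir / f"{cfg.scenario_id}_probabilities.csv"
        _write_csv(pd.DataFrame(rows), path)
        artifacts.append(path.name)
    if forcing_rows is not None:
        path = out_dir / f"{cfg.scenario_id}_release_scan.csv"
        _write_csv(forcing_rows.drop(columns=["failed"], errors="ignore"), path)
        artifacts.append(path.name)
    return artifacts


def _peak_trough(forcing: SeasonalForcing) -> float:
    F = forcing._cycle_F
    if F is None:
        return 1.0
    return float(F.max() / F.min())


def _run_ssa(cfg: ScenarioConfig, out_dir: Path) -> list[str]:
    params = cfg.model_params()
    sc = SSAConfig(params=params, variant=cfg.variant, n_runs=cfg.n_runs,
                   horizon=min(cfg.horizon, 200.0), base_seed=cfg.seed)
    summ = ssa_ensemble(sc)
    runs = pd.DataFrame([{
        "seed": r.seed, "outcome": r.outcome,
        "elimination_time": r.elimination_time,
        "mutation_arisen": r.mutation_arisen,
        "below33": r.below33, "below5": r.below5,
    } for r in summ.runs])
    path = out_dir / f"{cfg.scenario_id}_runs.csv"
    _write_csv(runs, path)
    jpath = out_dir / f"{cfg.scenario_id}_summary.json"
    summary = dataclasses.asdict(summ)
    summary.pop("runs")
    jpath.write_text(json.dumps(summary, indent=2, default=float))
    return [path.name, jpath.name]


def run_scenario(cfg: ScenarioConfig, out_dir: str | Path = "out") -> dict:
    """Execute a scenario and write its artifact set; returns the manifest."""
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid scenario config:\n  " + "\n  ".join(errors))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("running scenario %s (engine=%s variant=%s)",
                cfg.scenario_id, cfg.engine, cfg.variant)
    t0 = time.perf_counter()
    runner = {"deterministic": _run_deterministic,
              "branching": _run_branching,
              "ssa": _run_ssa}[cfg.engine]
    artifacts = runner(cfg, out_dir)
    runtime = time.perf_counter() - t0
    manifest = {
        "scenario": dataclasses.asdict(cfg),
        "artifacts": artifacts,
        "runtime_s": round(runtime, 3),
        "versions": {
            "ydrive": _pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    mpath = out_dir / f"{cfg.scenario_id}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("scenario %s done in %.2fs -> %s", cfg.scenario_id, runtime,
                ", ".join(artifacts))
    return manifest


def registry() -> dict[str, ScenarioConfig]:
    """Built-in scenario catalogue."""
    baseline = dict(R_m=6.0, m=0.95, h0=0.05)
    uN0_axis = list(np.round(np.logspace(-2, 1, 13), 10))
    eps = 1e-3
    m_axis = list(np.round(np.linspace(m_crit(6.0) + eps, 0.999, 9), 10))
    scen = {
        "fig1": ScenarioConfig(
            "fig1", variant="drive", engine="deterministic", params=baseline,
            description="Baseline elimination time course (R_m=6, m=0.95, "
                        "h0=0.05) with cumulative birth integrals."),
        "fig2a": ScenarioConfig(
            "fig2a", variant="modelI", engine="branching", params=baseline,
            sweep={"param": "u", "values": uN0_axis},
            description="Model I probabilities vs mutation supply uN0 "
                        "(normalized N0=1, so u = uN0)."),
        "fig2b": ScenarioConfig(
            "fig2b", variant="modelI", engine="branching", params=baseline,
            sweep={"param": "R_m", "values": [2.5, 3, 4, 5, 6, 8, 9.9]},
            description="Model I probabilities vs intrinsic growth rate R_m "
                        "at uN0=1 (axis capped below the no-elimination "
                        "boundary R_m = 1/[2(1-m)(1-u)])."),
        "fig2c": ScenarioConfig(
            "fig2c", variant="modelI", engine="branching",
            params=dict(baseline, u=1.0),
            sweep={"param": "m", "values": m_axis},
            description="Model I probabilities vs drive strength m in "
                        "(m_crit, 1) at uN0=1."),
        "fig2d": ScenarioConfig(
            "fig2d", variant="modelI", engine="branching",
            params=dict(baseline, u=1.0),
            sweep={"param": "w", "values": [0.6, 0.65, 0.7, 0.8, 0.9, 1.0]},
            description="Model I probabilities vs mutant fitness w at uN0=1."),
        "fig3": ScenarioConfig(
            "fig3", variant="modelI", engine="deterministic",
            params=dict(baseline, u=1e-6),
            grid={"w_values": list(np.round(np.linspace(0.3, 1.0, 15), 10)),
                  "R_m_values": [2, 4, 6, 8, 10, 12]},
            description="Model I deterministic (w, R_m) suppression grid."),
        "fig4": ScenarioConfig(
            "fig4", variant="modelI", engine="branching",
            params=dict(baseline, u=1.0),
            forcing={"a": 0.9825, "T": 18.25}, horizon=600.0,
            description="Seasonal release-time scan of P_Mut, P1, P_Con at "
                        "peak/trough 100:1."),
        "fig5": ScenarioConfig(
            "fig5", variant="modelI", engine="branching",
            params=dict(baseline, u=1.0), horizon=600.0,
            sweep={"param": "amplitude",
                   "values": [0.0, 0.3, 0.6, 0.8, 0.9, 0.9825]},
            description="P1 averaged over release times vs seasonal "
                        "amplitude (γ0[a] recalibrated per point)."),
        "fig6a": ScenarioConfig(
            "fig6a", variant="modelII", engine="branching", params=baseline,
            sweep={"param": "v", "values": uN0_axis},
            description="Model II probabilities vs suppressor supply vN0."),
        "fig6b": ScenarioConfig(
            "fig6b", variant="modelII", engine="branching",
            params=dict(baseline, v=0.1),
            sweep={"param": "R_m", "values": [2.5, 3, 4, 5, 6, 8, 9.9]},
            description="Model II probabilities vs R_m at vN0=0.1."),
        "fig6c": ScenarioConfig(
            "fig6c", variant="modelII", engine="branching",
            params=dict(baseline, v=0.1),
            sweep={"param": "m", "values": m_axis},
            description="Model II probabilities vs drive strength m at vN0=0.1."),
        "fig6d": ScenarioConfig(
            "fig6d", variant="modelII", engine="branching",
            params=dict(baseline, v=0.1),
            sweep={"param": "w", "values": [0.65, 0.7, 0.8, 0.9, 1.0]},
            description="Model II probabilities vs mutant fitness w at vN0=0.1."),
        "fig7": ScenarioConfig(
            "fig7", variant="modelII", engine="deterministic",
            params=dict(baseline, v=1e-7),
            grid={"w_values": list(np.round(np.linspace(0.3, 1.0, 15), 10)),
                  "R_m_values": [2, 4, 6, 8, 10, 12]},
            description="Model II deterministic (w, R_m) suppression grid."),
        "baseline-probabilities": ScenarioConfig(
            "baseline-probabilities", variant="modelI", engine="branching",
            params=dict(baseline, u=1.0),
            description="Baseline Model I outcome probabilities at uN0=1: "
                        "P_Mut, P1, P_Con (elimination probability = 1-P1)."),
        "ssa-durations": ScenarioConfig(
            "ssa-durations", variant="modelI", engine="ssa",
            params=dict(baseline, N0=1e4, u=1e-4), n_runs=2000,
            description="Stochastic ensemble at N0=1e4, uN0=1: rescue "
                        "fractions and suppression-duration statistics."),
    }
    return scen
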