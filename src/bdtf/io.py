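"""Run configuration, tabular serialization, response logs, and scenario
reproduction.

Config files are YAML (JSON is a YAML subset) with four blocks::

    controller:            # update-rule parameters
      lam: 0.01
      target: 0.7          # or schedule: {breakpoints: [0, 1500], targets: [0.7, 0.9]}
      d0: 0.5
    learner:               # skill-curve family + parameters
      family: logistic
      a: 1.0
      b: 1.0
    run:
      n_steps: 2000
      n_replicates: 1
      seed: 0
    output:                # optional
      trajectory: traj.csv
      report: report.json

Trajectories are written as comma-delimited UTF-8 with a fixed header
(``replicate,t,d,x,s_target,seed``) and round-trip-exact floats.  A response
log (columns ``t,d_presented,x``) drives the controller from recorded
outcomes instead of a simulated learner: :func:`next_difficulty` folds the
update rule over the log and returns the difficulty to present next.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import ControllerConfig, DifficultyState, step
from .learners import SkillCurve, curve_from_spec
from .analysis import predict_limit
from .simulation import (
    TargetSchedule,
    Trajectory,
    convergence_time,
    replicate,
    run_session,
    terminal_window_size,
    tracking_experiment,
)

__all__ = [
    "ConfigError",
    "ConfigParseError",
    "ConfigValidationError",
    "RunConfig",
    "load_config",
    "write_trajectory",
    "read_trajectory",
    "ResponseLog",
    "read_response_log",
    "next_difficulty",
    "reproduce_figure",
    "FIGURE_IDS",
]

TRAJECTORY_COLUMNS = ["replicate", "t", "d", "x", "s_target", "seed"]


class ConfigError(Exception):
    """Base class for run-config problems."""


class ConfigParseError(ConfigError):
    """The file is not valid structured text (distinct from validation)."""


class ConfigValidationError(ConfigError):
    """The file parsed but a field is missing, unknown, or invalid."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    controller: ControllerConfig
    curve: SkillCurve
    schedule: Optional[TargetSchedule]
    n_steps: int
    n_replicates: int
    seed: int
    trajectory_path: Optional[str] = None
    report_path: Optional[str] = None


_KNOWN_BLOCKS = {"controller", "learner", "run", "output"}
_KNOWN_KEYS = {
    "controller": {"lam", "target", "schedule", "d0"},
    "run": {"n_steps", "n_replicates", "seed"},
    "output": {"trajectory", "report"},
}


def _require(mapping: dict, block: str, key: str):
    if key not in mapping:
        raise ConfigValidationError(f"{block}.{key}: missing required field")
    return mapping[key]


def load_config(path: str) -> RunConfig:
    """Read and validate a YAML run configuration.

    Unknown keys are rejected with a message naming the key; field errors
    carry their ``block.key`` location.
    """
    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigParseError(f"{path}: not valid YAML: {exc}") from exc
    if raw is None:
        raise ConfigParseError(f"{path}: file is empty")
    if not isinstance(raw, dict):
        raise ConfigParseError(f"{path}: top level must be a mapping")

    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigValidationError(f"unknown block {sorted(unknown)[0]!r}")
    for block, allowed in _KNOWN_KEYS.items():
        extra = set(raw.get(block, {}) or {}) - allowed
        if extra:
            raise ConfigValidationError(
                f"{block}.{sorted(extra)[0]}: unknown key"
            )

    ctrl = raw.get("controller")
    if not isinstance(ctrl, dict):
        raise ConfigValidationError("controller: missing required block")
    learner = raw.get("learner")
    if not isinstance(learner, dict):
        raise ConfigValidationError("learner: missing required block")
    run = raw.get("run") or {}
    output = raw.get("output") or {}

    lam = _require(ctrl, "controller", "lam")
    d0 = ctrl.get("d0", 0.5)
    schedule = None
    if "schedule" in ctrl:
        sch = ctrl["schedule"]
        try:
            schedule = TargetSchedule(
                breakpoints=tuple(int(b) for b in sch["breakpoints"]),
                targets=tuple(float(s) for s in sch["targets"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigValidationError(f"controller.schedule: {exc}") from exc
        target = schedule.targets[0]
    else:
        target = _require(ctrl, "controller", "target")
    try:
        controller = ControllerConfig(lam=float(lam), target=float(target), d0=float(d0))
    except (TypeError, ValueError) as exc:
        raise ConfigValidationError(f"controller.lam: {exc}") from exc

    family = _require(learner, "learner", "family")
    params = {k: v for k, v in learner.items() if k != "family"}
    try:
        curve = curve_from_spec(family, **params)
    except (TypeError, ValueError) as exc:
        raise ConfigValidationError(f"learner.{family}: {exc}") from exc

    try:
        n_steps = int(run.get("n_steps", 2000))
        n_replicates = int(run.get("n_replicates", 1))
        seed = int(run.get("seed", 0))
    except (TypeError, ValueError) as exc:
        raise ConfigValidationError(f"run: {exc}") from exc
    if n_steps < 1:
        raise ConfigValidationError(f"run.n_steps: must be >= 1, got {n_steps}")
    if n_replicates < 1:
        raise ConfigValidationError(
            f"run.n_replicates: must be >= 1, got {n_replicates}"
        )

    return RunConfig(
        controller=controller,
        curve=curve,
        schedule=schedule,
        n_steps=n_steps,
        n_replicates=n_replicates,
        seed=seed,
        trajectory_path=output.get("trajectory"),
        report_path=output.get("report"),
    )


def _trajectory_frame(trajs: Sequence[Trajectory]) -> pd.DataFrame:
    frames = []
    for rep, traj in enumerate(trajs):
        frames.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "t": traj.t,
                    "d": traj.d,
                    "x": traj.x,
                    "s_target": traj.s_target,
                    "seed": traj.seed,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_trajectory(traj, path: str) -> str:
    """Write one trajectory (or a sequence of them) as CSV.

    Columns ``replicate,t,d,x,s_target,seed``; floats use round-trip-safe
    precision so a read-back reproduces every difficulty bit-exactly.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    frame = _trajectory_frame(trajs)
    try:
        frame.to_csv(path, index=False, float_format=None)
    except OSError as exc:
        raise OSError(f"cannot write trajectory to {path}: {exc}") from exc
    return path


def read_trajectory(path: str) -> pd.DataFrame:
    """Read a trajectory CSV back into a DataFrame (floats bit-exact)."""
    return pd.read_csv(path, float_precision="round_trip")


@dataclass(frozen=True)
class ResponseLog:
    """Recorded per-trial outcomes from a real (or replayed) session.

    Rows are (t, d_presented, x): trial index from 0 strictly increasing,
    presented difficulty in [0, 1], binary outcome.
    """

    t: tuple[int, ...]
    d_presented: tuple[float, ...]
    x: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.d_presented) == len(self.x) == n):
            raise ValueError("log columns must have equal length")
        for i in range(n):
            if self.x[i] not in (0, 1):
                raise ValueError(f"row {i}: outcome must be 0 or 1, got {self.x[i]!r}")
            if not (0.0 <= self.d_presented[i] <= 1.0):
                raise ValueError(
                    f"row {i}: difficulty must lie in [0, 1], got {self.d_presented[i]}"
                )
        if n and self.t[0] != 0:
            raise ValueError("row 0: trial index must start at 0")
        for i in range(1, n):
            if self.t[i] <= self.t[i - 1]:
                raise ValueError(f"row {i}: trial indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


def read_response_log(path: str) -> ResponseLog:
    """Read a response log CSV with columns ``t,d_presented,x``."""
    frame = pd.read_csv(path)
    missing = {"t", "d_presented", "x"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return ResponseLog(
        t=tuple(int(v) for v in frame["t"]),
        d_presented=tuple(float(v) for v in frame["d_presented"]),
        x=tuple(int(v) for v in frame["x"]),
    )


def next_difficulty(log: ResponseLog, config: ControllerConfig) -> float:
    """Difficulty to present next, given recorded outcomes.

    Folds the update rule over the log starting from ``config.d0`` — a pure
    function of (log, config).  Each recorded presented difficulty is checked
    against the fold; a mismatch (log produced by different parameters, or
    corrupted) is reported with its row index.
    """
    state = DifficultyState(t=0, d=config.d0)
    for i in range(len(log)):
        if not math.isclose(log.d_presented[i], state.d, abs_tol=1e-9):
            raise ValueError(
                f"row {i}: recorded difficulty {log.d_presented[i]} does not match "
                f"the controller fold ({state.d}); was the log produced with "
                f"these parameters?"
            )
        state = step(state, log.x[i], config)
    return state.d


# ---------------------------------------------------------------------------
# scenario reproduction

FIGURE_IDS = ("fig2", "fig3", "fig4", "fig5", "fig6")

_CASE_CURVES = {
    "fig2": {"family": "logistic", "a": 1.0, "b": 1.0},
    "fig3": {"family": "logistic", "a": 0.6, "b": 0.5},
    "fig4": {"family": "logistic", "a": 1.0, "b": 0.2},
}


def _report_for(curve: SkillCurve, target: float, trajs: Sequence[Trajectory]):
    label, d_star = predict_limit(curve, target)
    conv = [convergence_time(tr, d_star) for tr in trajs]
    w = terminal_window_size(len(trajs[0]))
    return {
        "case": label,
        "d_star": d_star,
        "convergence_times": conv,
        "terminal_window_means": [float(tr.d[-w:].mean()) for tr in trajs],
        "seeds": [tr.seed for tr in trajs],
    }


def _maybe_plot(trajs, labels, d_star, out_path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for traj, lab in zip(trajs, labels):
        ax.plot(traj.t, traj.d, lw=0.8, label=lab)
    if d_star is not None:
        ax.axhline(d_star, color="red", ls="--", lw=1, label="$d^*$")
    ax.set_xlabel("trial $t$")
    ax.set_ylabel("difficulty $d(t)$")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def reproduce_figure(
    figure_id: str, out_dir: str, seed: int = 0, plot: bool = False
) -> list[str]:
    """Re-run one of the published simulation scenarios and write its outputs.

    fig2/fig3/fig4 — the three convergence cases (interior, lower boundary,
    upper boundary) at λ=0.01, s*=0.7, 2000 trials; fig5 — the λ sweep
    {0.1, 0.01, 0.001} on the interior-case curve; fig6 — target change from
    0.7 to 0.9 at trial 1500 (λ ∈ {0.01, 0.001}, 4000 trials).

    Writes trajectory CSV(s) and a JSON convergence report per scenario;
    a PNG when ``plot`` is requested.  Returns the written paths.
    """
    if figure_id not in FIGURE_IDS:
        raise ValueError(f"unknown figure id {figure_id!r}; known: {FIGURE_IDS}")
    os.makedirs(out_dir, exist_ok=True)
    written: list[str] = []

    def _write(name, trajs, report, labels, d_star):
        traj_path = os.path.join(out_dir, f"{name}_trajectory.csv")
        write_trajectory(trajs, traj_path)
        written.append(traj_path)
        rep_path = os.path.join(out_dir, f"{name}_report.json")
        with open(rep_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        written.append(rep_path)
        if plot:
            png = os.path.join(out_dir, f"{name}.png")
            _maybe_plot(trajs, labels, d_star, png)
            written.append(png)

    if figure_id in _CASE_CURVES:
        curve = curve_from_spec(**_CASE_CURVES[figure_id])
        config = ControllerConfig(lam=0.01, target=0.7)
        traj = run_session(curve, config, n_steps=2000, seed=seed)
        report = _report_for(curve, 0.7, [traj])
        _write(figure_id, [traj], report, [f"λ=0.01"], report["d_star"])
    elif figure_id == "fig5":
        curve = curve_from_spec(family="logistic", a=1.0, b=1.0)
        trajs, labels = [], []
        for lam, n in ((0.1, 2000), (0.01, 2000), (0.001, 3000)):
            config = ControllerConfig(lam=lam, target=0.7)
            trajs.append(run_session(curve, config, n_steps=n, seed=seed))
            labels.append(f"λ={lam}")
        report = {
            f"lam={lam}": _report_for(curve, 0.7, [tr])
            for lam, tr in zip((0.1, 0.01, 0.001), trajs)
        }
        for lam, tr in zip((0.1, 0.01, 0.001), trajs):
            path = os.path.join(out_dir, f"fig5_lam{lam}_trajectory.csv")
            write_trajectory(tr, path)
            written.append(path)
        rep_path = os.path.join(out_dir, "fig5_report.json")
        with open(rep_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        written.append(rep_path)
        if plot:
            png = os.path.join(out_dir, "fig5.png")
            _maybe_plot(trajs, labels, report["lam=0.01"]["d_star"], png)
            written.append(png)
    else:  # fig6
        curve = curve_from_spec(family="logistic", a=1.0, b=1.0)
        trajs, labels = [], []
        for lam in (0.01, 0.001):
            trajs.append(
                tracking_experiment(
                    curve, lam=lam, n_steps=4000, switch_t=1500, seed=seed
                )
            )
            labels.append(f"λ={lam}")
        _, d_before = predict_limit(curve, 0.7)
        _, d_after = predict_limit(curve, 0.9)
        report = {
            "d_star_before": d_before,
            "d_star_after": d_after,
            "switch_t": 1500,
            "seeds": [tr.seed for tr in trajs],
            "post_switch_terminal_means": [
                float(tr.d[-400:].mean()) for tr in trajs
            ],
        }
        _write("fig6", trajs, report, labels, d_after)
    return written
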