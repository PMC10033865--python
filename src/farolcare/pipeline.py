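"""End-to-end scenario runner: series -> beliefs -> sweeps -> payoffs.

A scenario is described by a flat ``key = value`` text file (or a
:class:`ScenarioConfig` built in code) naming either an input visit CSV or
a synthetic preset plus seed, the belief parameters, optional sweep grids
and an output directory.  ``run_scenario`` writes a deterministic bundle:
trajectory CSV, summary JSON, sweep tables, payoff series and a manifest
echoing every parameter together with input hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from . import beliefs as bd
from . import io as fio
from . import reference, synthetic
from .errors import DataValidationError
from .payoff import aggregate_payoffs, payoff_trajectory

__all__ = ["ScenarioConfig", "parse_scenario_file", "run_scenario"]

log = logging.getLogger("farolcare")

_PRESETS = ("outpatient", "emergency")


def _package_version() -> str:
    try:
        return version("farolcare")
    except PackageNotFoundError:  # pragma: no cover - not installed
        return "unknown"


@dataclass
class ScenarioConfig:
    """Inputs of one report run; exactly one of visits_csv / preset."""

    outdir: Path
    visits_csv: Path | None = None
    preset: str | None = "outpatient"
    seed: int = 0
    indicators_csv: Path | None = None
    threshold: int | None = None  # default: 1250, the reference daily mean
    learning_rate: float = 0.2
    initial_p: float = 0.5
    window_days: int = 1
    signal_rule: str = "fraction"
    sweep_thresholds: list[int] = field(default_factory=list)
    sweep_omegas: list[float] = field(default_factory=list)
    sweep_initial_ps: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.visits_csv is None) == (self.preset is None):
            raise DataValidationError(
                "provide exactly one of visits_csv or a synthetic preset"
            )
        if self.preset is not None and self.preset not in _PRESETS:
            raise DataValidationError(f"preset must be one of {_PRESETS}")


def parse_scenario_file(path) -> ScenarioConfig:
    """Parse a flat ``key = value`` scenario file ('#' starts a comment)."""
    path = Path(path)
    raw: dict[str, str] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DataValidationError(f"{path} line {ln}: expected key = value")
        key, value = (s.strip() for s in line.split("=", 1))
        raw[key] = value

    def get_list(key, cast):
        return [cast(v) for v in raw[key].split(",")] if key in raw else []

    kwargs = dict(
        outdir=Path(raw.get("outdir", "farolcare-report")),
        visits_csv=Path(raw["visits_csv"]) if "visits_csv" in raw else None,
        preset=raw.get("preset") if "visits_csv" not in raw else None,
        seed=int(raw.get("seed", "0")),
        indicators_csv=Path(raw["indicators_csv"]) if "indicators_csv" in raw else None,
        threshold=int(raw["threshold"]) if "threshold" in raw else None,
        learning_rate=float(raw.get("learning_rate", "0.2")),
        initial_p=float(raw.get("initial_p", "0.5")),
        window_days=int(raw.get("window_days", "1")),
        signal_rule=raw.get("signal_rule", "fraction"),
        sweep_thresholds=get_list("sweep_thresholds", int),
        sweep_omegas=get_list("sweep_omegas", float),
        sweep_initial_ps=get_list("sweep_initial_ps", float),
    )
    if kwargs["visits_csv"] is None and kwargs["preset"] is None:
        kwargs["preset"] = "outpatient"
    return ScenarioConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_scenario(config: ScenarioConfig) -> dict:
    """Run a full scenario and write the report bundle; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _package_version(),
        "seed": config.seed,
        "inputs": {},
        "outputs": [],
    }

    if config.visits_csv is not None:
        if not Path(config.visits_csv).exists():
            raise FileNotFoundError(f"visit CSV not found: {config.visits_csv}")
        series = fio.load_visit_csv(config.visits_csv)
        manifest["inputs"]["visits_csv"] = {
            "path": str(config.visits_csv),
            "sha256": _sha256(Path(config.visits_csv)),
        }
        log.info("loaded visit series from %s (%d days)", config.visits_csv, len(series))
    else:
        maker = (
            synthetic.default_outpatient_config
            if config.preset == "outpatient"
            else synthetic.default_emergency_config
        )
        series = synthetic.generate_visit_series(maker(config.seed))
        fio.write_visit_csv(series, outdir / "series.csv")
        manifest["inputs"]["preset"] = config.preset
        manifest["outputs"].append("series.csv")
        log.info("generated %s series, seed %d (%d days)", config.preset, config.seed, len(series))

    threshold = config.threshold if config.threshold is not None else 1250
    params = bd.BeliefParams(
        threshold=threshold,
        learning_rate=config.learning_rate,
        initial_p=config.initial_p,
        window_days=config.window_days,
        signal_rule=config.signal_rule,
    )
    manifest["belief_params"] = {
        "threshold": params.threshold,
        "learning_rate": params.learning_rate,
        "initial_p": params.initial_p,
        "window_days": params.window_days,
        "signal_rule": params.signal_rule,
    }

    traj = bd.run_belief_trajectory(series, params)
    fio.write_table(traj.to_frame(), outdir / "trajectory.csv")
    manifest["outputs"].append("trajectory.csv")
    summary = bd.summarize_trajectory(traj)
    monthly = bd.monthly_summary(traj)
    summary_json = {
        "mean_p": summary.mean_p,
        "days_above_half": summary.days_above_half,
        "fraction_above_half": summary.fraction_above_half,
        "n_days": summary.n_days,
        "monthly_mean_p": {str(m): v for m, v in monthly.items()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary_json, indent=2))
    manifest["outputs"].append("summary.json")
    log.info("belief trajectory: mean p = %.3f", summary.mean_p)

    if config.sweep_thresholds:
        fio.write_table(
            bd.sweep_threshold(series, params, config.sweep_thresholds),
            outdir / "threshold_sweep.csv",
        )
        manifest["outputs"].append("threshold_sweep.csv")
    if config.sweep_omegas:
        fio.write_table(
            bd.sweep_omega(series, params, config.sweep_omegas),
            outdir / "omega_sweep.csv",
        )
        manifest["outputs"].append("omega_sweep.csv")
    if config.sweep_initial_ps:
        fio.write_table(
            bd.sweep_initial_p(series, params, config.sweep_initial_ps),
            outdir / "initial_p_sweep.csv",
        )
        manifest["outputs"].append("initial_p_sweep.csv")

    if config.indicators_csv is not None:
        if not Path(config.indicators_csv).exists():
            raise FileNotFoundError(f"indicator CSV not found: {config.indicators_csv}")
        records = fio.load_indicator_csv(config.indicators_csv)
        index = aggregate_payoffs(records)
        payoff_meta = {"source": str(config.indicators_csv)}
        manifest["inputs"]["indicators_csv"] = {
            "path": str(config.indicators_csv),
            "sha256": _sha256(Path(config.indicators_csv)),
        }
    else:
        index = reference.reference_payoff_index()
        payoff_meta = reference.reference_metadata()
    pseries = payoff_trajectory(traj, index)
    frame = pseries.to_frame()
    frame.insert(1, "p", traj.p_values)
    fio.write_table(frame, outdir / "payoff.csv")
    manifest["outputs"].append("payoff.csv")
    payoff_json = {
        "gain": index.gain,
        "loss": index.loss,
        "min_E": pseries.minimum,
        "max_E": pseries.maximum,
        "monthly_mean_E": {str(m): v for m, v in pseries.monthly_means.items()},
        "metadata": payoff_meta,
    }
    (outdir / "payoff_summary.json").write_text(json.dumps(payoff_json, indent=2))
    manifest["outputs"].append("payoff_summary.json")
    log.info("expected payoff: min %.3f, max %.3f", pseries.minimum, pseries.maximum)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
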