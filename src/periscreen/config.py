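"""Run configuration: a single YAML file driving the whole pipeline.

A configuration selects exactly one analysis (``run``, ``dsa``, ``psa``,
``estimate`` or ``simulate``) and assembles the model by overlaying the
built-in base-case parameter bundle with any pieces it names: per-arm
initial-distribution and transition CSVs, component cost inputs, state
utilities, the WTP threshold, semantics, mortality, renormalization, and
the uncertain-parameter table for the sensitivity analyses.

``run_pipeline`` executes the selected analysis, writes CSV results into
the output directory, and writes ``run.log`` recording the seed, input
file hashes, and the four number-changing flags (semantics, mortality,
renormalization, seed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import io as psio
from .cohort import (
    CategoryThresholds,
    baseline_distribution,
    estimate_anchored_transitions,
    estimate_chained_transitions,
    outcome_statistics,
)
from .costing import CostInputs
from .pipeline import base_case_report, model_builder_for
from .reference import ModelParameters, reference_parameters, reference_param_specs
from .sensitivity import ParamSpec, ceac, one_way_dsa, run_psa
from .simulate import SimulationConfig, simulate_trajectories
from .states import HealthState, Semantics, StateDistribution

__all__ = ["ConfigError", "RunConfig", "load_run_config", "run_pipeline", "export_reference_workspace"]

logger = logging.getLogger(__name__)

ANALYSES = ("run", "dsa", "psa", "estimate", "simulate")

_STATE_KEYS = {
    "normal": HealthState.NORMAL,
    "suspicious": HealthState.SUSPICIOUS,
    "high_risk": HealthState.HIGH_RISK,
}


class ConfigError(ValueError):
    """A configuration problem, naming the offending key."""


@dataclass
class RunConfig:
    analysis: str
    params: ModelParameters
    param_specs: list[ParamSpec]
    output_dir: Path
    config_dir: Path
    input_files: list[Path] = field(default_factory=list)
    # analysis-specific settings
    psa_n: int = 1000
    psa_seed: int = 1
    dsa_outcome: str = "icur"
    wtp_grid: list[float] | None = None
    estimate_cohort: Path | None = None
    estimate_chained: bool = False
    thresholds: CategoryThresholds = field(default_factory=CategoryThresholds)
    sim: SimulationConfig | None = None


def _require(mapping: dict, key: str, context: str = "configuration"):
    if key not in mapping or mapping[key] is None:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return mapping[key]


def _as_distribution(value, base_dir: Path, files: list[Path]) -> StateDistribution:
    if isinstance(value, str):
        path = base_dir / value
        files.append(path)
        return psio.read_initial_csv(path)
    if isinstance(value, dict):
        unknown = set(value) - set(_STATE_KEYS)
        if unknown:
            raise ConfigError(f"initial distribution: unknown state label(s) {sorted(unknown)}")
        return StateDistribution(
            float(value.get("normal", 0.0)),
            float(value.get("suspicious", 0.0)),
            float(value.get("high_risk", 0.0)),
        )
    raise ConfigError("initial distribution must be a file path or a state->share mapping")


def load_run_config(path: str | Path, analysis: str | None = None) -> RunConfig:
    """Parse and fully validate a YAML run configuration.

    ``analysis`` overrides the file's ``analysis`` key (the CLI subcommand
    uses this); the override is logged when the two differ.
    """
    path = Path(path)
    base_dir = path.parent
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")

    if analysis is None:
        analysis = _require(raw, "analysis")
    elif raw.get("analysis") not in (None, analysis):
        logger.info(
            "overriding configured analysis %r with %r", raw.get("analysis"), analysis
        )
    if analysis not in ANALYSES:
        raise ConfigError(f"analysis: must be one of {ANALYSES}, got {analysis!r}")
    wtp = float(_require(raw, "wtp"))
    if wtp <= 0:
        raise ConfigError("wtp: must be positive")

    params = reference_parameters()
    files: list[Path] = [path]

    semantics_raw = raw.get("semantics", "anchored")
    try:
        semantics = Semantics(semantics_raw)
    except ValueError as exc:
        raise ConfigError(f"semantics: must be anchored or chained, got {semantics_raw!r}") from exc

    strategies = raw.get("strategies", {})
    if not isinstance(strategies, dict) or set(strategies) - {"screening", "routine"}:
        raise ConfigError("strategies: only 'screening' and 'routine' arms are supported")
    updates: dict = {}
    for arm in ("screening", "routine"):
        spec = strategies.get(arm, {})
        if "initial" in spec:
            updates[f"{arm}_initial"] = _as_distribution(spec["initial"], base_dir, files)
        if "transitions" in spec:
            p = base_dir / spec["transitions"]
            files.append(p)
            updates[f"{arm}_schedule"] = psio.read_transition_csv(p)

    if "utilities" in raw:
        utilities = dict(params.utilities)
        for label, v in raw["utilities"].items():
            if label not in _STATE_KEYS:
                raise ConfigError(f"utilities: unknown state label {label!r}")
            utilities[_STATE_KEYS[label]] = float(v)
        updates["utilities"] = utilities
    if "cost_inputs" in raw:
        valid = set(CostInputs.__dataclass_fields__)
        unknown = set(raw["cost_inputs"]) - valid
        if unknown:
            raise ConfigError(f"cost_inputs: unknown field(s) {sorted(unknown)}")
        updates["cost_inputs"] = replace(
            params.cost_inputs, **{k: float(v) for k, v in raw["cost_inputs"].items()}
        )
    if "screening_positive_override" in raw:
        v = raw["screening_positive_override"]
        updates["screening_positive_override"] = None if v is None else float(v)

    params = replace(
        params,
        wtp=wtp,
        mortality=float(raw.get("mortality", 0.0)),
        renormalize=bool(raw.get("renormalize", False)),
        cycle_years=float(raw.get("cycle_years", 0.25)),
        **updates,
    ).with_semantics(semantics)

    if "params" in raw and raw["params"]:
        p = base_dir / raw["params"]
        files.append(p)
        specs = psio.read_param_specs_csv(p)
    else:
        specs = reference_param_specs()

    cfg = RunConfig(
        analysis=analysis,
        params=params,
        param_specs=specs,
        output_dir=base_dir / raw.get("output_dir", "out"),
        config_dir=base_dir,
        input_files=files,
    )

    thresholds_raw = raw.get("thresholds", {})
    cfg.thresholds = CategoryThresholds(
        float(thresholds_raw.get("suspicious_min", 9)),
        float(thresholds_raw.get("high_min", 13)),
    )

    if analysis == "psa":
        psa_raw = raw.get("psa", {})
        cfg.psa_n = int(psa_raw.get("n", 1000))
        cfg.psa_seed = int(_require(psa_raw, "seed", "psa"))
        if cfg.psa_n < 1:
            raise ConfigError("psa.n: must be at least 1")
        grid = psa_raw.get("wtp_grid")
        cfg.wtp_grid = [float(w) for w in grid] if grid else None
    elif analysis == "dsa":
        cfg.dsa_outcome = raw.get("dsa", {}).get("outcome", "icur")
        if cfg.dsa_outcome not in ("icur", "inmb", "delta_cost", "delta_qalys"):
            raise ConfigError(f"dsa.outcome: unknown outcome {cfg.dsa_outcome!r}")
    elif analysis == "estimate":
        est = raw.get("estimate", {})
        cfg.estimate_cohort = base_dir / _require(est, "cohort", "estimate")
        cfg.estimate_chained = bool(est.get("chained", False))
        files.append(cfg.estimate_cohort)
    elif analysis == "simulate":
        sim = raw.get("simulate", {})
        arm = sim.get("from_arm", "routine")
        if arm not in ("screening", "routine"):
            raise ConfigError(f"simulate.from_arm: must be screening or routine, got {arm!r}")
        baseline = (
            _as_distribution(sim["baseline"], base_dir, files)
            if "baseline" in sim
            else getattr(params, f"{arm}_initial")
        )
        if "transitions" in sim:
            p = base_dir / sim["transitions"]
            files.append(p)
            schedule = psio.read_transition_csv(p)
        else:
            schedule = getattr(params, f"{arm}_schedule")
        cfg.sim = SimulationConfig(
            baseline=baseline,
            schedule=schedule,
            n_subjects=int(_require(sim, "n_subjects", "simulate")),
            seed=int(_require(sim, "seed", "simulate")),
            missing_rate=float(sim.get("missing_rate", 0.0)),
            emit_scores=bool(sim.get("emit_scores", True)),
            thresholds=cfg.thresholds,
        )
    return cfg


def _outcome_selector(name: str, wtp: float):
    if name == "icur":
        return lambda c: float("nan") if c.icur is None else c.icur
    if name == "inmb":
        return lambda c: wtp * c.delta_qalys - c.delta_cost
    if name == "delta_cost":
        return lambda c: c.delta_cost
    return lambda c: c.delta_qalys


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> int:
    """Execute the configured analysis; returns a process exit status."""
    try:
        out = config.output_dir
        out.mkdir(parents=True, exist_ok=True)
        p = config.params
        seed = config.psa_seed if config.analysis == "psa" else (
            config.sim.seed if config.sim else None
        )

        if config.analysis == "run":
            traces, comparison, choice, table = base_case_report(p)
            table.to_csv(out / "cua_table.csv", index=False)
            cycles = []
            for name, trace in traces.items():
                for i, d in enumerate(trace.distributions, start=1):
                    cycles.append(
                        {
                            "strategy": name,
                            "cycle": i,
                            "normal": d.normal,
                            "suspicious": d.suspicious,
                            "high_risk": d.high_risk,
                            "dead": d.dead,
                            "cost": trace.cycle_costs[i - 1],
                            "qalys": trace.cycle_qalys[i - 1],
                        }
                    )
            import pandas as pd

            pd.DataFrame(cycles).to_csv(out / "trace.csv", index=False)
            logger.info("base case: preferred strategy at WTP %.0f is %s", p.wtp, choice)
        elif config.analysis == "dsa":
            records = one_way_dsa(
                model_builder_for(p),
                config.param_specs,
                _outcome_selector(config.dsa_outcome, p.wtp),
            )
            psio.write_dsa_csv(records, out / "dsa_tornado.csv")
        elif config.analysis == "psa":
            psa = run_psa(
                model_builder_for(p),
                config.param_specs,
                config.psa_n,
                config.psa_seed,
                p.wtp,
            )
            psio.write_psa_csv(psa, out / "psa_draws.csv", out / "psa_summary.csv")
            if config.wtp_grid:
                import pandas as pd

                pd.DataFrame(
                    ceac(psa, config.wtp_grid), columns=["wtp", "fraction_cost_effective"]
                ).to_csv(out / "ceac.csv", index=False)
        elif config.analysis == "estimate":
            assert config.estimate_cohort is not None
            trajectories = psio.read_cohort_csv(config.estimate_cohort, config.thresholds)
            estimator = (
                estimate_chained_transitions
                if config.estimate_chained
                else estimate_anchored_transitions
            )
            result = estimator(trajectories, config.thresholds)
            psio.write_transition_csv(result.schedule, out / "estimated_transitions.csv")
            result.counts.to_csv(out / "transition_counts.csv", index=False)
            dist, counts = baseline_distribution(trajectories)
            psio.write_initial_csv(dist, out / "estimated_initial.csv")
            try:
                summary = outcome_statistics(trajectories, config.thresholds)
                psio.write_cohort_summary_csv(summary, out / "cohort_summary.csv")
            except ValueError:
                logger.warning("no complete trajectories; cohort summary skipped")
            for flag in result.flags:
                logger.warning("estimation flag: %s", flag)
        elif config.analysis == "simulate":
            assert config.sim is not None
            trajectories, truth = simulate_trajectories(config.sim)
            psio.write_cohort_csv(trajectories, out / "cohort.csv")
            psio.write_transition_csv(truth.normalized_schedule, out / "true_transitions.csv")
            psio.write_initial_csv(truth.baseline, out / "true_initial.csv")

        with open(out / "run.log", "w", encoding="utf-8") as fh:
            fh.write(f"analysis: {config.analysis}\n")
            fh.write(f"semantics: {p.semantics.value}\n")
            fh.write(f"mortality: {p.mortality}\n")
            fh.write(f"renormalize: {p.renormalize}\n")
            fh.write(f"seed: {seed}\n")
            fh.write(f"wtp: {p.wtp}\n")
            for f in config.input_files:
                fh.write(f"input: {f.name} sha256={_sha256(f)}\n")
        return 0
    except Exception:
        logger.exception("pipeline failed")
        return 1


def export_reference_workspace(directory: str | Path) -> Path:
    """Write the base-case parameter bundle as a loadable workspace.

    Produces per-arm initial/transition CSVs, the uncertain-parameter
    table, and a ``config.yaml`` wired to them; returns the config path.
    Loading it back reproduces the built-in parameters exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = reference_parameters()
    psio.write_initial_csv(p.screening_initial, directory / "screening_initial.csv")
    psio.write_initial_csv(p.routine_initial, directory / "routine_initial.csv")
    psio.write_transition_csv(p.screening_schedule, directory / "screening_transitions.csv")
    psio.write_transition_csv(p.routine_schedule, directory / "routine_transitions.csv")
    psio.write_param_specs_csv(reference_param_specs(), directory / "params.csv")
    config = {
        "analysis": "run",
        "wtp": p.wtp,
        "semantics": p.semantics.value,
        "mortality": p.mortality,
        "renormalize": p.renormalize,
        "cycle_years": p.cycle_years,
        "strategies": {
            "screening": {
                "initial": "screening_initial.csv",
                "transitions": "screening_transitions.csv",
            },
            "routine": {
                "initial": "routine_initial.csv",
                "transitions": "routine_transitions.csv",
            },
        },
        "utilities": {k.value: v for k, v in p.utilities.items() if k is not HealthState.DEAD},
        "cost_inputs": {
            k: getattr(p.cost_inputs, k) for k in CostInputs.__dataclass_fields__
        },
        "screening_positive_override": p.screening_positive_override,
        "params": "params.csv",
        "psa": {"n": 1000, "seed": 1},
        "dsa": {"outcome": "icur"},
        "output_dir": "out",
    }
    config_path = directory / "config.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config_path
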