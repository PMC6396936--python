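"""Run configuration, result serialization, and test-fixture generation."""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .aggregation import DEFAULT_AGGREGATION_SIZE
from .diagnostics import SweepResult
from .exact import DetectionResult
from .model import CellState, ModelParameters, ValidationError, validate_parameters
from .simulate import DEFAULT_N_BATCHES, DEFAULT_RUNS_PER_BATCH, SimulationEstimate

__all__ = ["RunConfig", "load_config", "write_results", "generate_fixtures"]

logger = logging.getLogger("resistmc")

_KNOWN_KEYS = {
    "lambda",
    "mu",
    "alpha",
    "beta",
    "gamma",
    "M",
    "agg_size",
    "runs",
    "batches",
    "seed",
    "method",
    "initial_total",
    "initial_resistant",
    "out",
    "format",
}
_REQUIRED_KEYS = {"lambda", "mu", "alpha", "beta", "gamma", "M"}
_METHODS = {"exact", "approx", "simulate", "sweep", "compare"}


@dataclass(frozen=True)
class RunConfig:
    """A validated, fully-defaulted run configuration."""

    params: ModelParameters
    M: int
    method: str = "approx"
    agg_size: int = DEFAULT_AGGREGATION_SIZE
    runs: int = DEFAULT_RUNS_PER_BATCH
    batches: int = DEFAULT_N_BATCHES
    seed: int | None = None
    initial: CellState = field(default_factory=lambda: CellState(1, 0))
    out: str | None = None
    format: str = "json"


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML/JSON file and/or flag overrides.

    Flag values (``overrides``; ``None`` entries ignored) take precedence over
    file values; a conflict is logged at warning level.  Unknown keys raise.
    """
    values: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)  # YAML is a superset of JSON
        if not isinstance(loaded, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        values.update(loaded)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key in values and values[key] != val:
            logger.warning("flag --%s=%r overrides config value %r", key, val, values[key])
        values[key] = val

    unknown = sorted(set(values) - _KNOWN_KEYS)
    if unknown:
        raise ValidationError(f"unknown configuration keys: {', '.join(unknown)}")
    missing = sorted(_REQUIRED_KEYS - set(values))
    if missing:
        raise ValidationError(f"missing required configuration keys: {', '.join(missing)}")

    method = values.get("method", "approx")
    if method not in _METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}")
    params = ModelParameters(
        lambda_div=float(values["lambda"]),
        mu_death=float(values["mu"]),
        alpha_div=float(values["alpha"]),
        beta_death=float(values["beta"]),
        gamma_mut=float(values["gamma"]),
    )
    config = RunConfig(
        params=params,
        M=int(values["M"]),
        method=method,
        # the default aggregation size never exceeds the detection size
        agg_size=int(values.get("agg_size", min(DEFAULT_AGGREGATION_SIZE, int(values["M"])))),
        runs=int(values.get("runs", DEFAULT_RUNS_PER_BATCH)),
        batches=int(values.get("batches", DEFAULT_N_BATCHES)),
        seed=None if values.get("seed") is None else int(values["seed"]),
        initial=CellState(int(values.get("initial_total", 1)), int(values.get("initial_resistant", 0))),
        out=values.get("out"),
        format=values.get("format", "json"),
    )
    validate_parameters(config.params, config.M, config.agg_size if method == "approx" else None)
    return config


def _round9(x: float) -> float:
    """9 significant digits: enough to preserve tabulated 7-8 digit values."""
    return float(f"{x:.9g}")


def _config_echo(config: RunConfig | None) -> dict[str, Any]:
    if config is None:
        return {}
    p = config.params
    return {
        "lambda": p.lambda_div,
        "mu": p.mu_death,
        "alpha": p.alpha_div,
        "beta": p.beta_death,
        "gamma": p.gamma_mut,
        "M": config.M,
        "agg_size": config.agg_size,
        "runs": config.runs,
        "batches": config.batches,
        "seed": config.seed,
        "method": config.method,
        "initial_total": config.initial.total,
        "initial_resistant": config.initial.resistant,
    }


def _detection_rows(result: DetectionResult) -> list[tuple[str, float]]:
    labels = [str(j) for j in range(result.conditional.size)]
    if result.aggregated:
        labels[-1] = "m_star"
    return list(zip(labels, (_round9(v) for v in result.conditional)))


def _payload(result, config: RunConfig | None) -> dict[str, Any]:
    base: dict[str, Any] = {"tool": "resistmc", "version": __version__}
    if isinstance(result, DetectionResult):
        base.update(
            kind="detection_distribution",
            detection_size=result.detection_size,
            aggregated=result.aggregated,
            agg_size=result.agg_size,
            reach_probability=_round9(result.reach_probability),
            p_resistance=_round9(result.p_resistance),
            distribution={label: v for label, v in _detection_rows(result)},
        )
    elif isinstance(result, SimulationEstimate):
        base.update(
            kind="simulation_estimate",
            p_resistance=_round9(result.p_resistance_hat),
            ci_low=_round9(result.ci_low),
            ci_high=_round9(result.ci_high),
            runs_per_batch=result.runs_per_batch,
            n_batches=result.n_batches,
            seed=result.seed,
            batch_values=[_round9(v) for v in result.batch_values],
        )
    elif isinstance(result, SweepResult):
        base.update(
            kind="sweep",
            method=result.method,
            grid=[dataclasses.asdict(p) for p in result.grid],
            p_resistance=[_round9(v) for v in result.p_resistance],
        )
    elif isinstance(result, dict):
        base.update(result)
    else:
        raise ValidationError(f"cannot serialize result of type {type(result).__name__}")
    if config is not None:
        base["config"] = _config_echo(config)
    return base


def write_results(
    result,
    format: str = "json",
    path: str | Path | None = None,
    config: RunConfig | None = None,
) -> str:
    """Serialize an engine result to CSV or JSON; returns the text written.

    ``path=None`` writes to standard output (logging goes to standard error,
    so pipelines can consume the stream).  CSV for a detection distribution
    has columns ``n_resistant, probability`` with the aggregate row labeled
    ``m_star``; JSON carries the full result plus a config echo and the tool
    version, with deterministic field order.
    """
    if format == "json":
        text = json.dumps(_payload(result, config), indent=2, sort_keys=False) + "\n"
    elif format == "csv":
        if isinstance(result, DetectionResult):
            lines = ["n_resistant,probability"]
            lines += [f"{label},{value:.9g}" for label, value in _detection_rows(result)]
            text = "\n".join(lines) + "\n"
        elif isinstance(result, SweepResult):
            text = result.to_frame().to_csv(index=False, float_format="%.9g")
        elif hasattr(result, "to_csv"):  # pandas table in table orientation
            text = result.to_csv(float_format="%.9g")
        else:
            raise ValidationError(f"no CSV writer for {type(result).__name__}")
    else:
        raise ValidationError(f"unknown output format {format!r}")
    if path is None:
        sys.stdout.write(text)
    else:
        Path(path).write_text(text)
    return text


def generate_fixtures(seed: int = 0) -> list[RunConfig]:
    """Deterministic battery of tiny configurations for oracle-level testing.

    Covers random valid parameter draws at tiny detection sizes (where the
    fundamental-matrix oracle applies), mutation-free gambler's-ruin cases,
    and aggregate-boundary (k = 0) cases.
    """
    rng = np.random.default_rng(seed)
    fixtures: list[RunConfig] = []
    for M in range(2, 9):
        lam, alpha = rng.uniform(0.5, 4.0, 2)
        mu, beta = rng.uniform(0.0, 2.0, 2)
        gamma = rng.uniform(0.0, 0.3)
        params = ModelParameters(lam, mu, alpha, beta, gamma)
        fixtures.append(RunConfig(params=params, M=M, method="exact", agg_size=M))
    for lam, mu in ((2.0, 1.0), (3.0, 1.0), (1.5, 1.0)):
        params = ModelParameters(lam, mu, 2.0, 1.0, 0.0)
        fixtures.append(RunConfig(params=params, M=10, method="exact", agg_size=10))
    for m_agg in (1, 2, 5):
        params = ModelParameters(2.0, 1.0, 2.0, 1.0, 1e-3)
        fixtures.append(RunConfig(params=params, M=30, method="approx", agg_size=m_agg))
    return fixtures
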