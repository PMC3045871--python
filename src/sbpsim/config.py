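"""Run configuration: defaults, YAML/JSON loading, validation.

An empty or missing config reproduces the default study conditions:
a normal SBP population (mu=130, sigma=20 mm Hg), exponential risk with
k in {20, 30, 40}, l=100, m=140, a [10, 250] mm Hg grid at 1 mm Hg steps,
the four medication policy columns, the e-row sweep, and the three-by-three
promotion grid.  Unknown keys are rejected by name so that typos never
silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .core import ConfigurationError, IntegrationGrid, RiskModel, SBPDistribution
from .interventions import MedicationPolicy, SuccessRateTable, aggregate_success_rate
from .scenarios import (
    DEFAULT_ALPHAS,
    DEFAULT_BETAS,
    DEFAULT_E_ROWS,
    DEFAULT_MEDICATION_COLUMNS,
)

__all__ = ["RunConfig", "load_config", "config_to_dict"]


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of a full simulation run."""

    population: SBPDistribution = SBPDistribution()
    risks: tuple[RiskModel, ...] = (
        RiskModel(k=20), RiskModel(k=30), RiskModel(k=40),
    )
    grid: IntegrationGrid = IntegrationGrid()
    medication_columns: tuple[MedicationPolicy, ...] = DEFAULT_MEDICATION_COLUMNS
    e_rows: tuple[float, ...] = DEFAULT_E_ROWS
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    betas: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETAS)
    )
    promotion_contribution: float = 0.5
    outdir: str = "output"
    plots: bool = False
    log_level: str = "INFO"


def _reject_unknown(section: str, raw: Mapping[str, Any],
                    allowed: Sequence[str]) -> None:
    for key in raw:
        if key not in allowed:
            raise ConfigurationError(
                f"unknown key {key!r} in {section!r} section "
                f"(allowed: {', '.join(allowed)})"
            )


def _number(section: str, raw: Mapping[str, Any], key: str, default):
    value = raw.get(key, default)
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigurationError(f"{section}.{key} must be a number (got {value!r})")
    return float(value)


def _parse_population(raw: Mapping[str, Any]) -> SBPDistribution:
    _reject_unknown("population", raw, ["mu", "sigma"])
    return SBPDistribution(
        mu=_number("population", raw, "mu", 130.0),
        sigma=_number("population", raw, "sigma", 20.0),
    )


def _parse_risk(raw: Mapping[str, Any]) -> tuple[RiskModel, ...]:
    _reject_unknown("risk", raw, ["k", "l", "m"])
    ks = raw.get("k", [20.0, 30.0, 40.0])
    if isinstance(ks, (int, float)) and not isinstance(ks, bool):
        ks = [ks]
    if not isinstance(ks, list):
        raise ConfigurationError(f"risk.k must be a number or list (got {ks!r})")
    l = _number("risk", raw, "l", 100.0)
    m = _number("risk", raw, "m", 140.0)
    return tuple(RiskModel(k=float(k), l=l, m=m) for k in ks)


def _parse_grid(raw: Mapping[str, Any]) -> IntegrationGrid:
    _reject_unknown("grid", raw, ["lower", "upper", "step"])
    return IntegrationGrid(
        lower=_number("grid", raw, "lower", 10.0),
        upper=_number("grid", raw, "upper", 250.0),
        step=_number("grid", raw, "step", 1.0),
    )


def _parse_medication(raw: Mapping[str, Any]):
    _reject_unknown("medication", raw, ["columns", "e_rows", "contribution"])
    contribution = _number("medication", raw, "contribution", 0.5)
    columns = raw.get("columns")
    if columns is None:
        cols = tuple(
            MedicationPolicy(
                alarm=p.alarm, access=p.access, target=p.target,
                adherence=p.adherence, initiation=p.initiation,
                contribution=contribution, label=p.label,
            )
            for p in DEFAULT_MEDICATION_COLUMNS
        )
    else:
        cols = []
        for entry in columns:
            _reject_unknown("medication.columns[]", entry,
                            ["label", "a", "b", "c", "d", "e"])
            a = _number("medication.columns[]", entry, "a", 140.0)
            c = _number("medication.columns[]", entry, "c", a)
            cols.append(MedicationPolicy(
                alarm=a,
                access=_number("medication.columns[]", entry, "b", 0.03),
                target=c,
                adherence=_number("medication.columns[]", entry, "d", 0.7),
                initiation=_number("medication.columns[]", entry, "e", max(c, a + 10)),
                contribution=contribution,
                label=str(entry.get("label", f"a={a:g}")),
            ))
        cols = tuple(cols)
    e_rows = tuple(float(e) for e in raw.get("e_rows", DEFAULT_E_ROWS))
    return cols, e_rows


def _parse_promotion(raw: Mapping[str, Any]):
    _reject_unknown("promotion", raw, ["alphas", "betas", "tables", "contribution"])
    contribution = _number("promotion", raw, "contribution", 0.5)
    alphas = tuple(float(a) for a in raw.get("alphas", DEFAULT_ALPHAS))
    if "betas" in raw and "tables" in raw:
        raise ConfigurationError(
            "promotion accepts either 'betas' or 'tables', not both"
        )
    if "tables" in raw:
        betas = {}
        for name, strata in raw["tables"].items():
            table = SuccessRateTable(tuple(
                (str(s["label"]), float(s["share"]), float(s["success_rate"]))
                for s in strata
            ))
            betas[name] = aggregate_success_rate(table)
    else:
        betas = {
            str(name): float(value)
            for name, value in raw.get("betas", DEFAULT_BETAS).items()
        }
    for name, beta in betas.items():
        if not 0.0 <= beta <= 1.0:
            raise ConfigurationError(
                f"promotion beta {name!r} must be in [0, 1] (got {beta})"
            )
    return alphas, betas, contribution


_TOP_LEVEL = ["population", "risk", "grid", "medication", "promotion", "output"]


def _parse_output(raw: Mapping[str, Any]):
    _reject_unknown("output", raw, ["dir", "plots", "log_level"])
    return (
        str(raw.get("dir", "output")),
        bool(raw.get("plots", False)),
        str(raw.get("log_level", "INFO")),
    )


def config_from_dict(data: Mapping[str, Any] | None) -> RunConfig:
    """Build a validated RunConfig from a plain mapping (e.g. parsed YAML)."""
    data = data or {}
    if not isinstance(data, Mapping):
        raise ConfigurationError("config root must be a mapping")
    _reject_unknown("top-level", data, _TOP_LEVEL)
    columns, e_rows = _parse_medication(data.get("medication", {}))
    alphas, betas, promo_contrib = _parse_promotion(data.get("promotion", {}))
    outdir, plots, log_level = _parse_output(data.get("output", {}))
    return RunConfig(
        population=_parse_population(data.get("population", {})),
        risks=_parse_risk(data.get("risk", {})),
        grid=_parse_grid(data.get("grid", {})),
        medication_columns=columns,
        e_rows=e_rows,
        alphas=alphas,
        betas=betas,
        promotion_contribution=promo_contrib,
        outdir=outdir,
        plots=plots,
        log_level=log_level,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config file.

    An empty file yields the full default configuration.  Parse failures,
    unknown keys and invariant violations each raise ConfigurationError
    with a message naming the offending key.
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse config {path}: {exc}") from exc
    return config_from_dict(data)


def config_to_dict(config: RunConfig) -> dict[str, Any]:
    """Serialise a RunConfig to a plain dict; load_config of its dump
    reproduces an equivalent config."""
    return {
        "population": {"mu": config.population.mu, "sigma": config.population.sigma},
        "risk": {
            "k": [r.k for r in config.risks],
            "l": config.risks[0].l,
            "m": config.risks[0].m,
        },
        "grid": {
            "lower": config.grid.lower,
            "upper": config.grid.upper,
            "step": config.grid.step,
        },
        "medication": {
            "contribution": config.medication_columns[0].contribution,
            "columns": [
                {"label": p.label, "a": p.alarm, "b": p.access,
                 "c": p.target, "d": p.adherence, "e": p.initiation}
                for p in config.medication_columns
            ],
            "e_rows": list(config.e_rows),
        },
        "promotion": {
            "contribution": config.promotion_contribution,
            "alphas": list(config.alphas),
            "betas": dict(config.betas),
        },
        "output": {
            "dir": config.outdir,
            "plots": config.plots,
            "log_level": config.log_level,
        },
    }
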