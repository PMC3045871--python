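"""CSV/JSON writers for scenario grids, the campaign table and comparisons.

CSVs carry 3-significant-digit scientific notation (the convention of the
sensitivity tables); each CSV has a full-precision JSON twin.  Output is
deterministic: the same configuration produces byte-identical files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from .interventions import SuccessRateTable, aggregate_success_rate
from .scenarios import InterventionOutcome, ScenarioGridResult, StrategyComparison

__all__ = [
    "format_rate",
    "write_grid",
    "write_tables",
    "write_success_rate_table",
    "write_comparison",
]


def format_rate(value: float) -> str:
    """3-significant-digit scientific notation; blanks for missing cells."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.2e}"


def _grid_csv(result: ScenarioGridResult) -> str:
    lines = []
    for k in sorted(result.frames):
        frame = result.frames[k]
        lines.append(f"k = {k:g}," + ",".join(frame.columns))
        for row_label, row in frame.iterrows():
            lines.append(
                row_label + "," + ",".join(format_rate(v) for v in row)
            )
        lines.append("")
    return "\n".join(lines)


def _grid_json(result: ScenarioGridResult) -> dict:
    return {
        "kind": result.kind,
        "blocks": {
            f"k={k:g}": {
                row: {
                    col: (None if math.isnan(v) else v)
                    for col, v in frame.loc[row].items()
                }
                for row in frame.index
            }
            for k, frame in sorted(result.frames.items())
        },
    }


def write_grid(result: ScenarioGridResult, outdir: str | Path,
               stem: str) -> list[Path]:
    """Write one grid as <stem>.csv (display) and <stem>.json (full precision)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    json_path = outdir / f"{stem}.json"
    csv_path.write_text(_grid_csv(result))
    json_path.write_text(json.dumps(_grid_json(result), indent=2) + "\n")
    return [csv_path, json_path]


def write_tables(results: list[ScenarioGridResult], outdir: str | Path) -> list[Path]:
    """Write every grid; medication grids become table2.*, promotion table3.*."""
    if not results:
        raise ValueError("no grid results to write")
    paths = []
    for result in results:
        stem = "table2" if result.kind == "medication" else "table3"
        paths.extend(write_grid(result, outdir, stem))
    return paths


def write_success_rate_table(table: SuccessRateTable, path: str | Path) -> Path:
    """CSV mirroring the stratified campaign layout: a shares row, a rates
    row (both in percent) and the aggregate beta column."""
    path = Path(path)
    labels = [name for name, _, _ in table.strata]
    shares = [f"{share * 100:g}" for _, share, _ in table.strata]
    rates = [f"{rate * 100:g}" for _, _, rate in table.strata]
    sigma = aggregate_success_rate(table) * 100
    path.write_text(
        "," + ",".join(labels) + ",sigma\n"
        + "share %," + ",".join(shares) + ",\n"
        + "success rate %," + ",".join(rates) + f",{sigma:g}\n"
    )
    return path


def _outcome_json(outcome: InterventionOutcome) -> dict:
    return {
        "scenario": outcome.scenario_id,
        "baseline_ir": outcome.baseline_ir,
        "post_ir": outcome.post_ir,
        "delta_ir": outcome.delta_ir,
        "n_hc": None if math.isinf(outcome.n_hc) else outcome.n_hc,
        "n_hc_display": None if math.isinf(outcome.n_hc) else outcome.n_hc_display,
    }


def write_comparison(comparison: StrategyComparison, outdir: str | Path) -> list[Path]:
    """Write comparison.csv (3 s.d. display) and comparison.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "comparison.csv"
    json_path = outdir / "comparison.json"
    med, promo = comparison.medication, comparison.promotion
    csv_path.write_text(
        "strategy,scenario,delta_ir,n_hc\n"
        f"medication,{med.scenario_id},{format_rate(med.delta_ir)},"
        f"{med.n_hc_display:g}\n"
        f"promotion,{promo.scenario_id},{format_rate(promo.delta_ir)},"
        f"{promo.n_hc_display:g}\n"
        f"ratio (med/promo),,{comparison.delta_ratio:.3g},\n"
        f"winner,{comparison.winner},,\n"
    )
    json_path.write_text(json.dumps({
        "medication": _outcome_json(med),
        "promotion": _outcome_json(promo),
        "delta_ratio": comparison.delta_ratio,
        "n_hc_ratio": comparison.n_hc_ratio,
        "winner": comparison.winner,
    }, indent=2) + "\n")
    return [csv_path, json_path]
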