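"""Result serialization: per-run and aggregate CSV tables, regression
summaries, optional network-event and time-series traces, and a metadata
file sufficient for bit-exact replay."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import RunConfig
from .experiments import RUN_COLUMNS, aggregate_sweep
from .model import EventLog
from .stats import RegressionResult

__all__ = [
    "write_run_table",
    "read_run_table",
    "write_aggregate_table",
    "write_regression_table",
    "write_network_events",
    "write_time_series",
    "write_metadata",
    "write_results",
]


def write_run_table(table: pd.DataFrame, path: str | Path) -> Path:
    """One CSV row per (combination, replicate); full double precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in RUN_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in RUN_COLUMNS
    ]
    table[cols].to_csv(path, index=False)
    return path


def read_run_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_aggregate_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Per-combination means of the dependent variables."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aggregate_sweep(table).to_csv(path, index=False)
    return path


def write_regression_table(
    results: Iterable[RegressionResult], path: str | Path
) -> Path:
    """Long-format regression summary: one row per (response, predictor)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for res in results:
        for name in res.beta:
            rows.append(
                {
                    "response": res.response,
                    "R": res.R,
                    "R2": res.R2,
                    "predictor": name,
                    "beta": res.beta[name],
                    "t": res.t[name],
                    "p": res.p[name],
                    "n": res.n,
                }
            )
    pd.DataFrame(
        rows, columns=["response", "R", "R2", "predictor", "beta", "t", "p", "n"]
    ).to_csv(path, index=False)
    return path


def write_network_events(log: EventLog, path: str | Path) -> Path:
    """Tidy network-history event list: (step, patron, client, event)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        log.network_events, columns=["step", "patron_id", "client_id", "event"]
    ).to_csv(path, index=False)
    return path


def write_time_series(log: EventLog, path: str | Path) -> Path:
    """Per-step system aggregates from an event log."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(log.steps).to_csv(path, index=False)
    return path


def write_metadata(config: RunConfig, path: str | Path, **extra) -> Path:
    """Full configuration + seeds as JSON; enough to regenerate every row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config": config.to_dict(), **extra}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_results(
    table: pd.DataFrame,
    out_dir: str | Path,
    config: RunConfig,
    prefix: str = "runs",
    regressions: Sequence[RegressionResult] = (),
) -> dict[str, Path]:
    """Write the standard output bundle for one experiment."""
    out = Path(out_dir)
    written = {
        "runs": write_run_table(table, out / f"{prefix}.csv"),
        "aggregate": write_aggregate_table(table, out / f"{prefix}_aggregate.csv"),
        "metadata": write_metadata(config, out / f"{prefix}_metadata.json"),
    }
    if regressions:
        written["regression"] = write_regression_table(
            regressions, out / f"{prefix}_regression.csv"
        )
    return written
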