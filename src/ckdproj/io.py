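"""Delimited-text readers and writers for all model series.

All tabular IO is comma-delimited with a single header row; years are
integers, probabilities and counts are serialized at full double precision
(``%.17g``) so a write-then-read round trip is bit-exact.  Every output file
carries a metadata comment header (package version, seed, configuration
hash) on lines starting with ``#``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .states import HealthState, StateVector, TransitionMatrix

__all__ = [
    "write_transition_matrices",
    "read_transition_matrices",
    "write_series",
    "read_series",
    "write_table",
    "read_table",
    "write_results",
    "read_results",
    "config_hash",
]

FLOAT_FORMAT = "%.17g"
VERSION = "0.1.0"


def config_hash(config_text: str) -> str:
    return hashlib.sha256(config_text.encode()).hexdigest()[:16]


def _metadata_header(seed: int | None, conf_hash: str | None) -> str:
    parts = [f"# ckdproj version={VERSION}"]
    if seed is not None:
        parts.append(f"# seed={seed}")
    if conf_hash is not None:
        parts.append(f"# config_hash={conf_hash}")
    return "\n".join(parts) + "\n"


def write_table(
    df: pd.DataFrame,
    path: Path | str,
    seed: int | None = None,
    conf_hash: str | None = None,
) -> None:
    """Write a DataFrame as CSV with a metadata comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_metadata_header(seed, conf_hash))
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def read_table(path: Path | str) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, with line-numbered errors."""
    path = Path(path)
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc


def read_metadata(path: Path | str) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    key, value = token.split("=", 1)
                    meta[key] = value
    return meta


def write_transition_matrices(
    matrices: dict[int, TransitionMatrix], path: Path | str, **meta
) -> None:
    """Long-format dump: year, from_state, to_state, probability (nonzero only)."""
    rows = []
    for year in sorted(matrices):
        P = matrices[year].probs
        for i in HealthState:
            for j in HealthState:
                p = P[i.index, j.index]
                if p != 0.0:
                    rows.append(
                        {
                            "year": year,
                            "from_state": i.name,
                            "to_state": j.name,
                            "probability": p,
                        }
                    )
    write_table(pd.DataFrame(rows), path, **meta)


def read_transition_matrices(path: Path | str) -> dict[int, TransitionMatrix]:
    df = read_table(path)
    required = {"year", "from_state", "to_state", "probability"}
    if set(df.columns) != required:
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    matrices: dict[int, TransitionMatrix] = {}
    for year, group in df.groupby("year"):
        P = np.zeros((len(HealthState), len(HealthState)))
        for line, row in group.iterrows():
            try:
                i = HealthState[row["from_state"]]
                j = HealthState[row["to_state"]]
            except KeyError as exc:
                raise ValueError(f"{path}: row {line + 2}: unknown state {exc}") from exc
            P[i.index, j.index] = row["probability"]
        matrices[int(year)] = TransitionMatrix(int(year), P)
    return matrices


def write_series(series: dict[int, dict[str, float]], path: Path | str, **meta) -> None:
    """Long-format parameter series: year, parameter, value."""
    rows = [
        {"year": year, "parameter": name, "value": value}
        for year in sorted(series)
        for name, value in series[year].items()
    ]
    write_table(pd.DataFrame(rows), path, **meta)


def read_series(path: Path | str) -> dict[int, dict[str, float]]:
    df = read_table(path)
    required = {"year", "parameter", "value"}
    if set(df.columns) != required:
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    out: dict[int, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(int(row["year"]), {})[str(row["parameter"])] = float(row["value"])
    return out


def write_results(result, out_dir: Path | str, seed: int, conf_hash: str) -> None:
    """Write the projection: metric table, state trajectory, percentile bands.

    ``metrics.csv`` has one row per year per metric; ``states.csv`` one row
    per year per health state; ``bands.csv`` is written when the result
    carries Monte-Carlo bands.  All files share the metadata header.
    """
    out_dir = Path(out_dir)
    meta = {"seed": seed, "conf_hash": conf_hash}
    metric_rows = []
    for year, row in result.metrics.iterrows():
        for name, value in row.items():
            metric_rows.append({"year": int(year), "metric": name, "value": value})
    write_table(pd.DataFrame(metric_rows), out_dir / "metrics.csv", **meta)
    state_rows = [
        {"year": s.year, "state": h.name, "count": s.counts[h.index]}
        for s in result.states
        for h in HealthState
    ]
    write_table(pd.DataFrame(state_rows), out_dir / "states.csv", **meta)
    if result.bands is not None:
        write_table(result.bands, out_dir / "bands.csv", **meta)


def read_results(out_dir: Path | str):
    """Re-read a written projection; bit-exact for all stored fields."""
    from .projection import ProjectionResult

    out_dir = Path(out_dir)
    metrics_long = read_table(out_dir / "metrics.csv")
    metrics = metrics_long.pivot(index="year", columns="metric", values="value")
    metrics = metrics[
        [m for m in metrics_long["metric"].unique()]
    ]  # preserve column order
    metrics.columns.name = None
    states_df = read_table(out_dir / "states.csv")
    states = []
    for year, group in states_df.groupby("year", sort=True):
        counts = np.zeros(len(HealthState))
        for _, row in group.iterrows():
            counts[HealthState[row["state"]].index] = row["count"]
        states.append(StateVector(int(year), counts))
    bands_path = out_dir / "bands.csv"
    bands = read_table(bands_path) if bands_path.exists() else None
    return ProjectionResult(states, metrics, bands)
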