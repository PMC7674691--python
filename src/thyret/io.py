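"""CSV/JSON readers and writers for the pipeline stages.

All files are UTF-8; numeric columns round-trip to 12 significant digits.
Column headers carry units (``time_h``, ``activity_bq``).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidDataError
from .intake import DEFAULT_MEASUREMENT_SF, IntakeResult, Measurement, MeasurementSeries
from .propagation import RetentionSummary, ScatteringFactors
from .solver import RetentionCurve

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_retention",
    "write_retention",
    "read_raiu",
    "write_summary",
    "read_summary",
    "write_result_json",
    "write_sf_json",
    "SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
_FLOAT_FMT = "%.12g"


def _read_csv(path, required: tuple[str, ...], optional: tuple[str, ...] = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise InvalidDataError(f"cannot read CSV {path}: {exc}") from exc
    if df.empty:
        raise InvalidDataError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidDataError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required + optional]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", path, extra)
    return df


def read_measurements(path) -> MeasurementSeries:
    """Read a measurement series CSV (columns time_h, activity_bq, optional
    sf_m defaulting to 1.2); malformed rows raise with their line number."""
    df = _read_csv(path, required=("time_h", "activity_bq"), optional=("sf_m",))
    if "sf_m" not in df.columns:
        df["sf_m"] = DEFAULT_MEASUREMENT_SF
    measurements = []
    for idx, row in df.iterrows():
        try:
            measurements.append(
                Measurement(
                    t_h=float(row["time_h"]),
                    activity_bq=float(row["activity_bq"]),
                    sf_meas=float(row["sf_m"]),
                )
            )
        except (ValueError, TypeError) as exc:
            # +2: one for the header line, one for 0-based indexing
            raise InvalidDataError(f"{path}, line {idx + 2}: {exc}") from exc
    try:
        return MeasurementSeries(tuple(measurements))
    except InvalidDataError as exc:
        raise InvalidDataError(f"{path}: {exc}") from exc


def write_measurements(series: MeasurementSeries, path) -> None:
    df = pd.DataFrame(
        {
            "time_h": [m.t_h for m in series],
            "activity_bq": [m.activity_bq for m in series],
            "sf_m": [m.sf_meas for m in series],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_retention(path) -> RetentionCurve:
    df = _read_csv(path, required=("time_h", "m_t"))
    return RetentionCurve(
        times_h=df["time_h"].to_numpy(dtype=float), values=df["m_t"].to_numpy(dtype=float)
    )


def write_retention(curve: RetentionCurve, path) -> None:
    pd.DataFrame({"time_h": curve.times_h, "m_t": curve.values}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_raiu(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a normalized %RAIU table (columns time_h, raiu)."""
    df = _read_csv(path, required=("time_h", "raiu"))
    return df["time_h"].to_numpy(dtype=float), df["raiu"].to_numpy(dtype=float)


def write_summary(summary: RetentionSummary, path) -> None:
    pd.DataFrame(
        {
            "time_h": summary.times_h,
            "gm": summary.gm,
            "gsd": summary.gsd,
            "r2": summary.r_squared,
            "p05": summary.p05,
            "p50": summary.p50,
            "p95": summary.p95,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_summary(path) -> pd.DataFrame:
    return _read_csv(path, required=("time_h", "gm", "gsd", "r2", "p05", "p50", "p95"))


def write_result_json(result: IntakeResult, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "intake_bq": result.intake_bq,
        "chi2": result.chi2,
        "dof": result.dof,
        "p_value": None if np.isnan(result.p_value) else result.p_value,
        "log_likelihood": result.log_likelihood,
        "points": [
            {
                "time_h": float(t),
                "activity_bq": float(a),
                "m_t": float(m),
                "sf": float(sf),
                "implied_intake_bq": float(ie),
            }
            for t, a, m, sf, ie in zip(
                result.times_h, result.activities_bq, result.m, result.sf,
                result.implied_intake_bq,
            )
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_sf_json(table: dict[str, ScatteringFactors], path, meta: dict | None = None) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "scattering_factors": {
            route: {"sf_before_24h": sf.sf_before_24h, "sf_after_24h": sf.sf_after_24h}
            for route, sf in table.items()
        },
    }
    if meta:
        payload["meta"] = meta
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
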