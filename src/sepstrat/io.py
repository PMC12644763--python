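"""Schema-validated cohort CSV and report JSON/CSV input-output.

The cohort table is a plain :class:`pandas.DataFrame` with one row per
patient and a fixed required header::

    patient_id, center_id, age, aptt, inr, wbc, neut, lym, mon, plt,
    died_28d, survival_days, event, treated

Optional columns: ``latent_subpop`` (synthetic ground truth),
``treat_stratum`` (treatment-effect stratum used at generation time),
``is_synthetic`` (rebalancing provenance), and extended laboratory
columns prefixed ``x_``.

Units follow routine clinical conventions: APTT in seconds, INR
unitless, all cell counts in 1e9/L, age in years.  Readers never
rescale values; physiologically implausible entries only produce a
warning in the log.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("sepstrat")

#: Eight predictors of the risk models: seven coagulation-inflammatory
#: markers plus patient age.
MARKER_COLUMNS = ["age", "aptt", "inr", "wbc", "neut", "lym", "mon", "plt"]

#: Required cohort CSV header, in canonical order.
COHORT_COLUMNS = [
    "patient_id",
    "center_id",
    "age",
    "aptt",
    "inr",
    "wbc",
    "neut",
    "lym",
    "mon",
    "plt",
    "died_28d",
    "survival_days",
    "event",
    "treated",
]

_NUMERIC_COLUMNS = MARKER_COLUMNS + ["died_28d", "survival_days", "event", "treated"]

# Soft plausibility bounds (inclusive) used only for warnings.
_PLAUSIBLE_RANGES = {
    "age": (18.0, 120.0),
    "aptt": (5.0, 300.0),
    "inr": (0.5, 20.0),
    "wbc": (0.0, 200.0),
    "neut": (0.0, 150.0),
    "lym": (0.0, 50.0),
    "mon": (0.0, 20.0),
    "plt": (0.0, 2000.0),
}


class CohortSchemaError(ValueError):
    """Raised when a table does not satisfy the cohort schema."""


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate the cohort schema; return the frame unchanged.

    Raises :class:`CohortSchemaError` naming every missing required
    column or the first non-numeric / non-finite cell found.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortSchemaError(f"cohort is missing required columns: {missing}")
    if len(cohort) == 0:
        raise CohortSchemaError("cohort table is empty")
    for col in _NUMERIC_COLUMNS:
        values = pd.to_numeric(cohort[col], errors="coerce")
        bad = values.isna() & ~cohort[col].isna()
        if bad.any() or cohort[col].isna().any():
            row = int(np.flatnonzero(values.isna())[0])
            raise CohortSchemaError(
                f"non-numeric or missing value in column {col!r} at row {row}"
            )
        if not np.isfinite(values.to_numpy(dtype=float)).all():
            row = int(np.flatnonzero(~np.isfinite(values.to_numpy(dtype=float)))[0])
            raise CohortSchemaError(f"non-finite value in column {col!r} at row {row}")
    for col, (lo, hi) in _PLAUSIBLE_RANGES.items():
        vals = cohort[col].to_numpy(dtype=float)
        n_out = int(((vals < lo) | (vals > hi)).sum())
        if n_out:
            logger.warning(
                "%d values of %r outside plausible range [%g, %g]", n_out, col, lo, hi
            )
    return cohort


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    path = Path(path)
    try:
        cohort = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortSchemaError(f"cohort file {path} is empty") from exc
    return validate_cohort(cohort)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a validated cohort CSV with a canonical column order."""
    validate_cohort(cohort)
    extras = [c for c in cohort.columns if c not in COHORT_COLUMNS]
    cohort[COHORT_COLUMNS + extras].to_csv(path, index=False)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(
    results: Any,
    path: str | Path,
    format: str = "json",
    seed: int | None = None,
) -> None:
    """Serialize a result object with run metadata.

    JSON reports are wrapped in an envelope ``{"meta": {...},
    "results": ...}``; CSV reports require a DataFrame-like payload and
    embed metadata as ``# key: value`` header comments.
    """
    path = Path(path)
    from sepstrat import __version__

    meta = {
        "sepstrat_version": __version__,
        "seed": seed,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    if format == "json":
        payload = {"meta": meta, "results": _jsonable(results)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif format == "csv":
        frame = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
        with open(path, "w") as fh:
            for key, value in meta.items():
                fh.write(f"# {key}: {value}\n")
            frame.to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown report format {format!r}; valid formats: json, csv")


def read_report(path: str | Path) -> dict:
    """Read back a JSON report envelope."""
    return json.loads(Path(path).read_text())
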