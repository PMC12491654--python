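"""Tabular input, structured results and run manifests.

Input is two CSV files (UTF-8, comma-delimited, "." decimal, header row
mandatory): a sample table with one row per muscle strip and a points
table with the afterloaded force-velocity measurements.  Velocities are
stored in Lo/s, tensions in mN/mm^2, temperature in K; display scalings
are applied only when reporting, never in storage.

Strips that never contracted spontaneously are *flagged* excluded, not
dropped, mirroring the experimental discard rule while keeping the raw
tables intact.
"""
from __future__ import annotations

import json
import math
import os
from datetime import datetime, timezone
from typing import Any

import numpy as np
import pandas as pd

from .config import RunConfig

__all__ = [
    "SAMPLE_COLUMNS",
    "POINT_COLUMNS",
    "SchemaError",
    "ReferentialError",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_results",
    "read_results",
]

SAMPLE_COLUMNS = [
    "sample_id", "group", "temperature_K", "cross_section_mm2", "Lo_mm",
    "TT_mN_per_mm2", "MC_nmol_per_g", "contracted_spontaneously",
]
POINT_COLUMNS = ["sample_id", "load_mN_per_mm2", "velocity_Lo_per_s"]

GROUPS = ("caesarean", "hysterectomy")
MIN_POINTS = 4


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class ReferentialError(ValueError):
    """Points reference a sample_id absent from the sample table."""


class CohortValidationError(ValueError):
    """Row-level invariant violated (counts, signs, duplicates)."""


def _require_columns(df: pd.DataFrame, required, which: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{which} table is missing column(s): {', '.join(missing)}")


def _validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    _require_columns(samples, SAMPLE_COLUMNS, "sample")
    samples = samples.copy()
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise CohortValidationError(f"duplicate sample_id(s): {dups}")
    bad_group = set(samples["group"]) - set(GROUPS)
    if bad_group:
        raise CohortValidationError(f"unknown group value(s): {sorted(bad_group)}")
    if (samples["temperature_K"] <= 0).any():
        raise CohortValidationError("temperature_K must be positive")
    if (samples["TT_mN_per_mm2"] < 0).any():
        raise CohortValidationError("TT_mN_per_mm2 must be >= 0")
    samples["contracted_spontaneously"] = samples["contracted_spontaneously"].astype(bool)
    samples["excluded"] = ~samples["contracted_spontaneously"]
    return samples


def read_cohort(sample_path, points_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort's sample and points CSVs.

    Returns ``(samples, points)``; ``samples`` gains an ``excluded``
    boolean column (never changing the row count).  Raises
    :class:`SchemaError`, :class:`ReferentialError` or
    :class:`CohortValidationError` on malformed input.
    """
    samples = _validate_samples(pd.read_csv(sample_path))
    points = pd.read_csv(points_path)
    _require_columns(points, POINT_COLUMNS, "points")
    orphans = sorted(set(points["sample_id"]) - set(samples["sample_id"]))
    if orphans:
        raise ReferentialError(
            f"points reference unknown sample_id(s): {', '.join(map(str, orphans))}"
        )
    if (points["load_mN_per_mm2"] < 0).any() or (points["velocity_Lo_per_s"] < 0).any():
        raise CohortValidationError("loads and velocities must be >= 0")
    counts = points.groupby("sample_id").size()
    included = samples.loc[~samples["excluded"], "sample_id"]
    short = [sid for sid in included if counts.get(sid, 0) < MIN_POINTS]
    if short:
        raise CohortValidationError(
            f"included sample(s) with fewer than {MIN_POINTS} force-velocity "
            f"points: {', '.join(map(str, short))}"
        )
    return samples, points


def write_cohort(samples: pd.DataFrame, points: pd.DataFrame,
                 sample_path, points_path) -> None:
    """Write the two cohort CSVs (drops the derived ``excluded`` column)."""
    out = samples.drop(columns=["excluded"], errors="ignore")
    out.to_csv(sample_path, index=False)
    points[POINT_COLUMNS].to_csv(points_path, index=False)


# ---------------------------------------------------------------------------
# structured results
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    """Convert dataclass/numpy/enum trees to plain JSON types."""
    import dataclasses
    import enum
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def write_results(results: dict, path, cfg: RunConfig | None = None) -> dict:
    """Serialize a result tree to JSON with a reproducibility manifest.

    The manifest records the configuration, seed, package version and a
    UTC timestamp; re-reading reproduces the tree (floats at full
    repr precision, everything else bit-identically).
    """
    from . import __version__
    manifest = {
        "config": cfg.to_dict() if cfg is not None else None,
        "seed": cfg.seed if cfg is not None else None,
        "version": __version__,
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    doc = {"manifest": manifest, "results": _jsonable(results)}
    tmp = f"{path}.tmp.{os.getpid()}"
    try:
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
        os.replace(tmp, path)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    return manifest


def read_results(path) -> tuple[dict, dict]:
    """Read back a results file; returns ``(results, manifest)``."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return doc["results"], doc["manifest"]
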