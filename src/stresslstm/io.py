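"""Cohort CSV reading/writing and run manifests.

The on-disk format is a plain CSV with the twelve canonical columns
(eleven predictors + the stress label); categorical columns are encoded
as strings ({man, woman}, {no, yes}, {low, high}).  Reading is lenient
about bad rows — records with missing or unparseable values are dropped
with a logged count, mirroring how survey non-respondents are excluded —
but strict about the schema itself.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from .schema import BINARY_LEVELS, BINARY_VARS, COLUMNS, CONTINUOUS_VARS, LABEL, LABEL_LEVELS

__all__ = ["SchemaError", "read_cohort", "write_cohort", "write_manifest"]

logger = logging.getLogger("stresslstm")


class SchemaError(ValueError):
    """The file does not match the cohort schema; names the problem column."""


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV in canonical column order."""
    missing = [c for c in COLUMNS if c not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table is missing column(s): {missing}")
    cohort.loc[:, list(COLUMNS)].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Rows with non-numeric continuous values, unknown category strings or
    missing entries are dropped; the dropped count is logged as a
    warning.  A missing column (or an empty file) raises
    :class:`SchemaError` naming it.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True,
                          on_bad_lines="skip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    raw = raw.loc[:, list(COLUMNS)]

    valid = pd.Series(True, index=raw.index)
    out = pd.DataFrame(index=raw.index)
    for col in CONTINUOUS_VARS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        valid &= np.isfinite(vals)
        out[col] = vals
    for col in BINARY_VARS:
        vals = raw[col].str.strip().str.lower()
        valid &= vals.isin(BINARY_LEVELS[col])
        out[col] = vals
    labels = raw[LABEL].str.strip().str.lower()
    valid &= labels.isin(LABEL_LEVELS)
    out[LABEL] = labels

    dropped = int((~valid).sum())
    if dropped:
        logger.warning("%s: dropped %d malformed record(s) of %d", path, dropped, len(raw))
    cohort = out.loc[valid, list(COLUMNS)].reset_index(drop=True)
    if len(cohort) == 0:
        raise SchemaError(f"{path}: no valid records")
    return cohort


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_manifest(path: str | Path, *, seed: int, config: dict,
                   artifacts: dict[str, str]) -> None:
    """Record versions, the seed, a config hash and artifact paths."""
    from . import __version__

    manifest = {
        "package": {"name": "stresslstm", "version": __version__},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "artifacts": artifacts,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
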