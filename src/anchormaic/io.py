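"""File formats: IPD CSV, aggregate-summary JSON, scenario YAML/JSON.

The IPD schema is one row per patient with columns (case-insensitive,
order-free): id, arm ∈ {active, anchor}, center, age, male ∈ {0,1}, bmi,
off_baseline, optional endpoint-change columns, and optional 0/1 safety
flags. All JSON is written UTF-8 with sorted keys at full float precision,
so reruns under the same seed are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .containers import AgDSummary
from .exceptions import SchemaError
from .scenarios import EFFICACY_ENDPOINTS, SAFETY_ENDPOINTS, TrialScenario

PathLike = Union[str, Path]

IPD_REQUIRED = ["id", "arm", "center", "age", "male", "bmi", "off_baseline"]
IPD_OPTIONAL = list(EFFICACY_ENDPOINTS) + list(SAFETY_ENDPOINTS)
_NUMERIC = ["age", "male", "bmi", "off_baseline"] + IPD_OPTIONAL
_BINARY = ["male"] + list(SAFETY_ENDPOINTS)


def read_ipd(path: PathLike) -> pd.DataFrame:
    """Read and validate a patient-level CSV; errors cite columns and line numbers."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in IPD_REQUIRED if c not in df.columns]
    extra = [c for c in df.columns if c not in IPD_REQUIRED + IPD_OPTIONAL]
    if missing or extra:
        raise SchemaError(
            f"IPD header mismatch in {path}: missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    # line number = data-frame index + 2 (header is line 1)
    bad_arm = df.index[~df["arm"].isin(["active", "anchor"])]
    if len(bad_arm):
        raise SchemaError(
            f"arm must be 'active' or 'anchor'; bad rows at lines "
            f"{[int(i) + 2 for i in bad_arm[:5]]}"
        )
    out = df.copy()
    for col in df.columns:
        if col in ("id", "arm"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric value in column {col!r} at line(s) "
                f"{[int(i) + 2 for i in bad[:5]]}"
            )
        out[col] = coerced
    out["center"] = out["center"].astype(int)
    for col in _BINARY:
        if col in out.columns:
            vals = set(pd.unique(out[col].dropna()))
            if vals - {0, 1, 0.0, 1.0}:
                rows = out.index[~out[col].isin([0, 1])]
                raise SchemaError(
                    f"column {col!r} must be 0/1; bad rows at lines "
                    f"{[int(i) + 2 for i in rows[:5]]}"
                )
            out[col] = out[col].astype(int)
    return out


def write_ipd(ipd: pd.DataFrame, path: PathLike) -> None:
    ipd.to_csv(path, index=False)


def read_agd(path: PathLike) -> AgDSummary:
    text = Path(path).read_text(encoding="utf-8")
    try:
        return AgDSummary.model_validate_json(text)
    except ValueError as exc:
        raise SchemaError(f"invalid aggregate summary {path}: {exc}") from exc


def write_agd(agd: AgDSummary, path: PathLike) -> None:
    write_json(agd.model_dump(), path)


def read_scenario(path: PathLike) -> TrialScenario:
    raw = _read_structured(path)
    try:
        return TrialScenario(**raw)
    except ValueError as exc:
        raise SchemaError(f"invalid scenario {path}: {exc}") from exc


def _read_structured(path: PathLike) -> dict:
    p = Path(path)
    text = p.read_text(encoding="utf-8")
    if p.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _jsonable(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def config_hash(obj: dict) -> str:
    """SHA-256 of the canonical JSON form of a configuration."""
    blob = json.dumps(obj, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()
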