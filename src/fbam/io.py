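"""CSV input, JSON result output, and result-schema validation."""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import collapsed_power
from .exceptions import FBAMError
from .ga import FBAMResult
from .spectral import SpectralEstimateSet, TimeSeriesSet

__all__ = ["read_series", "write_result", "read_result", "validate_result"]

SCHEMA_VERSION = 1
_SCHEMA_PATH = Path(__file__).parent / "schemas" / "result.schema.json"


def read_series(
    path: str | Path,
    layout: str = "wide",
    sampling_rate: float | None = None,
) -> TimeSeriesSet:
    """Read a collection of series from CSV.

    ``wide``: one row per series, optional non-numeric first column of ids,
    no header required.  ``long``: columns (id, t, value) with a header; row
    order is irrelevant.  Unequal series lengths, non-numeric cells and
    missing values are rejected with the offending series named.
    """
    path = Path(path)
    if layout == "wide":
        df = pd.read_csv(path, header=None)
        first = df.iloc[:, 0]
        if first.dtype == object and not np.all([_is_number(v) for v in first]):
            ids = [str(v) for v in first]
            df = df.iloc[:, 1:]
        else:
            ids = [f"s{i + 1}" for i in range(len(df))]
        values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
        if bad.size:
            names = ", ".join(ids[i] for i in bad)
            raise FBAMError(f"non-numeric or missing values in series: {names}")
        return TimeSeriesSet(values=values, series_ids=ids, sampling_rate=sampling_rate)
    if layout == "long":
        df = pd.read_csv(path)
        if df.shape[1] < 3:
            raise FBAMError("long layout needs columns (id, t, value)")
        df.columns = ["id", "t", "value"] + list(df.columns[3:])
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        pivot = df.pivot_table(index="id", columns="t", values="value", sort=True)
        lengths = pivot.notna().sum(axis=1)
        if lengths.nunique() > 1 or pivot.isna().any().any():
            short = lengths[lengths < lengths.max()].index.tolist()
            raise FBAMError(f"ragged or missing series: {short}")
        ids = [str(i) for i in pivot.index]
        return TimeSeriesSet(
            values=pivot.to_numpy(dtype=float), series_ids=ids, sampling_rate=sampling_rate
        )
    raise FBAMError(f"unknown layout {layout!r}; use 'wide' or 'long'")


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def result_to_dict(result: FBAMResult, spectra: SpectralEstimateSet) -> dict:
    """Serializable view of a fitted result (labels 1-based, cuts as Fourier
    index m plus cycles/sample, plus Hz when a sampling rate is known)."""
    T = spectra.T
    fs = spectra.sampling_rate
    sol = result.best
    groups = []
    for j, part in enumerate(sol.partitions):
        rows = spectra.power[sol.clustering.members(j)]
        cm = collapsed_power(rows, part)
        cut_freqs = part.cut_frequencies(T)
        group = {
            "group": j + 1,
            "size": int(rows.shape[0]),
            "cut_indices": [int(c) + 1 for c in part.cuts],  # Fourier index m
            "cut_frequencies": [float(f) for f in cut_freqs],
            "band_means": [float(v) for v in cm.per_band_mean],
            "band_sizes": [int(v) for v in cm.band_sizes],
        }
        if fs is not None:
            group["cut_frequencies_hz"] = [float(f * fs) for f in cut_freqs]
        groups.append(group)
    table = result.table.to_dataframe()
    return {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            **{k: _jsonify(v) for k, v in result.provenance.items()},
            "config": {k: _jsonify(v) for k, v in result.config.__dict__.items()},
            "sampling_rate": fs,
        },
        "mode": result.mode,
        "selected": {"J": result.selected[0], "L": result.selected[1]},
        "loss": float(sol.loss),
        "labels": [int(l) + 1 for l in sol.clustering.labels],
        "groups": groups,
        "criterion_table": [
            {k: _jsonify(v) for k, v in row.items()} for row in table.to_dict("records")
        ],
    }


def _jsonify(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        v = float(v)
    if isinstance(v, float) and not math.isfinite(v):
        return None
    if isinstance(v, (list, tuple)):
        return [_jsonify(x) for x in v]
    if v is None or isinstance(v, (int, float, str, bool, dict)):
        return v
    return str(v)


def write_result(
    result: FBAMResult, path: str | Path, spectra: SpectralEstimateSet
) -> None:
    """Write a fitted result as JSON (validated against the shipped schema)."""
    obj = result_to_dict(result, spectra)
    validate_result(obj)
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=False))


def read_result(path: str | Path) -> dict:
    obj = json.loads(Path(path).read_text())
    validate_result(obj)
    return obj


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(obj, schema, where: str) -> None:
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        if "null" in allowed and obj is None:
            return
        pys = tuple(_TYPES[t] for t in allowed if t != "null")
        if not isinstance(obj, pys) or (isinstance(obj, bool) and bool not in pys):
            raise FBAMError(f"{where}: expected {typ}, got {type(obj).__name__}")
    if "enum" in schema and obj not in schema["enum"]:
        raise FBAMError(f"{where}: {obj!r} not in {schema['enum']}")
    if isinstance(obj, dict):
        for key in schema.get("required", []):
            if key not in obj:
                raise FBAMError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                _check(obj[key], sub, f"{where}.{key}")
    if isinstance(obj, list) and "items" in schema:
        for i, item in enumerate(obj):
            _check(item, schema["items"], f"{where}[{i}]")


def validate_result(obj: dict) -> None:
    """Validate a result dict against the shipped JSON schema.

    Covers the subset of JSON-Schema used by the schema file (type, enum,
    required, properties, items).
    """
    schema = json.loads(_SCHEMA_PATH.read_text())
    _check(obj, schema, "result")
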