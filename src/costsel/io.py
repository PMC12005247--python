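"""Readers, writers, and configuration loading.

Cohort tables travel as UTF-8 comma-separated files with a header row. The
canonical columns are (genotype, environment, pot, seeds_planted,
seedlings_retained, adults, seeds_produced); ``column_map`` lets a table
with different column names (for instance a deposited dataset's layout) be
loaded without rewriting the file. Environment density is either supplied
as an explicit mapping / config entry or inferred from environment ids that
contain "high_density" / "low_density".
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .empirical import REQUIRED_COLUMNS, CohortTable, PipelineConfig
from .errors import ValidationError

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "infer_density_map",
    "load_config",
    "pipeline_config_from_mapping",
    "json_ready",
    "dump_json",
]


def infer_density_map(environments) -> dict[str, str]:
    """Infer density labels from environment ids containing a density token."""
    out: dict[str, str] = {}
    for env in environments:
        low = "low_density" in env or env.endswith("_low")
        high = "high_density" in env or env.endswith("_high")
        if low == high:
            raise ValidationError(
                f"cannot infer density for environment {env!r}; pass an "
                "explicit density map"
            )
        out[env] = "low" if low else "high"
    return out


def read_cohort_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    density_map: Mapping[str, str] | None = None,
) -> CohortTable:
    """Load and validate a cohort table from CSV.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"genotype": "line_id"}``; unmapped canonical names are expected
    verbatim. Malformed rows are reported with their file line numbers
    (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    rename = {}
    for canonical in REQUIRED_COLUMNS:
        source = (column_map or {}).get(canonical, canonical)
        if source not in df.columns:
            raise ValidationError(
                f"{path}: missing column {source!r} (for {canonical!r})"
            )
        rename[source] = canonical
    df = df.rename(columns=rename).loc[:, list(REQUIRED_COLUMNS)]

    problems = []
    for col in ("seeds_planted", "seedlings_retained", "adults", "seeds_produced"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna() | (values < 0) | (values % 1 != 0)]
        problems += [(int(i) + 2, f"{col} is not a non-negative count") for i in bad]
        df[col] = values
    ok = ~df[["seeds_planted", "seedlings_retained", "adults"]].isna().any(axis=1)
    order_bad = df.index[
        ok
        & (
            (df["adults"] > df["seedlings_retained"])
            | (df["seedlings_retained"] > df["seeds_planted"])
        )
    ]
    problems += [
        (int(i) + 2, "requires adults <= seedlings_retained <= seeds_planted")
        for i in order_bad
    ]
    if problems:
        listing = "; ".join(f"line {ln}: {msg}" for ln, msg in sorted(problems)[:20])
        raise ValidationError(f"{path}: {len(problems)} malformed row(s): {listing}")

    if density_map is None:
        density_map = infer_density_map(df["environment"].unique())
    return CohortTable(data=df, density_map=dict(density_map))


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write the canonical CSV layout (UTF-8, comma-separated, header)."""
    table.data.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return loaded


def pipeline_config_from_mapping(mapping: Mapping) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a config-file mapping."""
    kwargs = {}
    for key in (
        "dispersal_survival",
        "bootstrap_replicates",
        "alpha",
        "n_permutations",
        "seed",
        "strategy",
    ):
        if key in mapping:
            value = mapping[key]
            if key == "dispersal_survival":
                value = tuple(float(v) for v in value)
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def json_ready(obj):
    """Recursively convert to JSON-serializable values; floats get 10
    significant digits, NaN becomes null."""
    if isinstance(obj, Mapping):
        return {str(k): json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, np.ndarray)):
        return [json_ready(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        if math.isnan(f) or math.isinf(f):
            return None
        return float(f"{f:.10g}")
    return obj


def dump_json(obj, fh=None) -> str:
    """Serialize with the package's float convention; optionally write."""
    text = json.dumps(json_ready(obj), indent=2, sort_keys=True)
    if fh is not None:
        fh.write(text + "\n")
    return text
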