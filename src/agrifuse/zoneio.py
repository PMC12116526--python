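"""Per-zone CSV tables and JSON run manifests.

One CSV dialect is shared by every stage (RFC 4180, UTF-8, '.' decimal):
a required 0-based integer ``zone_id`` key plus whatever per-zone
columns the stage produces.  Floats are written with 17 significant
digits so write-then-read round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "ZONE_KEY",
    "PLAN_COLUMNS",
    "read_zone_table",
    "write_zone_table",
    "write_manifest",
]

ZONE_KEY = "zone_id"
PLAN_COLUMNS = [ZONE_KEY, "row", "col", "u_water", "u_fertilizer", "u_pesticide"]


def read_zone_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a per-zone CSV, validating the key and required columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"zone table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in [ZONE_KEY] + (required or []) if c not in df.columns]
    if missing:
        raise ValueError(f"zone table {path} is missing required columns: {missing}")
    if len(df):
        dup = df[ZONE_KEY][df[ZONE_KEY].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate zone_id values: {sorted(set(int(v) for v in dup))}")
        df[ZONE_KEY] = df[ZONE_KEY].astype(int)
    return df


def write_zone_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-zone CSV losslessly (17 significant digits)."""
    if ZONE_KEY not in df.columns:
        raise ValueError(f"zone table must carry a {ZONE_KEY!r} column")
    df.to_csv(path, index=False, float_format="%.17g")


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (seed, config hash, versions) for reproducibility."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True) + "\n")
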