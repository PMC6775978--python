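"""Shared table readers/writers.

All tabular output is TSV, UTF-8, LF line endings, with floats serialized
to 9 significant digits — enough to round-trip the quantities computed here
bit-stably across platforms.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_tsv", "read_tsv", "write_json", "format_float"]

FLOAT_FORMAT = "%.9g"


def format_float(x: float) -> str:
    return FLOAT_FORMAT % x


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as deterministic TSV (no index, 9-sig-digit floats)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(
        path,
        sep="\t",
        index=False,
        float_format=FLOAT_FORMAT,
        lineterminator="\n",
        encoding="utf-8",
    )


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
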