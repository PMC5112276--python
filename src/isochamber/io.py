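"""Delimited-text I/O with a versioned schema comment line.

Every table written by the pipeline starts with a single comment line
``# isochamber:<name>:v1`` followed by a normal CSV header; readers skip
comment lines, so the files stay plain pandas-compatible CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMA_VERSION = 1


def write_table(df: pd.DataFrame, path: str | Path, name: str,
                float_format: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# isochamber:{name}:v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False, float_format=float_format)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
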