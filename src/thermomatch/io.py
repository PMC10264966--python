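"""Typed tabular I/O helpers.

All tables are CSV with units baked into the column names (temperature_C,
oxygen_mg_per_L, ...). Floats are written in shortest round-trip form so a
written table re-read reproduces the in-memory values bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_csv", "read_csv"]


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False,
              float_format=lambda v: repr(float(v)))


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")
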