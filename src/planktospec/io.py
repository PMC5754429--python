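"""CSV writers/readers with '#'-prefixed metadata headers.

Every output file carries a complete parameter echo so a run can be
reproduced from its own header.  Floats are written at full precision
(round-trip exact)."""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["write_table_csv", "read_table_csv"]


def write_table_csv(df: pd.DataFrame, path: str,
                    metadata: Optional[Dict[str, object]] = None) -> None:
    """Write a DataFrame with metadata rows ('# key = value') on top.

    Non-finite values are refused with the offending location."""
    arr = df.select_dtypes(include=[np.number]).to_numpy()
    if arr.size and not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))[0]
        raise DomainError(
            f"non-finite value at row {bad[0]}, column "
            f"{df.select_dtypes(include=[np.number]).columns[bad[1]]!r}")
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table_csv(path: str) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a CSV written by :func:`write_table_csv`; '#' rows become the
    metadata dict."""
    meta: Dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    return df, meta
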