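"""Output and observation-file I/O.

Every CSV written by the package carries a provenance header comment
(package version, configuration hash, seed); all readers skip comment
lines. Observation tables use the tidy schema date,variable,value[,sd]
with the four observed streams named by variable and unit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["write_csv", "read_observations", "OBS_VARIABLES"]

OBS_VARIABLES = ("psi_xylem_midday", "berry_fw_g", "berry_dw_g", "sugar_g_per_l")


def write_csv(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config_hash: str | None = None,
    index: bool = True,
) -> None:
    """Write a DataFrame with the provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = f"# vinesim {__version__}"
    if config_hash is not None:
        header += f" config={config_hash}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=index)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a tidy observation CSV: date,variable,value[,sd].

    Validates the variable names and value/date parsing with line-anchored
    errors (line numbers refer to the file including header/comments).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    offset = 1
    while offset <= len(lines) and lines[offset - 1].startswith("#"):
        offset += 1
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    if cols[:3] != ["date", "variable", "value"] or cols not in (
        ["date", "variable", "value"],
        ["date", "variable", "value", "sd"],
    ):
        raise ValueError(
            f"{path}: expected columns date,variable,value[,sd], found {cols}"
        )
    for i, var in enumerate(df["variable"]):
        if var not in OBS_VARIABLES:
            raise ValueError(
                f"{path}:{offset + 1 + i}: unknown variable {var!r}; "
                f"valid: {OBS_VARIABLES}"
            )
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        line = offset + 1 + int(np.flatnonzero(vals.isna())[0])
        raise ValueError(f"{path}:{line}: unparseable value")
    try:
        dates = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df["date"], errors="coerce")
        line = offset + 1 + int(np.flatnonzero(parsed.isna())[0])
        raise ValueError(f"{path}:{line}: unparseable date") from None
    out = df.copy()
    out["date"] = dates
    out["value"] = vals.astype(float)
    if "sd" in out.columns:
        out["sd"] = pd.to_numeric(out["sd"], errors="coerce")
    return out
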