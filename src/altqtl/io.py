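"""Delimited-text readers and writers for every pipeline table."""

from __future__ import annotations

import pandas as pd

HYDRO_COLUMNS = ["line", "block", "plant", "il_c", "fl_c", "il_Al", "fl_Al"]
FIELD_COLUMNS = ["line", "environment", "replicate", "block", "yield_t_ha"]
HYBRID_COLUMNS = ["whole_plot", "treatment", "hybrid", "female", "male", "dosage",
                  "yield_t_ha"]


def _read_checked(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_hydroponics(path) -> pd.DataFrame:
    df = _read_checked(path, HYDRO_COLUMNS)
    df["line"] = df["line"].astype(str)
    return df


def read_field(path) -> pd.DataFrame:
    df = _read_checked(path, FIELD_COLUMNS)
    df["line"] = df["line"].astype(str)
    return df


def read_hybrid(path) -> pd.DataFrame:
    return _read_checked(path, HYBRID_COLUMNS)


def read_traits(path) -> pd.DataFrame:
    """Line x trait BLUE table, first column the line id."""
    df = pd.read_csv(path, sep=None, engine="python")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "line"
    return df.astype(float)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path)


def write_scan_profile(scan, path) -> None:
    """Scan table plus the threshold as a constant column (plottable profile)."""
    t = scan.table.copy()
    t["threshold_neglog10p"] = scan.threshold
    t.to_csv(path, index=False)


def write_varcomp(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False)
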