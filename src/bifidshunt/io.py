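"""CSV schemas and readers/writers for the pipeline's four input tables.

Schemas (long format, UTF-8, delimiter configurable):

* growth:    strain, substrate, replicate, time_h, od600
* standards: analyte, concentration_mM, response
* panel:     sample, strain, substrate, replicate, analyte, concentration_mM
* ct:        sample, condition, gene, role, ct  (+ optional technical_replicate)

Numbers are serialized with 12 significant digits so write -> read round
trips are the identity at that precision.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_growth",
    "read_standards",
    "read_panel",
    "read_ct",
]

SCHEMAS = {
    "growth": ["strain", "substrate", "replicate", "time_h", "od600"],
    "standards": ["analyte", "concentration_mM", "response"],
    "panel": ["sample", "strain", "substrate", "replicate", "analyte", "concentration_mM"],
    "ct": ["sample", "condition", "gene", "role", "ct"],
}

_NONNEGATIVE = {
    "growth": ["time_h"],
    "standards": ["concentration_mM"],
    "panel": ["concentration_mM"],
    "ct": [],
}


def read_table(path, schema: str, sep: str = ",") -> pd.DataFrame:
    """Read one of the four schemas, validating required columns and
    basic invariants (LF and CRLF line endings both accepted)."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in _NONNEGATIVE[schema]:
        if (df[col].astype(float) < 0).any():
            raise ValueError(f"{path}: negative values in column {col!r}")
    return df


def write_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.12g", lineterminator="\n")


def read_growth(path, sep: str = ",") -> pd.DataFrame:
    return read_table(path, "growth", sep)


def read_standards(path, sep: str = ",") -> pd.DataFrame:
    return read_table(path, "standards", sep)


def read_panel(path, sep: str = ",") -> pd.DataFrame:
    return read_table(path, "panel", sep)


def read_ct(path, sep: str = ",") -> pd.DataFrame:
    return read_table(path, "ct", sep)
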