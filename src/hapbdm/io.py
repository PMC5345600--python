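"""CSV/TSV readers and writers for genotype and peak tables.

Both readers sniff the delimiter (comma or tab) and treat empty fields,
``NA`` and ``NaN`` as missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotyping import META_COLUMNS

_NA_VALUES = ["", "NA", "NaN", "nan"]


def read_genotype_table(path) -> pd.DataFrame:
    """Read a genotype table: sample_id, phenotype, cytotype, then markers."""
    table = pd.read_csv(
        path, sep=None, engine="python", na_values=_NA_VALUES, keep_default_na=False, dtype=str
    )
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"genotype table lacks required columns: {missing}")
    if table["sample_id"].duplicated().any():
        raise ValueError("sample_ids must be unique")
    for c in table.columns:
        if c not in META_COLUMNS:
            table[c] = table[c].astype(object).where(table[c].notna(), np.nan)
    return table


def write_genotype_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep="NA")


def read_peak_table(path) -> dict[tuple[str, str], list[tuple[float, float]]]:
    """Read a fragment peak table (sample_id, marker, size_bp, area) into a
    ``(sample, marker) -> [(size, area), ...]`` map."""
    raw = pd.read_csv(path, sep=None, engine="python", na_values=_NA_VALUES, keep_default_na=False)
    required = {"sample_id", "marker", "size_bp", "area"}
    if not required.issubset(raw.columns):
        raise ValueError(f"peak table lacks required columns: {sorted(required - set(raw.columns))}")
    peaks: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for row in raw.itertuples(index=False):
        peaks.setdefault((str(row.sample_id), str(row.marker)), []).append(
            (float(row.size_bp), float(row.area))
        )
    return peaks
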