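"""Reading and writing the long-format quantitation tables.

The interchange format is TSV (CSV accepted by delimiter sniffing) with
one row per (sample, feature) and the fixed header columns:

    athlete_id, arm, occasion, batch_id, injection_order, is_qc,
    protein_id, peptide_id (optional), intensity

Unknown columns are preserved as annotations; schema violations raise
``DataError`` naming the offending rows/columns.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .synthetic_data import QUANT_COLUMNS

REQUIRED_COLUMNS = [c for c in QUANT_COLUMNS if c != "peptide_id"]


class DataError(ValueError):
    pass


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_quant_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format quantitation table (TSV/CSV)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    table = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"missing required column(s): {missing}")
    if "peptide_id" not in table.columns:
        table["peptide_id"] = ""
    table["peptide_id"] = table["peptide_id"].fillna("").astype(str)

    bad = table.index[~(table["intensity"] > 0)]
    if len(bad):
        raise DataError(
            f"non-positive or missing intensity at row(s) {bad.tolist()[:10]}"
        )
    key_cols = ["batch_id", "athlete_id", "arm", "occasion", "injection_order",
                "protein_id", "peptide_id"]
    dup = table.duplicated(key_cols, keep=False)
    if dup.any():
        offenders = table.loc[dup, key_cols].drop_duplicates().head(5)
        raise DataError(
            "duplicate (sample, feature) key(s):\n" + offenders.to_string(index=False)
        )
    return table


def write_quant_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a quantitation table as TSV (round-trips through read)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = QUANT_COLUMNS + [c for c in table.columns if c not in QUANT_COLUMNS]
    table[cols].to_csv(path, sep="\t", index=False)


def write_matrix(matrix, values_path: str | Path, cv_path: str | Path | None = None) -> None:
    """Write a ProteinMatrix as wide TSV plus a per-protein CV TSV."""
    values_path = Path(values_path)
    values_path.parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(values_path, sep="\t")
    meta_path = values_path.with_name(values_path.stem + "_samples.tsv")
    matrix.samples.to_csv(meta_path, sep="\t")
    if cv_path is not None and matrix.technical_cv is not None:
        matrix.technical_cv.rename("technical_cv").to_csv(cv_path, sep="\t")
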