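"""Tabular and sequence I/O for the pipeline.

Everything on disk is plain text: FASTA for sequences, UTF-8 TSV with a
header row for tables, YAML for the marker-catalog manifest, pathway
definitions and pipeline configuration.  Floats are written with six
significant digits; tests compare with tolerances, never printed strings.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "read_counts",
    "read_sample_sheet",
    "read_bin_table",
    "write_bin_table",
    "read_env_table",
]

_FLOAT_FORMAT = "%.6g"


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Duplicate identifiers are rejected; CRLF line endings and a missing
    trailing newline are tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: dict[str, str] = {}
    text = path.read_text().replace("\r\n", "\n").replace("\r", "\n")
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id '{rec.id}' in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_table(path: str | Path, required: Iterable[str] | None = None) -> pd.DataFrame:
    """Read a TSV table, checking that ``required`` columns are present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing required column(s) {missing}; "
                f"expected header to include {list(required)}"
            )
    return df


def write_table(path: str | Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def read_counts(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a count table (feature_id, length, one column per sample).

    Returns ``(counts, lengths)`` with features as the index.
    """
    df = read_table(path, required=["feature_id", "length"])
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"duplicate feature_id(s) in {path}: {dups}")
    df = df.set_index("feature_id")
    lengths = df.pop("length")
    return df, lengths


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a sample sheet (sample_id, group) into a sample→group Series."""
    df = read_table(path, required=["sample_id", "group"])
    if df["sample_id"].duplicated().any():
        raise ValueError(f"duplicate sample_id in {path}")
    return df.set_index("sample_id")["group"]


def read_bin_table(path: str | Path) -> pd.DataFrame:
    """Read a CheckM-style bin table.

    Columns: bin_id, scaffold_ids (';'-separated), completeness,
    contamination, strain_heterogeneity, species.
    """
    df = read_table(
        path,
        required=[
            "bin_id",
            "scaffold_ids",
            "completeness",
            "contamination",
            "strain_heterogeneity",
            "species",
        ],
    )
    if df["bin_id"].duplicated().any():
        raise ValueError(f"duplicate bin_id in {path}")
    df["scaffold_ids"] = df["scaffold_ids"].map(lambda s: tuple(str(s).split(";")))
    return df


def write_bin_table(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    out["scaffold_ids"] = out["scaffold_ids"].map(";".join)
    write_table(path, out)


ENV_COLUMNS = [
    "sample",
    "group",
    "pH",
    "ammonia_mM",
    "ni_uM",
    "acetate_mM",
    "propionate_mM",
    "butyrate_mM",
    "l_lactate_mM",
    "d_lactate_mM",
]


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Read the environmental/fermentation variable table (fixed header)."""
    df = read_table(path, required=ENV_COLUMNS)
    return df.set_index("sample")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ValueError(f"{path}: file is empty")
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data
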