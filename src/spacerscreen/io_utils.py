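"""File formats and run summaries.

FASTA through Biopython; tidy TSV/CSV through pandas.  Every run writes a
JSON summary with the seed, a config hash and record-exclusion counts so
results are traceable to their inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .sequence_features import LogoMatrix

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_table",
    "read_plate_table",
    "write_logo_tsv",
    "config_hash",
    "write_run_summary",
]


def write_fasta(records: dict[str, str], path) -> None:
    """Write id->sequence pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path, *, comment: str | None = None) -> None:
    """Write a tidy table; an optional '#' header line documents units/conventions."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_plate_table(path) -> pd.DataFrame:
    """Read a plate endpoint/timecourse CSV/TSV, reporting the offending line on failure."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    required = {"clone_id", "condition", "od600", "rfu", "blank_od", "blank_rfu"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("condition", "od600", "rfu", "blank_od", "blank_rfu"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric value in column '{col}' at line {line}")
        df[col] = pd.to_numeric(df[col])
    return df


def write_logo_tsv(matrix: LogoMatrix, path) -> None:
    """Serialize a logo as rows A, C, G, T (frequencies) plus an ic row (bits)."""
    df = pd.DataFrame(matrix.freq, index=list(LogoMatrix.ROWS))
    df.loc["ic"] = matrix.ic
    df.columns = [f"pos{i + 1}" for i in range(matrix.freq.shape[1])]
    df.to_csv(path, sep="\t", index_label="row")


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_run_summary(path, *, seed: int, config: dict, exclusions: dict | None = None,
                      extra: dict | None = None) -> dict:
    summary = {
        "package": "spacerscreen",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "exclusions": exclusions or {},
    }
    if extra:
        summary.update(extra)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
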