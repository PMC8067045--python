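"""Readers and writers for the standard formats the pipeline consumes.

FASTA goes through Biopython; tables through pandas; GMT (gene-set) files are
the simple tab-separated dialect: set name, description, then member ids.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read GMT into {set name: {"description": str, "members": set}}."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need >=3 fields): {line!r}")
            name, desc, members = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValueError(f"duplicate gene-set name: {name}")
            sets[name] = {"description": desc, "members": set(m for m in members if m)}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, body in sets.items():
            members = sorted(body["members"])
            fh.write("\t".join([name, body.get("description", "")] + members) + "\n")


def read_tsv(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
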