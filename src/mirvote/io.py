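"""FASTA and feature-table I/O.

FASTA reading normalizes residues (uppercase, T→U) and tolerates line
wrapping; ids must be unique.  Feature tables are TSV with an ``id`` first
column, the 125 registry columns in order, and optional ``label`` /
``tag`` trailing columns.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import FEATURE_NAMES
from .simulate import DatasetManifest, SimRecord
from .structure import RnaSequence


def read_fasta(path) -> list[RnaSequence]:
    """Read FASTA into validated :class:`RnaSequence` records.

    Duplicate ids raise ``ValueError``; empty records are skipped with a
    warning.
    """
    out: list[RnaSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = str(rec.seq)
        if not residues:
            warnings.warn(f"skipping empty record {rec.id!r}", stacklevel=2)
            continue
        out.append(RnaSequence(id=rec.id, residues=residues))
    return out


def write_fasta(records: Iterable[RnaSequence | SimRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_feature_table(
    frame: pd.DataFrame,
    path,
    labels: Optional[Sequence] = None,
    tags: Optional[Sequence] = None,
) -> None:
    """Write a feature table as TSV: id column, registry columns, optional
    label/tag columns; header row mandatory."""
    out = frame.copy()
    if labels is not None:
        out["label"] = list(labels)
    if tags is not None:
        out["tag"] = list(tags)
    out.to_csv(path, sep="\t", index=True, index_label="id")


def read_feature_table(path) -> pd.DataFrame:
    """Read a TSV feature table back (id column becomes the index)."""
    return pd.read_csv(path, sep="\t", index_col="id")


def write_manifest(manifest: DatasetManifest, path) -> None:
    frame = pd.DataFrame(
        [
            {"id": r.id, "residues": r.residues, "label": r.label, "tag": r.tag}
            for r in manifest.records
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> DatasetManifest:
    frame = pd.read_csv(path, sep="\t")
    records = tuple(
        SimRecord(str(r.id), str(r.residues), str(r.label), str(r.tag))
        for r in frame.itertuples(index=False)
    )
    return DatasetManifest(records=records, provenance={"path": str(path)})
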