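"""Readers and writers for the plain-text formats the pipeline touches.

All in-memory coordinates are 0-based half-open; only the GFF3 layer
converts to/from the 1-based inclusive convention used on file. FASTA goes
through Biopython, Newick through dendropy; the GFF3 dialect here is a thin
strict subset (nine columns, ``key=value`` attributes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence (DNA or amino acid)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record has an empty id")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class AnnotationRecord:
    """One GFF3 feature, held with 0-based half-open coordinates.

    ``start``/``end`` are the in-memory interval; file I/O converts to the
    1-based inclusive columns of GFF3.
    """

    scaffold_id: str
    feature_type: str
    start: int
    end: int
    strand: str
    attributes: dict = field(default_factory=dict)
    source: str = "tfxkit"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(
                f"feature on {self.scaffold_id} has unknown strand {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature on {self.scaffold_id} has empty/negative interval "
                f"[{self.start},{self.end})"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file, rejecting duplicate ids and empty sequences."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), desc))
    logger.info("read %d FASTA records from %s", len(records), path)
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise FormatError(f"duplicate sequence id {r.id!r} on write")
        seen.add(r.id)
    bio = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
    logger.info("wrote %d FASTA records to %s", len(records), path)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _escape_attr(value: str) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D")


def write_gff3(annotations: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Write features, converting 0-based half-open to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = ";".join(
                f"{k}={_escape_attr(v)}" for k, v in sorted(a.attributes.items())
            )
            fh.write(
                f"{a.scaffold_id}\t{a.source}\t{a.feature_type}\t"
                f"{a.start + 1}\t{a.end}\t.\t{a.strand}\t.\t{attrs or '.'}\n"
            )


def read_gff3(path: str | Path) -> list[AnnotationRecord]:
    """Read features, converting 1-based inclusive to 0-based half-open."""
    out: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, source, ftype, start, end, _score, strand, _phase, attr = cols
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise FormatError(f"{path}:{lineno}: end < start ({end_i} < {start_i})")
            attributes: dict = {}
            if attr not in {".", ""}:
                for pair in attr.split(";"):
                    if not pair:
                        continue
                    k, _, v = pair.partition("=")
                    attributes[k] = v.replace("%3B", ";").replace("%3D", "=")
            out.append(
                AnnotationRecord(
                    scaffold_id=seqid, feature_type=ftype,
                    start=start_i - 1, end=end_i, strand=strand,
                    attributes=attributes, source=source,
                )
            )
    logger.info("read %d GFF3 features from %s", len(out), path)
    return out


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises its own hierarchy
        raise FormatError(f"malformed Newick in {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise FormatError(f"duplicate leaf labels in {path}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------
# Vector tables
# ---------------------------------------------------------------------------

def read_vectors(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a labeled vector table (TSV or CSV; first column = protein id).

    Returns (ids, matrix); rows keep file order. Ragged or non-finite rows
    are rejected.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    # header row optional: sniff whether the first row's numeric fields parse
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    first = df.iloc[0, 1:]
    try:
        first.astype(float)
        has_header = False
    except ValueError:
        has_header = True
    if has_header:
        df = df.iloc[1:].reset_index(drop=True)
    if df.isnull().any().any():
        raise FormatError(f"ragged vector rows in {path}")
    ids = df.iloc[:, 0].tolist()
    if len(ids) != len(set(ids)):
        raise FormatError(f"duplicate vector ids in {path}")
    try:
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric vector entry in {path}: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise FormatError(f"non-finite vector entry in {path}")
    logger.info("read %d x %d vectors from %s", *values.shape, path)
    return ids, values


def write_vectors(ids: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    if len(ids) != values.shape[0]:
        raise FormatError("id count does not match vector row count")
    df = pd.DataFrame(values)
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Flat key=value config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key=value`` config file; '#' starts a comment line."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value")
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out


def write_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in config.items():
            fh.write(f"{k}={v}\n")


__all__ = [
    "SequenceRecord", "AnnotationRecord", "FormatError",
    "read_fasta", "write_fasta", "read_gff3", "write_gff3",
    "read_newick", "write_newick", "read_vectors", "write_vectors",
    "read_config", "write_config",
]
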