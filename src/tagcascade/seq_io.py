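"""Readers and writers for the on-disk formats the pipeline touches.

Four formats: 4-line FASTQ (gzip-transparent, phred offset 33 or 64),
FASTA with ``;size=N`` dereplication annotations, the feature-table TSV
(``#FEATURE_ID`` + one column per sample + optional trailing ``taxonomy``
column), and single-tree newick.  Parsing of FASTQ/FASTA is delegated to
Biopython and newick to scikit-bio; the wrappers exist to give uniform
record types and precise error messages.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised on malformed input files."""


@dataclass
class SeqRecord:
    """One read or reference sequence with optional per-base phred scores.

    ``seq`` is uppercased on ingestion and U is mapped to T; ``qual``,
    when present, has the same length as ``seq``.
    """

    id: str
    seq: str
    qual: Optional[list[int]] = None
    desc: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        qual = None if self.qual is None else list(reversed(self.qual))
        return SeqRecord(self.id, reverse_complement(self.seq), qual, self.desc)


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, phred_offset: int = 33) -> Iterator[SeqRecord]:
    """Stream records from a 4-line FASTQ file (``.gz`` handled transparently).

    Raises :class:`FormatError` on truncated records (naming the offending
    position) or seq/qual length mismatches (naming the record id).
    """
    if phred_offset not in (33, 64):
        raise ValueError(f"phred_offset must be 33 or 64, got {phred_offset}")
    fmt = "fastq" if phred_offset == 33 else "fastq-illumina"
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, fmt):
                qual = list(rec.letter_annotations["phred_quality"])
                ident, _, desc = rec.description.partition(" ")
                yield SeqRecord(rec.id, str(rec.seq), qual, desc)
        except ValueError as exc:  # Biopython's parse errors
            raise FormatError(f"{path}: {exc}") from exc


def write_fastq(records: Iterable[SeqRecord], path, phred_offset: int = 33) -> int:
    """Write records as 4-line FASTQ; returns the number written."""
    n = 0
    with _open_text(path, "wt") as out:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            header = rec.id if not rec.desc else f"{rec.id} {rec.desc}"
            qline = "".join(chr(min(q, 93) + phred_offset) for q in rec.qual)
            out.write(f"@{header}\n{rec.seq}\n+\n{qline}\n")
            n += 1
    return n


_SIZE_RE = re.compile(r"(?:^|;)size=(-?\d+);?")


def read_sized_fasta(path) -> Iterator[tuple[SeqRecord, int]]:
    """Stream ``(record, size)`` pairs from a dereplication-annotated FASTA.

    The size is carried as a ``;size=N`` header field (trailing ``;``
    tolerated).  Records lacking the annotation default to size 1 with a
    logged warning; size <= 0 is a :class:`FormatError`.
    """
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            m = _SIZE_RE.search(rec.description)
            if m is None:
                logger.warning("record %r lacks a size annotation; assuming size=1", rec.id)
                size = 1
                ident = rec.id
            else:
                size = int(m.group(1))
                if size <= 0:
                    raise FormatError(f"record {rec.id!r}: size={size} is not positive")
                ident = rec.id.split(";")[0]
            yield SeqRecord(ident, str(rec.seq)), size


def write_sized_fasta(entries: Iterable[tuple[SeqRecord, int]], path) -> int:
    """Write ``(record, size)`` pairs as ``>id;size=N`` FASTA."""
    n = 0
    with _open_text(path, "wt") as out:
        for rec, size in entries:
            if size <= 0:
                raise FormatError(f"record {rec.id!r}: size={size} is not positive")
            out.write(f">{rec.id};size={size}\n{rec.seq}\n")
            n += 1
    return n


def read_fasta(path) -> Iterator[SeqRecord]:
    """Plain FASTA reader (headers kept as id + description)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            ident, _, desc = rec.description.partition(" ")
            yield SeqRecord(rec.id, str(rec.seq), desc=desc.strip())


def write_fasta(records: Iterable[SeqRecord], path) -> int:
    n = 0
    with _open_text(path, "wt") as out:
        for rec in records:
            header = rec.id if not rec.desc else f"{rec.id} {rec.desc}"
            out.write(f">{header}\n{rec.seq}\n")
            n += 1
    return n


@dataclass
class FeatureTable:
    """Features x samples count matrix with optional lineage annotations.

    Raw tables are integral; consensus-rarefied tables are real-valued.
    ``lineage`` maps feature id -> ';'-separated ranked lineage string.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    lineage: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.feature_ids)}, {len(self.sample_ids)})"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicated feature id")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def sample_totals(self) -> pd.Series:
        return self.to_dataframe().sum(axis=0)

    def select_features(self, keep: Sequence[str]) -> "FeatureTable":
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        feats = [self.feature_ids[i] for i in idx]
        lin = None
        if self.lineage is not None:
            lin = {f: self.lineage[f] for f in feats if f in self.lineage}
        return FeatureTable(feats, list(self.sample_ids), self.counts[idx, :], lin)


def _format_value(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return f"{x:.12g}"


def write_feature_table(table: FeatureTable, path) -> None:
    """Serialize to the ``#FEATURE_ID`` TSV schema (12 significant digits)."""
    with open(path, "wt") as out:
        cols = ["#FEATURE_ID"] + list(table.sample_ids)
        if table.lineage is not None:
            cols.append("taxonomy")
        out.write("\t".join(cols) + "\n")
        for i, fid in enumerate(table.feature_ids):
            row = [fid] + [_format_value(v) for v in table.counts[i]]
            if table.lineage is not None:
                row.append(table.lineage.get(fid, ""))
            out.write("\t".join(row) + "\n")


def read_feature_table(path) -> FeatureTable:
    """Parse the ``#FEATURE_ID`` TSV schema back into a :class:`FeatureTable`."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if not header or header[0] != "#FEATURE_ID":
            raise FormatError(f"{path}: first column must be '#FEATURE_ID'")
        has_tax = header[-1] == "taxonomy"
        sample_ids = header[1:-1] if has_tax else header[1:]
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        lineage: dict[str, str] = {}
        for lineno, line in enumerate(handle, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}: row {lineno} has {len(parts)} fields, expected {len(header)}"
                )
            fid = parts[0]
            if fid in feature_ids:
                raise FormatError(f"{path}: duplicated feature id {fid!r}")
            vals = parts[1:-1] if has_tax else parts[1:]
            row = []
            for col, v in zip(sample_ids, vals):
                try:
                    row.append(float(v))
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell at row {fid!r}, column {col!r}: {v!r}"
                    ) from None
            feature_ids.append(fid)
            rows.append(row)
            if has_tax and parts[-1]:
                lineage[fid] = parts[-1]
    counts = np.array(rows, dtype=float) if rows else np.zeros((0, len(sample_ids)))
    return FeatureTable(feature_ids, list(sample_ids), counts, lineage if has_tax else None)


def read_newick(path) -> TreeNode:
    """Read a single rooted tree; leaf names must be unique, branch lengths >= 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"{path}: newick parse error: {exc}") from exc
    names = [t.name for t in tree.tips()]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise FormatError(f"{path}: duplicate leaf name(s): {sorted(dupes)}")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise FormatError(f"{path}: negative branch length on {node.name!r}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
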