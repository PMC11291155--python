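"""Shared I/O layer: reference sequences, alignments, and tabular output.

All coordinates in this package are 1-based and inclusive on the mature
reference sequence; "C12" means the 12th nucleotide of the mature tRNA.
Sequences are stored in the DNA alphabet (U is converted to T on input) so
pileups and codon tables share one alphabet.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam
import yaml
from Bio import SeqIO

logger = logging.getLogger("trnamod")

DNA_BASES = ("A", "C", "G", "T")
#: Marker used inside :attr:`AlignmentRecord.bases` for a deleted reference base.
DELETION = "-"


def configure_logging(level: str = "INFO") -> None:
    """Configure the package logger once, for CLI and script use."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def load_config(path: str | os.PathLike) -> dict:
    """Read a YAML key-value configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------

@dataclass
class Annotation:
    """A labelled 1-based position on a reference (e.g. a modified site)."""

    position: int
    label: str = ""


@dataclass
class ReferenceRecord:
    id: str
    sequence: str
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if not self.sequence:
            raise ValueError(f"reference {self.id!r} has an empty sequence")
        for ann in self.annotations:
            if not 1 <= ann.position <= len(self.sequence):
                raise ValueError(
                    f"annotation position {ann.position} outside reference "
                    f"{self.id!r} of length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        return self.sequence[position - 1]


class ReferenceSet:
    """An ordered collection of uniquely named reference sequences."""

    def __init__(self, records: Iterable[ReferenceRecord] = ()) -> None:
        self.records: list[ReferenceRecord] = []
        self._by_id: dict[str, ReferenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: ReferenceRecord) -> None:
        if rec.id in self._by_id:
            raise ValueError(f"duplicate reference id {rec.id!r}")
        self.records.append(rec)
        self._by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    def __getitem__(self, ref_id: str) -> ReferenceRecord:
        return self._by_id[ref_id]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | os.PathLike) -> ReferenceSet:
    """Read a FASTA file into a :class:`ReferenceSet`.

    U is converted to T and sequences are upper-cased.  Duplicate record ids
    and empty sequences raise ``ValueError``.  An empty file yields an empty
    set.
    """
    refs = ReferenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        refs.add(ReferenceRecord(id=rec.id, sequence=str(rec.seq)))
    return refs


def write_fasta(refs: ReferenceSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in refs:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """A single-end, forward-strand, gapped-reference alignment.

    ``bases[i]`` is the read base presented at reference position
    ``start + i`` (1-based); :data:`DELETION` marks a deleted reference base.
    Insertions relative to the reference are dropped, so reference positions
    covered by the record are always contiguous.
    """

    read_id: str
    ref_id: str
    start: int
    bases: str

    @property
    def end(self) -> int:
        """Last reference position covered (inclusive)."""
        return self.start + len(self.bases) - 1

    @property
    def aligned_bases(self) -> list[tuple[int, str]]:
        return [(self.start + i, b) for i, b in enumerate(self.bases)]


_TSV_COLUMNS = ("read_id", "ref_id", "start", "bases")

# cigar consumption: (consumes_query, consumes_ref)
_CIGAR = {
    "M": (True, True),
    "=": (True, True),
    "X": (True, True),
    "D": (False, True),
    "I": (True, False),
    "S": (True, False),  # soft clips ignored for pileup purposes
}


def _aligned_from_cigar(pos: int, cigar: str, seq: str, line_no: int) -> str:
    """Expand a CIGAR string into per-reference-position bases."""
    out: list[str] = []
    qi = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        if not num:
            raise ValueError(f"malformed CIGAR {cigar!r} at line {line_no}")
        n = int(num)
        num = ""
        if ch == "H":
            continue
        if ch not in _CIGAR:
            raise ValueError(
                f"unsupported CIGAR op {ch!r} at line {line_no}; "
                "only M/=/X/D/I/S/H are accepted"
            )
        consumes_query, consumes_ref = _CIGAR[ch]
        if consumes_ref:
            if consumes_query:
                out.append(seq[qi : qi + n])
            else:
                out.append(DELETION * n)
        if consumes_query:
            qi += n
    if num:
        raise ValueError(f"malformed CIGAR {cigar!r} at line {line_no}")
    return "".join(out)


def _read_sam(path: str, refs: ReferenceSet) -> tuple[list[AlignmentRecord], int]:
    """Parse a SAM file (header optional) through pysam.

    pysam requires @SQ header lines to resolve reference names; when the
    file lacks a header, one is synthesised from ``refs`` into a temporary
    copy before parsing.
    """
    with open(path) as fh:
        first = fh.readline()
    has_header = first.startswith("@")
    if not has_header:
        with tempfile.NamedTemporaryFile(
            "w", suffix=".sam", delete=False
        ) as tmp:
            for rec in refs:
                tmp.write(f"@SQ\tSN:{rec.id}\tLN:{len(rec)}\n")
            with open(path) as fh:
                tmp.write(fh.read())
            sam_path = tmp.name
    else:
        sam_path = str(path)

    records: list[AlignmentRecord] = []
    excluded = 0
    try:
        with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
            for i, aln in enumerate(sam.fetch(until_eof=True), start=1):
                if aln.is_unmapped:
                    continue
                ref_name = aln.reference_name
                if ref_name not in refs:
                    excluded += 1
                    continue
                bases = _aligned_from_cigar(
                    aln.reference_start + 1,
                    aln.cigarstring or "",
                    aln.query_sequence or "",
                    i,
                )
                records.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        ref_id=ref_name,
                        start=aln.reference_start + 1,
                        bases=normalize_sequence(bases),
                    )
                )
    finally:
        if not has_header:
            os.unlink(sam_path)
    return records, excluded


def _read_alignment_tsv(
    path: str, refs: ReferenceSet
) -> tuple[list[AlignmentRecord], int]:
    records: list[AlignmentRecord] = []
    excluded = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TSV_COLUMNS:
            raise ValueError(
                f"alignment TSV must have columns {_TSV_COLUMNS}, got {header}"
            )
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_TSV_COLUMNS):
                raise ValueError(f"malformed alignment line {line_no}")
            read_id, ref_id, start_s, bases = parts
            try:
                start = int(start_s)
            except ValueError as exc:
                raise ValueError(f"malformed start at line {line_no}") from exc
            if ref_id not in refs:
                excluded += 1
                continue
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    ref_id=ref_id,
                    start=start,
                    bases=normalize_sequence(bases),
                )
            )
    return records, excluded


def read_alignments(
    path: str | os.PathLike, refs: ReferenceSet
) -> list[AlignmentRecord]:
    """Read alignments from a SAM file or the package's TSV dialect.

    Files ending in ``.sam`` are parsed as SAM (single-end forward-strand;
    M/=/X/D/I/S CIGAR ops; soft clips ignored).  Anything else is parsed as a
    four-column TSV (``read_id  ref_id  start  bases``) where ``bases`` is the
    per-reference-position base string with ``-`` for deletions.  Reads
    mapped to references absent from ``refs`` are excluded and the exclusion
    count is logged.
    """
    path = str(path)
    if path.endswith(".sam"):
        records, excluded = _read_sam(path, refs)
    else:
        records, excluded = _read_alignment_tsv(path, refs)
    if excluded:
        logger.warning(
            "excluded %d reads mapped to references absent from the reference set",
            excluded,
        )
    return records


def write_alignments_sam(
    records: Sequence[AlignmentRecord], refs: ReferenceSet, path: str | os.PathLike
) -> None:
    """Write alignments as headered SAM (deletions become D CIGAR ops)."""
    with open(path, "w") as fh:
        for rec in refs:
            fh.write(f"@SQ\tSN:{rec.id}\tLN:{len(rec)}\n")
        for aln in records:
            cigar_parts: list[str] = []
            seq_parts: list[str] = []
            for is_del, group in _run_groups(aln.bases):
                n = len(group)
                if is_del:
                    cigar_parts.append(f"{n}D")
                else:
                    cigar_parts.append(f"{n}M")
                    seq_parts.append(group)
            fh.write(
                "\t".join(
                    [
                        aln.read_id,
                        "0",
                        aln.ref_id,
                        str(aln.start),
                        "255",
                        "".join(cigar_parts),
                        "*",
                        "0",
                        "0",
                        "".join(seq_parts),
                        "*",
                    ]
                )
                + "\n"
            )


def _run_groups(bases: str) -> Iterator[tuple[bool, str]]:
    i = 0
    while i < len(bases):
        is_del = bases[i] == DELETION
        j = i
        while j < len(bases) and (bases[j] == DELETION) == is_del:
            j += 1
        yield is_del, bases[i:j]
        i = j


def write_alignments_tsv(
    records: Sequence[AlignmentRecord], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for aln in records:
            fh.write(f"{aln.read_id}\t{aln.ref_id}\t{aln.start}\t{aln.bases}\n")


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_table(
    rows: Sequence[Mapping], path: str | os.PathLike, schema: Sequence[str]
) -> None:
    """Write records as a TSV with a header row.

    Every row must carry every schema field; floats are serialised with
    enough digits (repr-level precision) to round-trip losslessly through
    :func:`read_table`.
    """
    for i, row in enumerate(rows):
        for fieldname in schema:
            if fieldname not in row:
                raise ValueError(f"row {i} is missing field {fieldname!r}")
    df = pd.DataFrame([{f: row[f] for f in schema} for row in rows], columns=schema)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
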