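"""Sequence input/output and fragmentation protocols.

Reads multi-record FASTA files into :class:`LabeledSequence` objects,
optionally attaching taxonomy labels from the record description or from a
sidecar tab-delimited table, and implements the two fragmentation protocols
used throughout the pipeline: splitting a genome into equally spaced
non-overlapping fixed-length chunks, and stitching many short discontiguous
fragments into longer composite sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Taxonomy ranks recognised in headers and label tables.
RANKS = ("order", "family", "genus", "species", "strain")

#: IUPAC nucleotide one-letter codes (unambiguous + ambiguity codes).
IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN")


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


@dataclass
class LabeledSequence:
    """A nucleotide sequence with an identifier and optional taxonomy labels.

    The sequence is stored uppercased; all downstream lookups are
    case-insensitive by construction.
    """

    id: str
    sequence: str
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_NUCLEOTIDES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ChunkSpec:
    """How to split a genome into fixed-length non-overlapping chunks.

    ``chunk_len=20000`` and ``max_chunks=37`` are the reference settings for
    microbial genome identification; chunks are placed with approximately
    equal spacing across the genome.
    """

    chunk_len: int = 20000
    max_chunks: int = 37

    def __post_init__(self) -> None:
        if self.chunk_len < 1:
            raise ValueError("chunk_len must be >= 1")
        if self.max_chunks < 1:
            raise ValueError("max_chunks must be >= 1")


def _parse_labels(text: str) -> dict[str, str]:
    """Parse ``rank=value`` pairs from free text (whitespace or ';' separated)."""
    labels: dict[str, str] = {}
    for token in text.replace(";", " ").split():
        if "=" in token:
            rank, _, value = token.partition("=")
            rank = rank.strip().lower()
            if rank and value:
                labels[rank] = value
    return labels


def read_fasta(path: str | Path) -> list[LabeledSequence]:
    """Read a FASTA file into a list of :class:`LabeledSequence`.

    The header token before the first whitespace becomes the id; the
    remainder of the header is scanned for ``rank=value`` pairs. Sequences
    are uppercased and line breaks removed. Raises :class:`FastaParseError`
    with a line number if the file does not start with '>' or contains an
    empty record.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lineno}: expected '>' at start of first "
                        f"non-blank line, got {line.strip()[:20]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: file contains no records")

    records: list[LabeledSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        labels = _parse_labels(rec.description.partition(" ")[2])
        records.append(LabeledSequence(id=rec.id, sequence=seq, labels=labels))
    if not records:
        raise FastaParseError(f"{path}: file contains no records")
    return records


def write_fasta(path: str | Path, seqs: Iterable[LabeledSequence], width: int = 80) -> None:
    """Write sequences to FASTA; labels are embedded as ``rank=value`` pairs."""
    records = []
    for s in seqs:
        desc = " ".join(f"{rank}={value}" for rank, value in s.labels.items())
        records.append(SeqRecord(Seq(s.sequence), id=s.id, description=desc))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def read_label_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a 2-column TSV label sidecar: ``id<TAB>rank=value;rank=value``."""
    table: dict[str, dict[str, str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            table[parts[0]] = _parse_labels(parts[1])
    return table


def attach_labels(
    seqs: Iterable[LabeledSequence], table: dict[str, dict[str, str]]
) -> list[LabeledSequence]:
    """Merge sidecar labels into sequences (sidecar wins on conflicts)."""
    out = []
    for s in seqs:
        merged = {**s.labels, **table.get(s.id, {})}
        out.append(LabeledSequence(id=s.id, sequence=s.sequence, labels=merged))
    return out


def chunk_starts(length: int, chunk_len: int, max_chunks: int) -> list[int]:
    """Start offsets of up to ``max_chunks`` non-overlapping equally spaced chunks.

    ``c = min(length // chunk_len, max_chunks)`` chunks are placed at
    ``start_i = floor(i * (length - chunk_len) / (c - 1))`` for c > 1, which
    spreads them approximately evenly over the genome while guaranteeing no
    overlap (consecutive starts differ by at least chunk_len).
    """
    q = length // chunk_len
    c = min(q, max_chunks)
    if c == 0:
        return []
    if c == 1:
        return [0]
    span = length - chunk_len
    return [i * span // (c - 1) for i in range(c)]


def chunk_genome(seq: LabeledSequence, spec: ChunkSpec) -> list[LabeledSequence]:
    """Split a genome into non-overlapping, approximately equally spaced chunks.

    Each chunk is exactly ``spec.chunk_len`` bp, inherits the parent labels,
    and is named ``{parent}_chunk{i}``. Genomes shorter than one chunk yield
    an empty list (with a log message).
    """
    starts = chunk_starts(len(seq), spec.chunk_len, spec.max_chunks)
    if not starts:
        logger.warning(
            "genome %s (%d bp) shorter than chunk_len=%d: no chunks",
            seq.id, len(seq), spec.chunk_len,
        )
        return []
    return [
        LabeledSequence(
            id=f"{seq.id}_chunk{i}",
            sequence=seq.sequence[start : start + spec.chunk_len],
            labels=dict(seq.labels),
        )
        for i, start in enumerate(starts)
    ]


def stitch_fragments(
    fragments: list[LabeledSequence], group_size: int
) -> list[LabeledSequence]:
    """Stitch short discontiguous fragments into longer composite sequences.

    Fragments are truncated to a multiple of ``group_size``, arranged
    row-wise into a matrix with ``group_size`` columns, the matrix is
    transposed, and each resulting row is concatenated. Fragment ``i`` thus
    lands in stitched sequence ``i mod group_size``, so every composite
    samples fragments spread across the whole genome rather than one
    contiguous region.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if not fragments:
        return []
    frag_len = len(fragments[0])
    if any(len(f) != frag_len for f in fragments):
        raise ValueError("all fragments must have equal length")
    n_rows = len(fragments) // group_size
    if n_rows == 0:
        # fewer fragments than one full group: transpose of a single partial row
        n_rows, usable = 1, fragments
    else:
        usable = fragments[: n_rows * group_size]
    n_cols = min(group_size, len(usable))
    parent = fragments[0].id.rsplit("_", 1)[0]
    stitched = []
    for col in range(n_cols):
        pieces = [usable[row * group_size + col].sequence
                  for row in range(n_rows)
                  if row * group_size + col < len(usable)]
        stitched.append(
            LabeledSequence(
                id=f"{parent}_stitch{col}",
                sequence="".join(pieces),
                labels=dict(fragments[0].labels),
            )
        )
    return stitched


def sample_fragments(
    seq: LabeledSequence, frag_len: int, n_fragments: int
) -> list[LabeledSequence]:
    """Extract up to ``n_fragments`` non-overlapping fragments of ``frag_len`` bp.

    Fragments are equally spaced across the genome (same placement rule as
    :func:`chunk_genome`); this models multiple short reads drawn from
    scattered genomic locations.
    """
    frags = chunk_genome(seq, ChunkSpec(chunk_len=frag_len, max_chunks=n_fragments))
    for i, f in enumerate(frags):
        f.id = f"{seq.id}_frag{i}"
    return frags
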