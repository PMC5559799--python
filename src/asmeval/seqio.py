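"""Sequence and alignment I/O for the assembly-evaluation pipeline.

Readers and writers for the plain-text formats the pipeline touches —
FASTA assemblies, FASTQ reads, a minimal SAM subset, and 12-column
tabular homology hit files (the BLAST ``outfmt 6`` dialect) — plus
Phred-threshold quality trimming of reads.

Parsing is deliberately fail-loud: malformed records raise with the
offending line or position rather than being silently skipped, so that
every downstream metric is computed from exactly the data on disk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Contig",
    "AssemblySet",
    "Read",
    "HitRecord",
    "AlignmentRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_hits_tabular",
    "write_hits_tabular",
    "read_sam_minimal",
    "quality_trim",
    "revcomp",
]

# Alphabet accepted in assembly FASTA after normalisation (U -> T, uppercase).
_DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence under evaluation."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be nonempty")
        if not self.seq:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


class AssemblySet:
    """An ordered, id-unique collection of contigs with a source label."""

    def __init__(self, label: str, contigs: Iterable[Contig] = ()):
        self.label = label
        self._contigs: list[Contig] = []
        self._index: dict[str, int] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._index:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        self._index[contig.id] = len(self._contigs)
        self._contigs.append(contig)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._contigs)

    def __len__(self) -> int:
        return len(self._contigs)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._index

    def __getitem__(self, contig_id: str) -> Contig:
        return self._contigs[self._index[contig_id]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssemblySet):
            return NotImplemented
        return self._contigs == other._contigs

    def __repr__(self) -> str:
        return f"AssemblySet({self.label!r}, {len(self)} contigs)"

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self._contigs)

    def lengths(self) -> list[int]:
        return [c.length for c in self._contigs]


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    seq: str
    quals: tuple[int, ...]
    mate: int = 1

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: {len(self.quals)} qualities for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular homology search result.

    Coordinates are 1-based inclusive as printed by the search tools.
    Nucleotide-query rows with qstart > qend (minus-strand matches) are
    normalised on input: the positions are swapped and ``strand`` set to
    ``'-'`` so downstream span arithmetic can assume qstart <= qend.
    """

    query: str
    subject: str
    pct_identity: float
    align_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query!r}->{self.subject!r}: negative evalue")
        if self.align_len < 1:
            raise ValueError(f"hit {self.query!r}->{self.subject!r}: align_len < 1")
        if self.qstart > self.qend:
            raise ValueError("qstart > qend after normalisation")

    @property
    def sspan(self) -> int:
        """Subject-side span in residues (send - sstart + 1)."""
        return abs(self.send - self.sstart) + 1

    @property
    def qspan(self) -> int:
        return self.qend - self.qstart + 1


@dataclass(frozen=True)
class AlignmentRecord:
    """A per-read placement distilled from one SAM alignment line."""

    read_id: str
    mate: int
    mapped: bool
    contig_id: str | None = None
    aligned_len: int = 0
    read_len: int = 0
    identity: float | None = None
    mate_contig_id: str | None = None

    def __post_init__(self) -> None:
        if self.mapped:
            if self.contig_id is None:
                raise ValueError(f"read {self.read_id!r}: mapped without a contig")
            if not (1 <= self.aligned_len <= self.read_len):
                raise ValueError(
                    f"read {self.read_id!r}: aligned_len {self.aligned_len} "
                    f"outside [1, {self.read_len}]"
                )
            if self.identity is not None and not (0.0 <= self.identity <= 1.0):
                raise ValueError(f"read {self.read_id!r}: identity out of [0,1]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, label: str | None = None) -> AssemblySet:
    """Read a FASTA file into an :class:`AssemblySet`.

    Sequences are uppercased, U is mapped to T and whitespace stripped.
    Record order is preserved. Duplicate ids, empty records and
    characters outside {A,C,G,T,N} are errors.
    """
    path = Path(path)
    assembly = AssemblySet(label if label is not None else path.stem)
    with open(path) as handle:
        for title, raw_seq in SimpleFastaParser(handle):
            rec_id = title.split()[0] if title.split() else ""
            if not rec_id:
                raise ValueError(f"{path}: record with empty header")
            seq = re.sub(r"\s+", "", raw_seq).upper().replace("U", "T")
            if not seq:
                raise ValueError(f"{path}: record {rec_id!r} has no sequence")
            bad = next(
                (i for i, ch in enumerate(seq) if ch not in _DNA_ALPHABET), None
            )
            if bad is not None:
                raise ValueError(
                    f"{path}: record {rec_id!r} has non-IUPAC-DNA character "
                    f"{seq[bad]!r} at position {bad + 1}"
                )
            if rec_id in assembly:
                raise ValueError(f"{path}: duplicate record id {rec_id!r}")
            assembly.add(Contig(rec_id, seq))
    return assembly


def write_fasta(
    assembly: AssemblySet | Iterable[Contig],
    path: str | Path,
    line_width: int = 70,
) -> None:
    """Write contigs in iteration order, wrapping sequence at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as handle:
        for contig in assembly:
            handle.write(f">{contig.id}\n")
            for i in range(0, len(contig.seq), line_width):
                handle.write(contig.seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

_MATE_SUFFIX = re.compile(r"/([12])$")


def read_fastq(path: str | Path) -> list[Read]:
    """Read FASTQ records; a trailing ``/1`` or ``/2`` on the id sets the mate."""
    reads: list[Read] = []
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            rec_id = title.split()[0]
            m = _MATE_SUFFIX.search(rec_id)
            mate = int(m.group(1)) if m else 1
            quals = tuple(ord(ch) - 33 for ch in qual)
            reads.append(Read(rec_id, seq.upper(), quals, mate))
    return reads


# ---------------------------------------------------------------------------
# Tabular hit files (12-column outfmt-6 dialect)
# ---------------------------------------------------------------------------


def read_hits_tabular(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table.

    Exactly twelve columns per line are required; extra or missing
    columns are an error naming the line. Minus-strand nucleotide
    queries (qstart > qend) are normalised by swapping the query
    coordinates and recording strand ``'-'``.
    """
    hits: list[HitRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                strand = "+"
                if qstart > qend:
                    qstart, qend = qend, qstart
                    strand = "-"
                hits.append(
                    HitRecord(
                        query=fields[0],
                        subject=fields[1],
                        pct_identity=float(fields[2]),
                        align_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        qstart=qstart,
                        qend=qend,
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits_tabular(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits back out in the 12-column dialect (strand re-encoded
    by swapping qstart/qend on minus-strand rows)."""
    with open(path, "w") as handle:
        for h in hits:
            qstart, qend = h.qstart, h.qend
            if h.strand == "-":
                qstart, qend = qend, qstart
            handle.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query,
                        h.subject,
                        f"{h.pct_identity:.2f}",
                        h.align_len,
                        h.mismatches,
                        h.gap_opens,
                        qstart,
                        qend,
                        h.sstart,
                        h.send,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM (minimal subset)
# ---------------------------------------------------------------------------

_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")
# CIGAR ops that consume the query and count as aligned columns
_ALIGNED_OPS = frozenset("M=X")
# CIGAR ops that consume the query (read length on the sequenced fragment)
_QUERY_OPS = frozenset("MIS=X")


def _parse_cigar(cigar: str, context: str) -> tuple[int, int]:
    """Return (aligned_len, read_len) from a CIGAR string."""
    if cigar == "*":
        raise ValueError(f"{context}: mapped record with '*' CIGAR")
    consumed = 0
    aligned = 0
    read_len = 0
    for m in _CIGAR_OP.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        consumed += len(m.group(0))
        if op in _ALIGNED_OPS:
            aligned += n
        if op in _QUERY_OPS:
            read_len += n
    if consumed != len(cigar):
        raise ValueError(f"{context}: malformed CIGAR {cigar!r}")
    return aligned, read_len


def read_sam_minimal(path: str | Path) -> list[AlignmentRecord]:
    """Parse a text SAM file into :class:`AlignmentRecord` objects.

    Only the fields the mapping metrics need are interpreted: FLAG
    (mapped bit 0x4 and mate bits 0x40/0x80), RNAME, CIGAR, RNEXT and
    the ``NM:i:`` edit-distance tag. Identity is the edit-distance
    proxy ``1 - NM / aligned_len``; a record lacking NM carries
    ``identity=None`` and is flagged for the caller to count separately.
    """
    records: list[AlignmentRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: fewer than 11 SAM columns")
            qname, flag_s, rname, _pos, _mapq, cigar, rnext = fields[:7]
            flag = int(flag_s)
            mate = 2 if flag & 0x80 else 1
            if flag & 0x4:
                records.append(AlignmentRecord(qname, mate, mapped=False))
                continue
            aligned_len, read_len = _parse_cigar(cigar, f"{path}:{lineno}")
            nm: int | None = None
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
                    break
            identity = None
            if nm is not None and aligned_len > 0:
                identity = max(0.0, 1.0 - nm / aligned_len)
            mate_contig = None
            if rnext == "=":
                mate_contig = rname
            elif rnext != "*":
                mate_contig = rnext
            records.append(
                AlignmentRecord(
                    read_id=qname,
                    mate=mate,
                    mapped=True,
                    contig_id=rname,
                    aligned_len=aligned_len,
                    read_len=read_len,
                    identity=identity,
                    mate_contig_id=mate_contig,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------


def quality_trim(read: Read, phred_cutoff: int = 20) -> Read:
    """Trim a read to its maximal-scoring segment (modified-Mott rule).

    Each base scores ``L - p_i`` where ``p_i = 10**(-q_i/10)`` is its
    error probability and ``L = 10**(-cutoff/10)`` the error limit; the
    retained segment maximises the running sum. A read whose best
    segment scores <= 0 (all bases below the cutoff) trims to empty.
    Ties are broken toward the earliest start, then the earliest end.
    """
    if phred_cutoff < 0:
        raise ValueError("phred_cutoff must be >= 0")
    if len(read) == 0:
        return read
    limit = 10.0 ** (-phred_cutoff / 10.0)
    scores = [limit - 10.0 ** (-q / 10.0) for q in read.quals]

    best_score = 0.0
    best_start = best_end = 0  # empty segment
    run_score = 0.0
    run_start = 0
    for i, s in enumerate(scores):
        if run_score <= 0.0:
            run_score = s
            run_start = i
        else:
            run_score += s
        if run_score > best_score:
            best_score = run_score
            best_start, best_end = run_start, i + 1
    if best_end == best_start:
        return replace(read, seq="", quals=())
    return replace(
        read,
        seq=read.seq[best_start:best_end],
        quals=read.quals[best_start:best_end],
    )
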