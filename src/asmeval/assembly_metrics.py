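"""Length-based and read-mapping quality metrics for an assembly.

Length statistics (N50/N90, mean/min/max, fraction >= 1 kb) summarise
contig size distribution; the mapping metrics measure how completely
the read set is explained by the assembly: the percentage of reads
mapped back to the transcripts (RMBT), the percentage mapped in proper
pairs (both mates on one contig) and the percentage in broken pairs
(mates on two different contigs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .seqio import AlignmentRecord, AssemblySet

logger = logging.getLogger(__name__)

__all__ = [
    "LengthReport",
    "MappingReport",
    "filter_contigs",
    "length_report",
    "accept_alignment",
    "mapping_report",
]


@dataclass(frozen=True)
class LengthReport:
    """Contig-length summary of one assembly."""

    n_contigs: int
    total_len: int
    mean_len: float
    min_len: int
    max_len: int
    n50: int
    n90: int
    pct_ge_1kb: float


@dataclass(frozen=True)
class MappingReport:
    """Read-mapping completeness percentages (over total reads).

    ``pct_mapped`` counts every read with an accepted placement;
    ``pct_in_pairs`` those whose mate is accepted on the same contig;
    ``pct_broken`` those whose mate is accepted on a different contig.
    Mapped singletons (mate rejected) contribute to ``pct_mapped`` only.
    """

    pct_mapped: float
    pct_in_pairs: float
    pct_broken: float
    n_reads: int = 0
    n_no_identity: int = 0


def filter_contigs(assembly: AssemblySet, min_len: int = 300) -> AssemblySet:
    """Drop contigs shorter than ``min_len`` bases, preserving order.

    The 300 bp default is the conventional floor below which short
    de Bruijn contigs are discarded before evaluation.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return AssemblySet(
        assembly.label, (c for c in assembly if c.length >= min_len)
    )


def _nx(sorted_desc: list[int], total: int, fraction: float) -> int:
    """Length of the contig at which descending cumulative length first
    reaches ``fraction`` of ``total``."""
    threshold = fraction * total
    cumulative = 0
    for length in sorted_desc:
        cumulative += length
        if cumulative >= threshold:
            return length
    return sorted_desc[-1]


def length_report(assembly: AssemblySet) -> LengthReport:
    """Compute the length statistics of a nonempty assembly.

    N50 (N90) is the contig length at which the cumulative length of
    contigs sorted in descending order first reaches >= 50% (90%) of
    total assembly bases. Mean length is reported to 0.01 bp.
    """
    lengths = assembly.lengths()
    if not lengths:
        raise ValueError("length_report: empty assembly")
    desc = sorted(lengths, reverse=True)
    total = sum(desc)
    return LengthReport(
        n_contigs=len(desc),
        total_len=total,
        mean_len=round(total / len(desc), 2),
        min_len=desc[-1],
        max_len=desc[0],
        n50=_nx(desc, total, 0.50),
        n90=_nx(desc, total, 0.90),
        pct_ge_1kb=round(100.0 * sum(1 for x in desc if x >= 1000) / len(desc), 2),
    )


def accept_alignment(
    record: AlignmentRecord,
    length_fraction: float = 0.75,
    similarity: float = 0.90,
) -> bool:
    """Apply the length-fraction/similarity acceptance rule to a mapped read.

    A placement is accepted iff aligned_len/read_len >= length_fraction
    and identity >= similarity (both comparisons inclusive). Records
    without a usable identity (missing NM tag) are rejected and logged.
    """
    if not record.mapped:
        raise ValueError("accept_alignment requires a mapped record")
    if not (0 < length_fraction <= 1) or not (0 < similarity <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    if record.identity is None:
        logger.warning(
            "read %s/%d: identity unknown (no NM tag); placement rejected",
            record.read_id,
            record.mate,
        )
        return False
    return (
        record.aligned_len / record.read_len >= length_fraction
        and record.identity >= similarity
    )


def mapping_report(
    alignments: list[AlignmentRecord],
    length_fraction: float = 0.75,
    similarity: float = 0.90,
) -> MappingReport:
    """Compute RMBT, in-pair and broken-pair percentages over total reads.

    Every read (mapped or not) enters the denominator. A read with
    several accepted placements counts once, at its best placement
    (highest identity, then longest alignment). Both mates of a read id
    must be present; a read id missing a mate is an error.
    """
    # best accepted placement per (read, mate); None = seen but not accepted
    best: dict[tuple[str, int], AlignmentRecord | None] = {}
    n_no_identity = 0
    for rec in alignments:
        key = (rec.read_id, rec.mate)
        best.setdefault(key, None)
        if not rec.mapped:
            continue
        if rec.identity is None:
            n_no_identity += 1
        if not accept_alignment(rec, length_fraction, similarity):
            continue
        incumbent = best[key]
        if incumbent is None or (rec.identity, rec.aligned_len) > (
            incumbent.identity,
            incumbent.aligned_len,
        ):
            best[key] = rec

    by_read: dict[str, set[int]] = {}
    for read_id, mate in best:
        by_read.setdefault(read_id, set()).add(mate)
    bad = sorted(rid for rid, mates in by_read.items() if mates != {1, 2})
    if bad:
        raise ValueError(
            f"reads without both mates present: {', '.join(bad[:10])}"
            + ("..." if len(bad) > 10 else "")
        )

    n_reads = 2 * len(by_read)
    n_mapped = n_in_pairs = n_broken = 0
    for read_id in by_read:
        m1 = best[(read_id, 1)]
        m2 = best[(read_id, 2)]
        for mine, other in ((m1, m2), (m2, m1)):
            if mine is None:
                continue
            n_mapped += 1
            if other is None:
                continue  # mapped singleton
            if mine.contig_id == other.contig_id:
                n_in_pairs += 1
            else:
                n_broken += 1

    if n_reads == 0:
        return MappingReport(0.0, 0.0, 0.0, 0, n_no_identity)
    return MappingReport(
        pct_mapped=round(100.0 * n_mapped / n_reads, 2),
        pct_in_pairs=round(100.0 * n_in_pairs / n_reads, 2),
        pct_broken=round(100.0 * n_broken / n_reads, 2),
        n_reads=n_reads,
        n_no_identity=n_no_identity,
    )
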