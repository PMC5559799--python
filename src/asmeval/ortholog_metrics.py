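"""Annotation-based assembly quality metrics.

Given homology hit tables against a related species' proteome (forward:
contig -> protein, reverse: protein -> contig), this module computes the
best-hit tables at an e-value cutoff, counts of unique proteins found,
reciprocal best hits (RBH, the operational ortholog call), the ortholog
hit ratio (OHR: fraction of the ortholog covered by the best hit, so an
OHR of 1 marks a full-length reconstruction) with its histogram, and
core-gene-set completeness (complete vs partial recovery of a set of
universally conserved proteins).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .seqio import HitRecord

__all__ = [
    "BestHitTable",
    "OHRRecord",
    "CompletenessReport",
    "best_hits",
    "unique_subject_count",
    "reciprocal_best_hits",
    "ortholog_hit_ratio",
    "ohr_distribution",
    "core_completeness",
]

DEFAULT_EVALUE_CUTOFF = 1e-5
FULL_LENGTH_OHR = 0.8


@dataclass(frozen=True)
class BestHitTable:
    """Per-query top hit at a fixed e-value cutoff.

    ``direction`` is 'forward' (contig -> protein) or 'reverse'
    (protein -> contig); entries map each query to its single best hit.
    """

    direction: str
    cutoff: float
    entries: Mapping[str, HitRecord]

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, query: str) -> bool:
        return query in self.entries

    def __getitem__(self, query: str) -> HitRecord:
        return self.entries[query]


@dataclass(frozen=True)
class OHRRecord:
    contig_id: str
    protein_id: str
    ohr: float
    is_full: bool


@dataclass(frozen=True)
class CompletenessReport:
    """Core-protein recovery: complete (single hit covering >= the
    completeness fraction of the protein) and partial (any hit; a
    superset of complete, following the core-gene-assessment convention)."""

    n_core: int
    n_complete: int
    n_partial: int
    pct_complete: float
    pct_partial: float


def _hit_sort_key(hit: HitRecord) -> tuple:
    # max bitscore, then min evalue, then longest subject span,
    # then lexicographically smallest subject: a total order, so the
    # result is invariant to input row order.
    return (-hit.bitscore, hit.evalue, -hit.sspan, hit.subject)


def best_hits(
    hits: Iterable[HitRecord],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    direction: str = "forward",
) -> BestHitTable:
    """Keep, per query, the top hit among those passing the e-value cutoff."""
    if evalue_cutoff <= 0:
        raise ValueError("evalue_cutoff must be > 0")
    entries: dict[str, HitRecord] = {}
    for hit in hits:
        if hit.evalue > evalue_cutoff:
            continue
        incumbent = entries.get(hit.query)
        if incumbent is None or _hit_sort_key(hit) < _hit_sort_key(incumbent):
            entries[hit.query] = hit
    return BestHitTable(direction, evalue_cutoff, entries)


def unique_subject_count(table: BestHitTable) -> int:
    """Number of distinct subjects across all best-hit entries."""
    return len({h.subject for h in table.entries.values()})


def reciprocal_best_hits(
    forward: BestHitTable, reverse: BestHitTable
) -> list[tuple[str, str]]:
    """Contig-protein pairs where each is the other's best hit.

    The result is a matching: each contig and each protein appears at
    most once. Pairs are returned sorted by contig id.
    """
    if forward.direction != "forward" or reverse.direction != "reverse":
        raise ValueError(
            "reciprocal_best_hits needs a forward and a reverse table, got "
            f"{forward.direction!r}/{reverse.direction!r}"
        )
    pairs = [
        (contig, hit.subject)
        for contig, hit in forward.entries.items()
        if hit.subject in reverse and reverse[hit.subject].subject == contig
    ]
    return sorted(pairs)


def ortholog_hit_ratio(
    rbh_pair: tuple[str, str],
    best_hit_entry: HitRecord,
    protein_len: int,
    full_threshold: float = FULL_LENGTH_OHR,
) -> OHRRecord:
    """OHR of one RBH pair: best-hit span on the ortholog over its length.

    The numerator is the subject span of the contig's best forward hit
    in amino acids (send - sstart + 1), so a hit covering the whole
    protein gives OHR 1.0 regardless of UTR sequence on the contig.
    """
    contig_id, protein_id = rbh_pair
    if protein_len <= 0:
        raise ValueError(f"protein {protein_id!r}: nonpositive length")
    if best_hit_entry.query != contig_id or best_hit_entry.subject != protein_id:
        raise ValueError("best_hit_entry does not belong to the RBH pair")
    ohr = best_hit_entry.sspan / protein_len
    return OHRRecord(contig_id, protein_id, ohr, is_full=ohr >= full_threshold)


def ohr_distribution(
    records: Iterable[OHRRecord],
    bin_width: float = 0.1,
    full_threshold: float = FULL_LENGTH_OHR,
) -> tuple[dict[int, int], int, float]:
    """Histogram of OHR values plus the full-length count and percent.

    Bins are right-open [k*w, (k+1)*w) except that values >= 1.0 all
    fall in the bin containing 1.0. Returns (histogram keyed by bin
    index, count with OHR >= full_threshold, percent of records full).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    last_bin = int(1.0 / bin_width - 1e-9)  # bin whose right edge is 1.0
    histogram: Counter[int] = Counter()
    n_full = 0
    n_total = 0
    for rec in records:
        n_total += 1
        k = int(rec.ohr / bin_width)
        histogram[min(k, last_bin)] += 1
        if rec.ohr >= full_threshold:
            n_full += 1
    pct_full = round(100.0 * n_full / n_total, 2) if n_total else 0.0
    return dict(histogram), n_full, pct_full


def core_completeness(
    hits_vs_core: Iterable[HitRecord],
    core_lengths: Mapping[str, int],
    complete_fraction: float = 0.70,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> CompletenessReport:
    """Classify each core protein as complete, partial or missing.

    A core protein is complete iff a single accepted hit's subject span
    covers >= ``complete_fraction`` of its length (inclusive at the
    boundary); partial iff it has any accepted hit. Percentages are over
    the size of the core set.
    """
    if not (0 < complete_fraction <= 1):
        raise ValueError("complete_fraction must lie in (0, 1]")
    complete: set[str] = set()
    partial: set[str] = set()
    for hit in hits_vs_core:
        if hit.evalue > evalue_cutoff:
            continue
        if hit.subject not in core_lengths:
            raise ValueError(
                f"hit subject {hit.subject!r} missing from core_lengths"
            )
        partial.add(hit.subject)
        if hit.sspan / core_lengths[hit.subject] >= complete_fraction:
            complete.add(hit.subject)
    n_core = len(core_lengths)
    if n_core == 0:
        raise ValueError("empty core set")
    return CompletenessReport(
        n_core=n_core,
        n_complete=len(complete),
        n_partial=len(partial),
        pct_complete=round(100.0 * len(complete) / n_core, 2),
        pct_partial=round(100.0 * len(partial) / n_core, 2),
    )
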