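"""Microsatellite (SSR) mining, primer design and virtual PCR.

Detects perfect di- to hexanucleotide tandem repeats with per-unit
minimum repeat counts (default: six repeats for dinucleotides, five for
tri- to hexanucleotides), groups motifs into canonical strand classes
(a motif paired with its reverse complement, e.g. GA/TC — rotational
variants such as AG/CT are counted as separate classes), designs
flanking PCR primer pairs with a simple GC/Tm rule system, screens the
pairs by exhaustive in-silico PCR (a single amplicon suggests a
single-locus marker), and tabulates summary statistics.

Coordinates are 0-based half-open in memory and 1-based inclusive in
TSV output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .seqio import AssemblySet, Contig, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "SSRLocus",
    "PrimerPair",
    "PrimerConstraints",
    "AmpliconSet",
    "find_ssrs",
    "canonical_class",
    "design_primers",
    "virtual_pcr",
    "ssr_summary",
]

#: minimum repeat count by motif length
DEFAULT_MIN_REPEATS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SSRLocus:
    """A maximal perfect tandem repeat of a primitive 2-6 bp motif."""

    contig_id: str
    start: int  # 0-based half-open
    end: int
    motif: str
    repeats: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.repeats * len(self.motif):
            raise ValueError("interval length inconsistent with motif x repeats")

    @property
    def unit_len(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 24
    min_gc: float = 40.0
    max_gc: float = 60.0
    min_tm: float = 50.0
    max_tm: float = 65.0
    max_tm_diff: float = 5.0
    min_product: int = 100
    max_product: int = 300


@dataclass(frozen=True)
class PrimerPair:
    """A flanking primer pair; the right primer is given 5'->3' on the
    minus strand (it anneals to the plus strand downstream of the locus)."""

    left: str
    right: str
    left_start: int  # 0-based start of the left primer on the contig
    right_end: int  # 0-based exclusive end of the right primer's plus-strand site
    tm_left: float
    tm_right: float
    gc_left: float
    gc_right: float
    expected_product: int


@dataclass(frozen=True)
class Amplicon:
    contig_id: str
    start: int
    end: int

    @property
    def product_len(self) -> int:
        return self.end - self.start


@dataclass
class AmpliconSet:
    pair: PrimerPair
    amplicons: list[Amplicon] = field(default_factory=list)

    @property
    def single_locus(self) -> bool:
        return len(self.amplicons) == 1


# ---------------------------------------------------------------------------
# SSR detection
# ---------------------------------------------------------------------------


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def find_ssrs(
    contig: Contig,
    min_repeats_by_unit: Mapping[int, int] | None = None,
) -> list[SSRLocus]:
    """All maximal perfect SSRs on a contig meeting the repeat thresholds.

    A locus is reported at its smallest primitive unit — an (AT)x8 run
    is a dinucleotide SSR, never a tetranucleotide ATAT one — and
    phase-shifted reports of the same run collapse to the leftmost
    start. Loci are returned sorted by (start, unit length).
    """
    thresholds = dict(min_repeats_by_unit or DEFAULT_MIN_REPEATS)
    seq = contig.seq
    n = len(seq)
    loci: list[SSRLocus] = []
    for k, min_rep in sorted(thresholds.items()):
        if not (2 <= k <= 6):
            raise ValueError("motif lengths must be 2-6")
        i = 0
        while i + k * min_rep <= n:
            motif = seq[i : i + k]
            if "N" in motif or not _is_primitive(motif):
                i += 1
                continue
            # extend the run: j is one past the last position matching k back
            j = i + k
            while j < n and seq[j] == seq[j - k]:
                j += 1
            repeats = (j - i) // k
            if repeats >= min_rep:
                loci.append(SSRLocus(contig.id, i, i + repeats * k, motif, repeats))
                # skip past this run so phase-shifted copies are not re-reported
                i = j - k + 1
            else:
                i += 1
    loci.sort(key=lambda l: (l.start, l.unit_len))
    return loci


def canonical_class(motif: str) -> str:
    """Strand-canonical class label: the lexicographically smaller of
    the motif and its reverse complement, written "X/Y". Rotations are
    not merged (GA/TC and AG/CT are distinct classes)."""
    if not (2 <= len(motif) <= 6) or not _is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not a primitive 2-6 bp motif")
    rc = revcomp(motif)
    smaller = min(motif, rc)
    return f"{smaller}/{revcomp(smaller)}"


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------


def _gc_pct(seq: str) -> float:
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def _wallace_tm(seq: str) -> float:
    """Salt-free approximation Tm = 64.9 + 41*(GC - 16.4)/len (deg C)."""
    gc = sum(1 for b in seq if b in "GC")
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def _primer_ok(seq: str, c: PrimerConstraints) -> bool:
    if "N" in seq:
        return False
    gc = _gc_pct(seq)
    tm = _wallace_tm(seq)
    return c.min_gc <= gc <= c.max_gc and c.min_tm <= tm <= c.max_tm


def design_primers(
    contig: Contig,
    locus: SSRLocus,
    constraints: PrimerConstraints | None = None,
) -> PrimerPair | None:
    """Design a flanking primer pair for an SSR locus, or return None.

    Candidate windows are scanned in the flanks from the locus outward;
    the first pair meeting the length, GC, Tm, Tm-difference and
    product-size constraints is returned. Loci too close to a contig
    end have insufficient flanking sequence and yield None.
    """
    c = constraints or PrimerConstraints()
    if locus.contig_id != contig.id or locus.end > contig.length:
        raise ValueError(f"locus is not on contig {contig.id!r}")
    seq = contig.seq

    def left_candidates():
        # windows ending at or before locus.start, nearest first
        for end in range(locus.start, c.min_len - 1, -1):
            for ln in range(c.min_len, c.max_len + 1):
                start = end - ln
                if start < 0:
                    break
                window = seq[start:end]
                if _primer_ok(window, c):
                    yield start, end, window

    # plus-strand binding sites starting at or after locus.end, nearest
    # first; sites beyond locus.start + max_product can never give a
    # product within range for any admissible left primer
    right_cands: list[tuple[int, int, str]] = []
    last_start = min(contig.length - c.min_len, locus.start + c.max_product)
    for start in range(locus.end, last_start + 1):
        for ln in range(c.min_len, c.max_len + 1):
            end = start + ln
            if end > contig.length:
                break
            site = seq[start:end]
            if _primer_ok(site, c):
                right_cands.append((start, end, site))

    for lstart, lend, lseq in left_candidates():
        for rstart, rend, rsite in right_cands:
            if rstart + c.min_len - lstart > c.max_product:
                break
            product = rend - lstart
            if not (c.min_product <= product <= c.max_product):
                continue
            tm_l, tm_r = _wallace_tm(lseq), _wallace_tm(rsite)
            if abs(tm_l - tm_r) > c.max_tm_diff:
                continue
            return PrimerPair(
                left=lseq,
                right=revcomp(rsite),
                left_start=lstart,
                right_end=rend,
                tm_left=round(tm_l, 2),
                tm_right=round(tm_r, 2),
                gc_left=round(_gc_pct(lseq), 2),
                gc_right=round(_gc_pct(rsite), 2),
                expected_product=product,
            )
    return None


# ---------------------------------------------------------------------------
# Virtual PCR
# ---------------------------------------------------------------------------


def _binding_sites(template: str, probe: str, max_mismatches: int, anchor_3prime_index: int) -> list[int]:
    """Start positions where ``probe`` matches ``template`` with at most
    ``max_mismatches`` mismatches and an exact match at the probe index
    corresponding to its 3' terminal base."""
    sites = []
    lp = len(probe)
    for i in range(len(template) - lp + 1):
        window = template[i : i + lp]
        if window[anchor_3prime_index] != probe[anchor_3prime_index]:
            continue
        mismatches = sum(1 for x, y in zip(window, probe) if x != y)
        if mismatches <= max_mismatches:
            sites.append(i)
    return sites


def virtual_pcr(
    pair: PrimerPair,
    assembly: AssemblySet,
    max_mismatches: int = 0,
    max_product: int = 3000,
) -> AmpliconSet:
    """Exhaustive in-silico PCR of a primer pair against an assembly.

    An amplicon arises wherever the left primer binds a template strand
    and the right primer's plus-strand site lies downstream on the same
    strand within ``max_product`` bases; each binding tolerates at most
    ``max_mismatches`` mismatches with an exact 3'-terminal base. Both
    strands of every contig are searched; amplicons are reported on
    plus-strand coordinates and de-duplicated.
    """
    if max_mismatches < 0 or max_product < 1:
        raise ValueError("invalid virtual PCR parameters")
    right_site = revcomp(pair.right)  # the right primer's plus-strand footprint
    found: set[Amplicon] = set()
    for contig in assembly:
        for strand_seq, minus in ((contig.seq, False), (revcomp(contig.seq), True)):
            # left primer 3' end is its last base; right primer 3' end
            # corresponds to the first base of its plus-strand footprint
            lefts = _binding_sites(strand_seq, pair.left, max_mismatches, len(pair.left) - 1)
            rights = _binding_sites(strand_seq, right_site, max_mismatches, 0)
            for i in lefts:
                for j in rights:
                    if j < i:
                        continue
                    end = j + len(right_site)
                    if end - i > max_product:
                        continue
                    if minus:
                        start_p = contig.length - end
                        end_p = contig.length - i
                    else:
                        start_p, end_p = i, end
                    found.add(Amplicon(contig.id, start_p, end_p))
    return AmpliconSet(pair, sorted(found, key=lambda a: (a.contig_id, a.start, a.end)))


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSRSummary:
    n_sequences: int
    total_ssrs: int
    n_containing: int
    n_multi: int
    by_unit: dict[int, int]
    pct_by_unit: dict[int, float]
    class_counts: dict[str, int]
    frequency_kb: float | None  # assembly kb per SSR


def ssr_summary(loci: Iterable[SSRLocus], assembly: AssemblySet) -> SSRSummary:
    """Tabulate SSR statistics for an assembly.

    Reports the totals, the number of sequences containing one or more
    than one SSR, counts and percentages by unit length (percent of
    total SSRs, to 0.1), the canonical motif-class frequency table and
    the SSR frequency (assembly kilobases per SSR).
    """
    loci = list(loci)
    per_contig: dict[str, int] = {}
    by_unit: dict[int, int] = {k: 0 for k in range(2, 7)}
    class_counts: dict[str, int] = {}
    for locus in loci:
        per_contig[locus.contig_id] = per_contig.get(locus.contig_id, 0) + 1
        by_unit[locus.unit_len] += 1
        cls = canonical_class(locus.motif)
        class_counts[cls] = class_counts.get(cls, 0) + 1
    total = len(loci)
    pct_by_unit = {
        k: (round(100.0 * v / total, 1) if total else 0.0) for k, v in by_unit.items()
    }
    frequency_kb = (
        round(assembly.total_length / total / 1000.0, 2) if total else None
    )
    return SSRSummary(
        n_sequences=len(assembly),
        total_ssrs=total,
        n_containing=len(per_contig),
        n_multi=sum(1 for v in per_contig.values() if v > 1),
        by_unit=by_unit,
        pct_by_unit=pct_by_unit,
        class_counts=dict(sorted(class_counts.items())),
        frequency_kb=frequency_kb,
    )
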