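"""Seed-deterministic synthetic ground truth for every pipeline stage.

The evaluation metrics in this package are exercised against data whose
truth is known by construction: a reference transcriptome with explicit
UTR/CDS structure and its translated proteome; candidate assemblies
derived from it with controlled fragmentation, duplication,
reverse-complementation and chimerism (recorded in a provenance truth
table); paired-read alignment records with exact unmapped and
broken-pair fractions; SSR loci planted at known coordinates with
guaranteed maximality; homology hit tables computed arithmetically from
provenance rather than by running an aligner; and qRT-PCR Ct tables
generated from known efficiencies and true expression ratios.

All generators are pure functions of their arguments: the same seed
yields byte-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .seqio import AlignmentRecord, AssemblySet, Contig, HitRecord, revcomp
from .ssr_markers import find_ssrs
from .stress_expression import CT_COLUMNS, CtTable

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceGene",
    "ContigProvenance",
    "TruthTable",
    "SSRTruth",
    "generate_reference",
    "corrupt_assembly",
    "plant_ssrs",
    "simulate_alignments",
    "alignments_to_sam",
    "hits_from_truth",
    "simulate_ct_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass(frozen=True)
class ReferenceGene:
    """A ground-truth gene: transcript = utr5 + cds + utr3, with the
    protein equal to the standard-code translation of the CDS."""

    id: str
    utr5: str
    cds: str
    utr3: str
    protein: str

    @property
    def transcript(self) -> str:
        return self.utr5 + self.cds + self.utr3

    @property
    def cds_interval(self) -> tuple[int, int]:
        """0-based half-open CDS interval on the transcript."""
        return len(self.utr5), len(self.utr5) + len(self.cds)


@dataclass(frozen=True)
class ContigProvenance:
    """Where one derived contig came from."""

    contig_id: str
    gene_id: str
    interval: tuple[int, int]  # 0-based half-open on the source transcript
    strand: str  # '+' or '-'
    is_chimera: bool = False
    second_gene_id: str | None = None
    second_interval: tuple[int, int] | None = None
    duplicate_of: str | None = None


class TruthTable:
    """Per-contig provenance records, addressable by contig id."""

    def __init__(self, records: Iterable[ContigProvenance] = ()):
        self.records: list[ContigProvenance] = list(records)
        self._by_contig = {r.contig_id: r for r in self.records}
        if len(self._by_contig) != len(self.records):
            raise ValueError("duplicate contig id in truth table")

    def add(self, record: ContigProvenance) -> None:
        if record.contig_id in self._by_contig:
            raise ValueError(f"duplicate contig id {record.contig_id!r}")
        self.records.append(record)
        self._by_contig[record.contig_id] = record

    def __getitem__(self, contig_id: str) -> ContigProvenance:
        return self._by_contig[contig_id]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SSRTruth:
    contig_id: str
    start: int
    end: int
    motif: str
    repeats: int


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Reference transcriptome + proteome
# ---------------------------------------------------------------------------


def generate_reference(
    n_genes: int,
    cds_len_range: tuple[int, int] = (300, 1200),
    utr_len_range: tuple[int, int] = (50, 250),
    seed: int = 0,
) -> list[ReferenceGene]:
    """Generate reference genes with ATG...stop CDSs free of internal
    stops, uniform-random UTRs, and translated proteins."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = cds_len_range
    # admissible CDS lengths: multiples of 3, >= 9 (start + 1 codon + stop)
    lengths = [l for l in range(max(lo, 9), hi + 1) if l % 3 == 0]
    if not lengths:
        raise ValueError(
            f"cds_len_range {cds_len_range} admits no multiple of 3 >= 9"
        )
    ulo, uhi = utr_len_range
    if not (0 <= ulo <= uhi):
        raise ValueError(f"invalid utr_len_range {utr_len_range}")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = []
    for i in range(n_genes):
        cds_len = int(rng.choice(lengths))
        n_mid = cds_len // 3 - 2
        mid = "".join(_CODONS[k] for k in rng.integers(0, len(_CODONS), size=n_mid))
        cds = "ATG" + mid + _STOPS[int(rng.integers(0, 3))]
        utr5 = _random_dna(rng, int(rng.integers(ulo, uhi + 1)))
        utr3 = _random_dna(rng, int(rng.integers(ulo, uhi + 1)))
        protein = str(Seq(cds[:-3]).translate())
        genes.append(ReferenceGene(f"gene{i + 1:0{width}d}", utr5, cds, utr3, protein))
    return genes


def reference_transcripts(genes: Sequence[ReferenceGene], label: str = "reference") -> AssemblySet:
    """Full transcripts of the reference genes as an assembly."""
    return AssemblySet(label, (Contig(g.id, g.transcript) for g in genes))


# ---------------------------------------------------------------------------
# Corrupted candidate assemblies
# ---------------------------------------------------------------------------


def corrupt_assembly(
    reference: Sequence[ReferenceGene],
    fragmentation: float = 1.0,
    duplication_rate: float = 0.0,
    revcomp_rate: float = 0.0,
    chimera_rate: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> tuple[AssemblySet, TruthTable]:
    """Derive an assembly of controlled quality from the reference.

    One contig is derived per gene: a contiguous substring retaining a
    ``fragmentation`` fraction of the full transcript, at a random
    position, reverse-complemented with probability ``revcomp_rate``.
    With probability ``chimera_rate`` the contig is instead a chimeric
    concatenation of fragments from two genes. Each contig is then
    duplicated (an exact copy) with probability ``duplication_rate``.
    Every output is recorded in the returned truth table.
    """
    if not (0 < fragmentation <= 1):
        raise ValueError("fragmentation must lie in (0, 1]")
    for name, rate in (
        ("duplication_rate", duplication_rate),
        ("revcomp_rate", revcomp_rate),
        ("chimera_rate", chimera_rate),
    ):
        if not (0 <= rate <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    assembly = AssemblySet(label)
    truth = TruthTable()

    def fragment(gene: ReferenceGene, frac: float) -> tuple[str, tuple[int, int]]:
        t = gene.transcript
        flen = max(30, round(frac * len(t)))
        flen = min(flen, len(t))
        start = int(rng.integers(0, len(t) - flen + 1))
        return t[start : start + flen], (start, start + flen)

    counter = 0
    for idx, gene in enumerate(reference):
        counter += 1
        cid = f"{label}_c{counter}"
        if chimera_rate > 0 and rng.random() < chimera_rate and len(reference) > 1:
            other = reference[(idx + 1 + int(rng.integers(0, len(reference) - 1))) % len(reference)]
            seq_a, iv_a = fragment(gene, fragmentation / 2)
            seq_b, iv_b = fragment(other, fragmentation / 2)
            seq = seq_a + seq_b
            prov = ContigProvenance(
                cid, gene.id, iv_a, "+", is_chimera=True,
                second_gene_id=other.id, second_interval=iv_b,
            )
        else:
            seq, interval = fragment(gene, fragmentation)
            strand = "+"
            if revcomp_rate > 0 and rng.random() < revcomp_rate:
                seq = revcomp(seq)
                strand = "-"
            prov = ContigProvenance(cid, gene.id, interval, strand)
        assembly.add(Contig(cid, seq))
        truth.add(prov)
        if duplication_rate > 0 and rng.random() < duplication_rate:
            counter += 1
            dup_id = f"{label}_c{counter}"
            assembly.add(Contig(dup_id, seq))
            truth.add(
                ContigProvenance(
                    dup_id, prov.gene_id, prov.interval, prov.strand,
                    is_chimera=prov.is_chimera,
                    second_gene_id=prov.second_gene_id,
                    second_interval=prov.second_interval,
                    duplicate_of=cid,
                )
            )
    return assembly, truth


# ---------------------------------------------------------------------------
# Planted SSR loci
# ---------------------------------------------------------------------------


def plant_ssrs(
    assembly: AssemblySet,
    motif_pool: Sequence[str] = ("AG", "GA", "AT", "ATG", "AAG", "AAAT", "AAAAG", "AAAAAG"),
    repeats_range: tuple[int, int] = (6, 10),
    per_contig_rate: float = 1.0,
    seed: int = 0,
    min_repeats_by_unit: Mapping[int, int] | None = None,
) -> tuple[AssemblySet, list[SSRTruth]]:
    """Plant one perfect SSR locus per selected contig, at a known
    position, and scrub accidental SSRs so a scan recovers exactly the
    planted truth.

    Maximality of each planted locus is guaranteed by forcing the base
    on each side to differ from the motif base that would extend the
    repeat. Contigs too short to host a locus with flanks are skipped
    with a log message. Any qualifying repeat that arises elsewhere by
    chance is broken by a single-base change away from the planted
    interval, so the returned truth is the complete set of loci at the
    detection thresholds.
    """
    for motif in motif_pool:
        if not (2 <= len(motif) <= 6):
            raise ValueError(f"motif {motif!r} outside length 2-6")
        from .ssr_markers import _is_primitive

        if not _is_primitive(motif):
            raise ValueError(f"motif {motif!r} is not primitive")
    rng = np.random.default_rng(seed)
    out = AssemblySet(f"{assembly.label}.ssr")
    truths: list[SSRTruth] = []
    for contig in assembly:
        seq = contig.seq
        planted: SSRTruth | None = None
        if rng.random() < per_contig_rate:
            motif = str(motif_pool[int(rng.integers(0, len(motif_pool)))])
            reps = int(rng.integers(repeats_range[0], repeats_range[1] + 1))
            block = motif * reps
            if len(seq) < len(block) + 2:
                logger.warning(
                    "contig %s too short (%d bp) to host (%s)x%d; skipped",
                    contig.id, len(seq), motif, reps,
                )
            else:
                start = int(rng.integers(1, len(seq) - len(block)))
                end = start + len(block)
                left = _differing_base(rng, motif[-1])
                right = _differing_base(rng, motif[0])
                seq = seq[: start - 1] + left + block + right + seq[end + 1 :]
                planted = SSRTruth(contig.id, start, end, motif, reps)
        seq = _scrub_accidental_ssrs(
            Contig(contig.id, seq), planted, min_repeats_by_unit, rng
        )
        out.add(Contig(contig.id, seq))
        if planted is not None:
            truths.append(planted)
    return out, truths


def _differing_base(rng: np.random.Generator, avoid: str) -> str:
    choices = [b for b in "ACGT" if b != avoid]
    return choices[int(rng.integers(0, len(choices)))]


def _scrub_accidental_ssrs(
    contig: Contig,
    planted: SSRTruth | None,
    min_repeats_by_unit: Mapping[int, int] | None,
    rng: np.random.Generator,
) -> str:
    """Break any detectable SSR other than the planted one by mutating a
    base near the run's centre, keeping clear of the planted interval
    and its maximality flanks."""
    seq = contig.seq
    keep = (planted.start - 1, planted.end + 1) if planted else None
    for _ in range(20):  # convergence is fast; bound the loop defensively
        extras = [
            l
            for l in find_ssrs(Contig(contig.id, seq), min_repeats_by_unit)
            if keep is None
            or not (l.start == planted.start and l.end == planted.end and l.motif == planted.motif)
        ]
        if not extras:
            return seq
        for locus in extras:
            pos = (locus.start + locus.end) // 2
            if keep and keep[0] <= pos <= keep[1]:
                pos = locus.start  # fall back to the run's first base
                if keep[0] <= pos <= keep[1]:
                    continue
            seq = seq[:pos] + _differing_base(rng, seq[pos]) + seq[pos + 1 :]
    raise RuntimeError(f"could not scrub accidental SSRs on {contig.id!r}")


# ---------------------------------------------------------------------------
# Simulated read alignments
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def simulate_alignments(
    assembly: AssemblySet,
    n_pairs: int,
    unmapped_frac: float = 0.0,
    broken_frac: float = 0.0,
    read_len: int = 100,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Paired-read placements with exact unmapped and broken fractions.

    Exactly ``round(n_pairs * unmapped_frac)`` pairs are fully unmapped
    and ``round(n_pairs * broken_frac)`` pairs have their mates on two
    different contigs (fractions converted to whole pairs by
    round-half-away-from-zero); the remainder are proper pairs on one
    contig. Every mapped record is fully aligned at identity 1.0, so it
    passes the length-fraction/similarity acceptance rule by
    construction.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    if unmapped_frac + broken_frac > 1 + 1e-12:
        raise ValueError("unmapped_frac + broken_frac must be <= 1")
    contig_ids = [c.id for c in assembly]
    n_unmapped = _round_half_away(n_pairs * unmapped_frac)
    n_broken = _round_half_away(n_pairs * broken_frac)
    if n_broken > 0 and len(contig_ids) < 2:
        raise ValueError("broken pairs require an assembly with >= 2 contigs")
    if n_broken + n_unmapped > n_pairs:
        raise ValueError("rounded unmapped + broken pairs exceed n_pairs")
    if n_pairs - n_unmapped > 0 and not contig_ids:
        raise ValueError("mapped pairs require a nonempty assembly")
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []

    def mapped(read_id: str, mate: int, contig: str, mate_contig: str) -> AlignmentRecord:
        return AlignmentRecord(
            read_id=read_id, mate=mate, mapped=True, contig_id=contig,
            aligned_len=read_len, read_len=read_len, identity=1.0,
            mate_contig_id=mate_contig,
        )

    pair_no = 0
    for _ in range(n_unmapped):
        pair_no += 1
        rid = f"pair{pair_no}"
        records.append(AlignmentRecord(rid, 1, mapped=False))
        records.append(AlignmentRecord(rid, 2, mapped=False))
    for _ in range(n_broken):
        pair_no += 1
        rid = f"pair{pair_no}"
        i, j = rng.choice(len(contig_ids), size=2, replace=False)
        c1, c2 = contig_ids[int(i)], contig_ids[int(j)]
        records.append(mapped(rid, 1, c1, c2))
        records.append(mapped(rid, 2, c2, c1))
    for _ in range(n_pairs - n_unmapped - n_broken):
        pair_no += 1
        rid = f"pair{pair_no}"
        c = contig_ids[int(rng.integers(0, len(contig_ids)))]
        records.append(mapped(rid, 1, c, c))
        records.append(mapped(rid, 2, c, c))
    return records


def alignments_to_sam(
    records: Sequence[AlignmentRecord], assembly: AssemblySet, path: str | Path
) -> None:
    """Write alignment records as a minimal text SAM file (FLAG, RNAME,
    CIGAR, RNEXT and NM populated; positions nominal)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig in assembly:
            fh.write(f"@SQ\tSN:{contig.id}\tLN:{contig.length}\n")
        for rec in records:
            flag = 0x1 | (0x40 if rec.mate == 1 else 0x80)
            if not rec.mapped:
                flag |= 0x4 | 0x8
                fh.write(f"{rec.read_id}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
                continue
            nm = 0
            if rec.identity is not None:
                nm = round((1.0 - rec.identity) * rec.aligned_len)
            rnext = "="
            if rec.mate_contig_id is not None and rec.mate_contig_id != rec.contig_id:
                rnext = rec.mate_contig_id
            cigar = f"{rec.aligned_len}M"
            if rec.read_len > rec.aligned_len:
                cigar += f"{rec.read_len - rec.aligned_len}S"
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.contig_id}\t1\t60\t{cigar}\t"
                f"{rnext}\t0\t0\t*\t*\tNM:i:{nm}\n"
            )


# ---------------------------------------------------------------------------
# Hit tables from provenance
# ---------------------------------------------------------------------------


def _codon_span(
    interval: tuple[int, int], cds_start: int, cds_end: int
) -> tuple[int, int] | None:
    """Protein positions (1-based inclusive) whose codons lie fully
    inside the part of the CDS covered by ``interval``; None if fewer
    than one full codon is covered."""
    lo = max(interval[0], cds_start)
    hi = min(interval[1], cds_end)
    if hi <= lo:
        return None
    first = math.ceil((lo - cds_start) / 3) + 1
    last = (hi - cds_start) // 3
    if last < first:
        return None
    return first, last


def hits_from_truth(
    assembly: AssemblySet,
    reference: Sequence[ReferenceGene],
    truth: TruthTable,
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Forward (contig -> protein) and reverse (protein -> contig) hit
    tables derived arithmetically from provenance.

    Each contig hits the protein(s) of its source gene(s) over the
    protein interval its fragment covers; no alignment is performed.
    E-values decrease monotonically with covered length (1e-5 *
    10**-span_aa, floored at 1e-180) and bitscores are proportional to
    it, so longer fragments always win best-hit comparisons. Chimeric
    contigs hit both source proteins.
    """
    genes = {g.id: g for g in reference}
    forward: list[HitRecord] = []
    reverse: list[HitRecord] = []

    def emit(contig: Contig, gene_id: str, interval: tuple[int, int], offset: int) -> None:
        gene = genes[gene_id]
        cds_start, cds_end = gene.cds_interval
        # protein region excluding the stop codon
        span = _codon_span(interval, cds_start, cds_end - 3)
        if span is None:
            return
        sstart, send = span
        span_aa = send - sstart + 1
        # contig coordinates of the covered codons (1-based)
        qstart = (cds_start + (sstart - 1) * 3) - interval[0] + 1 + offset
        qend = (cds_start + send * 3) - interval[0] + offset
        evalue = max(1e-180, 1e-5 * 10.0 ** (-span_aa))
        bitscore = round(2.0 * span_aa, 1)
        forward.append(
            HitRecord(
                query=contig.id, subject=gene_id, pct_identity=100.0,
                align_len=span_aa, mismatches=0, gap_opens=0,
                qstart=qstart, qend=qend, sstart=sstart, send=send,
                evalue=evalue, bitscore=bitscore,
            )
        )
        reverse.append(
            HitRecord(
                query=gene_id, subject=contig.id, pct_identity=100.0,
                align_len=span_aa, mismatches=0, gap_opens=0,
                qstart=sstart, qend=send, sstart=qstart, send=qend,
                evalue=evalue, bitscore=bitscore,
            )
        )

    for contig in assembly:
        prov = truth[contig.id]
        emit(contig, prov.gene_id, prov.interval, offset=0)
        if prov.is_chimera and prov.second_gene_id is not None:
            offset = prov.interval[1] - prov.interval[0]
            emit(contig, prov.second_gene_id, prov.second_interval, offset=offset)
    return forward, reverse


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    genes: Sequence[str],
    true_ratios: Mapping[str, float],
    efficiencies: Mapping[str, float],
    ref_gene: str,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    timepoint: object = "t1",
    base_ct: float = 25.0,
) -> CtTable:
    """Ct table generated from known true expression ratios.

    Control expression is 1 for every gene and treated expression is
    the gene's true ratio; Ct = base - log_E(expression) + N(0, sd), so
    with zero noise the Pfaffl pipeline recovers the ratios exactly.
    The reference gene must be present with a true ratio of 1.
    """
    if ref_gene not in genes:
        raise ValueError(f"reference gene {ref_gene!r} missing from genes")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        eff = efficiencies.get(gene, 2.0)
        if not (1.0 < eff <= 2.0):
            raise ValueError(f"gene {gene!r}: efficiency {eff} outside (1, 2]")
        ratio = 1.0 if gene == ref_gene else float(true_ratios.get(gene, 1.0))
        for condition, expr in (("control", 1.0), ("treated", ratio)):
            ct_true = base_ct - math.log(expr, eff)
            for rep in range(1, n_replicates + 1):
                ct = ct_true + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((gene, condition, timepoint, rep, ct))
    data = pd.DataFrame(rows, columns=CT_COLUMNS)
    return CtTable(data, {g: float(efficiencies.get(g, 2.0)) for g in genes})
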