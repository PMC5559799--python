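"""SSR detection, motif classes, primer design and virtual PCR."""

import re

import pytest

from asmeval import (
    AssemblySet,
    Contig,
    PrimerConstraints,
    canonical_class,
    design_primers,
    find_ssrs,
    revcomp,
    ssr_summary,
    virtual_pcr,
)
from asmeval.ssr_markers import DEFAULT_MIN_REPEATS, SSRLocus, _is_primitive

from conftest import random_dna


def contig(seq, cid="c1"):
    return Contig(cid, seq)


# ---------------------------------------------------------------------------
# find_ssrs
# ---------------------------------------------------------------------------


def test_dinucleotide_threshold_six():
    host = "CCTTCC" + "AG" * 6 + "TTCCTT"
    (locus,) = find_ssrs(contig(host))
    assert (locus.start, locus.end, locus.motif, locus.repeats) == (6, 18, "AG", 6)
    none = find_ssrs(contig("CCTTCC" + "AG" * 5 + "TTCCTT"))
    assert none == []


def test_trinucleotide_threshold_five():
    (locus,) = find_ssrs(contig("CC" + "ATG" * 5 + "CC"))
    assert (locus.motif, locus.repeats, locus.unit_len) == ("ATG", 5, 3)
    assert find_ssrs(contig("CC" + "ATG" * 4 + "CC")) == []


def test_composite_motif_reported_at_smallest_unit():
    # an (AT)x8 run is dinucleotide, never tetranucleotide ATAT
    loci = find_ssrs(contig("GCC" + "AT" * 8 + "GCC"))
    assert len(loci) == 1 and loci[0].unit_len == 2 and loci[0].repeats == 8


def test_phase_shifted_reports_collapse_to_leftmost():
    # 13-base AGAGAGAGAGAGA run: one locus starting at the A
    loci = find_ssrs(contig("CC" + "AG" * 6 + "A" + "CC"))
    assert len(loci) == 1
    assert (loci[0].start, loci[0].repeats) == (2, 6)


def regex_ssr_oracle(seq, thresholds=DEFAULT_MIN_REPEATS):
    """Regex enumeration of every maximal primitive tandem repeat."""
    records = []
    for k, min_rep in thresholds.items():
        found = []
        for m in re.finditer(rf"(?=((.{{{k}}})\2{{{min_rep - 1},}}))", seq):
            run, motif = m.group(1), m.group(2)
            i = m.start()
            if "N" in motif or not _is_primitive(motif):
                continue
            if i >= k and seq[i - k : i] == motif:
                continue  # not leftmost: a full unit precedes
            found.append((i, i + len(run), motif, len(run) // k))
        # collapse same-k records sharing >= k positions (phases of one run)
        found.sort()
        kept = []
        for rec in found:
            if kept and rec[0] < kept[-1][1] - k + 1:
                continue
            kept.append(rec)
        records.extend((s, e, mo, r, k) for s, e, mo, r in kept)
    return sorted(records)


def test_find_ssrs_equals_regex_oracle_on_random_sequences(rng):
    for i in range(100):
        seq = random_dna(rng, 2000)
        got = sorted(
            (l.start, l.end, l.motif, l.repeats, l.unit_len)
            for l in find_ssrs(contig(seq))
        )
        assert got == regex_ssr_oracle(seq), f"mismatch on sequence {i}"


def test_strand_covariance_of_detection(rng):
    for _ in range(20):
        seq = (
            random_dna(rng, 100) + "TTA" * 6 + random_dna(rng, 100)
            + "CA" * 7 + random_dna(rng, 100)
        )
        fwd = find_ssrs(contig(seq))
        rev = find_ssrs(contig(revcomp(seq)))
        n = len(seq)
        mirrored = sorted((n - l.end, n - l.start, l.unit_len, l.repeats) for l in fwd)
        observed = sorted((l.start, l.end, l.unit_len, l.repeats) for l in rev)
        assert len(observed) == len(mirrored)
        for (s, e, k, r), (ms, me, mk, mr) in zip(observed, mirrored):
            # the mirrored run may be phase-shifted by a partial unit
            assert (k, r) == (mk, mr)
            assert abs(s - ms) < k and abs(e - me) < k


# ---------------------------------------------------------------------------
# canonical_class
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "motif,expected",
    [
        ("GA", "GA/TC"),
        ("TC", "GA/TC"),
        ("AG", "AG/CT"),  # rotation of GA, but a distinct class
        ("CT", "AG/CT"),
        ("AT", "AT/AT"),  # self-reverse-complement
        ("AAG", "AAG/CTT"),
    ],
)
def test_canonical_class_pairs_strands_not_rotations(motif, expected):
    assert canonical_class(motif) == expected


def test_canonical_class_is_strand_invariant_and_idempotent(rng):
    for _ in range(50):
        k = int(rng.integers(2, 7))
        motif = random_dna(rng, k)
        if not _is_primitive(motif):
            continue
        cls = canonical_class(motif)
        assert canonical_class(revcomp(motif)) == cls
        left = cls.split("/")[0]
        assert canonical_class(left) == cls


# ---------------------------------------------------------------------------
# design_primers
# ---------------------------------------------------------------------------


def balanced_flank(rng, n):
    """Random DNA near 50% GC so primer windows exist."""
    pairs = ["AC", "GT", "TG", "CA", "AG", "CT"]
    s = "".join(pairs[int(rng.integers(0, len(pairs)))] for _ in range((n + 1) // 2))
    return s[:n]


def test_locus_near_contig_end_has_insufficient_flanks(rng):
    seq = "AT" * 5 + "AG" * 6 + balanced_flank(rng, 200)
    c = contig(seq)
    (locus,) = [l for l in find_ssrs(c) if l.motif == "AG"]
    assert design_primers(c, locus) is None


def test_constructed_feasible_locus_yields_valid_pair(rng):
    seq = balanced_flank(rng, 120) + "AG" * 6 + balanced_flank(rng, 120)
    c = contig(seq)
    (locus,) = find_ssrs(c)
    pair = design_primers(c, locus)
    assert pair is not None
    assert 100 <= pair.expected_product <= 300
    # the product spans the locus
    assert pair.left_start <= locus.start and pair.right_end >= locus.end


def test_designed_primers_satisfy_all_constraints(rng):
    c_def = PrimerConstraints()
    checked = 0
    for _ in range(200):
        seq = balanced_flank(rng, 150) + "ATG" * 5 + balanced_flank(rng, 150)
        c = contig(seq)
        loci = [l for l in find_ssrs(c) if l.motif == "ATG"]
        if not loci:
            continue
        pair = design_primers(c, loci[0])
        if pair is None:
            continue
        checked += 1
        for primer, gc, tm in (
            (pair.left, pair.gc_left, pair.tm_left),
            (revcomp(pair.right), pair.gc_right, pair.tm_right),
        ):
            assert c_def.min_len <= len(primer) <= c_def.max_len
            assert c_def.min_gc <= gc <= c_def.max_gc
            assert c_def.min_tm <= tm <= c_def.max_tm
        assert abs(pair.tm_left - pair.tm_right) <= c_def.max_tm_diff
        assert c_def.min_product <= pair.expected_product <= c_def.max_product
        # primers actually occur on the contig in the claimed places
        assert seq[pair.left_start : pair.left_start + len(pair.left)] == pair.left
        site = revcomp(pair.right)
        assert seq[pair.right_end - len(site) : pair.right_end] == site
    assert checked >= 100


def test_locus_off_contig_errors(rng):
    c = contig(balanced_flank(rng, 50))
    rogue = SSRLocus("other", 0, 12, "AG", 6)
    with pytest.raises(ValueError, match="not on contig"):
        design_primers(c, rogue)


# ---------------------------------------------------------------------------
# virtual_pcr
# ---------------------------------------------------------------------------


def designed_template(rng, seed_offset=0):
    import numpy as np

    local = np.random.default_rng(777 + seed_offset)
    # a T spacer pins the run's leftmost phase to the AG motif
    seq = balanced_flank(local, 130) + "T" + "AG" * 7 + "T" + balanced_flank(local, 130)
    c = contig(seq, "template")
    # the planted run sits right after the 130-base flank and its spacer
    (locus,) = [l for l in find_ssrs(c) if l.start == 131 and l.motif == "AG"]
    pair = design_primers(c, locus)
    assert pair is not None
    return c, pair


def test_unique_template_gives_single_amplicon(rng):
    c, pair = designed_template(rng)
    result = virtual_pcr(pair, AssemblySet("a", [c]))
    assert result.single_locus
    (amp,) = result.amplicons
    assert amp.product_len == pair.expected_product


def test_duplicated_template_gives_two_amplicons(rng):
    c, pair = designed_template(rng)
    asm = AssemblySet("a", [c, Contig("copy", c.seq)])
    result = virtual_pcr(pair, asm)
    assert len(result.amplicons) == 2 and not result.single_locus


def epcr_oracle(pair, assembly, max_product=3000):
    """Brute-force scan of every position pair on every contig/strand."""
    site = revcomp(pair.right)
    hits = set()
    for c in assembly:
        for seq, minus in ((c.seq, False), (revcomp(c.seq), True)):
            for i in range(len(seq) - len(pair.left) + 1):
                if seq[i : i + len(pair.left)] != pair.left:
                    continue
                for j in range(i, len(seq) - len(site) + 1):
                    if seq[j : j + len(site)] != site:
                        continue
                    end = j + len(site)
                    if end - i > max_product:
                        continue
                    if minus:
                        hits.add((c.id, len(seq) - end, len(seq) - i))
                    else:
                        hits.add((c.id, i, end))
    return hits


def test_virtual_pcr_equals_exhaustive_scan(rng):
    for k in range(50):
        c, pair = designed_template(rng, seed_offset=k)
        extra = Contig("decoy", random_dna(rng, 400))
        asm = AssemblySet("a", [c, extra])
        got = {(a.contig_id, a.start, a.end)
               for a in virtual_pcr(pair, asm).amplicons}
        assert got == epcr_oracle(pair, asm)


def test_designed_pair_always_amplifies_its_source(rng):
    for k in range(20):
        c, pair = designed_template(rng, seed_offset=100 + k)
        assert len(virtual_pcr(pair, AssemblySet("a", [c])).amplicons) >= 1


# ---------------------------------------------------------------------------
# ssr_summary
# ---------------------------------------------------------------------------


def test_summary_counts_and_percent_normalisation(rng):
    contigs = [Contig(f"c{i}", random_dna(rng, 400)) for i in range(5)]
    asm = AssemblySet("a", contigs)
    loci = [
        SSRLocus("c0", 0, 12, "AG", 6),
        SSRLocus("c0", 50, 65, "ATG", 5),
        SSRLocus("c1", 10, 22, "TC", 6),
    ]
    summary = ssr_summary(loci, asm)
    assert summary.total_ssrs == 3
    assert summary.n_containing == 2 and summary.n_multi == 1
    assert summary.by_unit[2] == 2 and summary.by_unit[3] == 1
    assert abs(sum(summary.pct_by_unit.values()) - 100.0) <= 0.2
    assert summary.class_counts == {"AG/CT": 1, "ATG/CAT": 1, "GA/TC": 1}
    assert summary.frequency_kb == pytest.approx(
        asm.total_length / 3 / 1000, abs=0.01
    )


def test_summary_on_planted_truth_matches_tallies():
    from asmeval import synthetic_data as sd

    genes = sd.generate_reference(40, seed=900)
    asm, _ = sd.corrupt_assembly(genes, 1.0, seed=901)
    planted, truths = sd.plant_ssrs(asm, seed=902)
    loci = [l for c in planted for l in find_ssrs(c)]
    summary = ssr_summary(loci, planted)
    assert summary.total_ssrs == len(truths)
    assert summary.n_containing == len({t.contig_id for t in truths})
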