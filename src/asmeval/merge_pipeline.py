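"""Multi-k merged-assembly strategy.

Assemblies built at several k-mer sizes are pooled, redundancy is
removed by greedy longest-first clustering at a nucleotide identity
threshold on both strands (the greedy-incremental clustering scheme of
cd-hit-est style tools: the longest sequence of each cluster is its
representative), overlapping representatives are meta-assembled into
longer consensus sequences by repeated suffix-prefix merging, and the
resulting contigs and singletons are pooled into the final assembly.

Identity here is exact: the best ungapped end-gap-free placement of
the shorter sequence against the longer, with matched columns counted
over the shorter sequence's length. No word-filter heuristic is used;
at desk scale the exact comparison is affordable and is what the
heuristic approximates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import AssemblySet, Contig, revcomp

__all__ = [
    "Cluster",
    "MetaAssemblyResult",
    "pool_assemblies",
    "sequence_identity",
    "cluster_reduce",
    "meta_assemble",
    "finalize_merge",
]

DEFAULT_IDENTITY = 0.99
DEFAULT_MIN_OVERLAP = 40
DEFAULT_OVERLAP_IDENTITY = 0.90


@dataclass
class Cluster:
    """A redundancy cluster; the representative is the longest member."""

    representative: Contig
    members: list[str] = field(default_factory=list)


@dataclass
class MetaAssemblyResult:
    """Meta-assembly output: consensus contigs (built from >= 2 inputs)
    and singletons (inputs that merged with nothing)."""

    contigs: list[Contig]
    singletons: list[Contig]


def pool_assemblies(assemblies: list[AssemblySet], label: str = "pooled") -> AssemblySet:
    """Concatenate assemblies, prefixing ids with the source label so
    ids stay unique across sources."""
    if not assemblies:
        raise ValueError("pool_assemblies requires at least one assembly")
    pooled = AssemblySet(label)
    for asm in assemblies:
        for contig in asm:
            pooled.add(Contig(f"{asm.label}|{contig.id}", contig.seq))
    return pooled


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _identity_one_strand(short: np.ndarray, long: np.ndarray) -> float:
    """Max fraction of matching columns over all full placements of
    ``short`` within ``long`` (ungapped, end-gap-free)."""
    m = short.size
    windows = np.lib.stride_tricks.sliding_window_view(long, m)
    matches = (windows == short).sum(axis=1)
    return float(matches.max()) / m


def sequence_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Identity of the shorter sequence against the longer.

    Matched columns in the best ungapped end-gap-free placement of the
    shorter sequence along the longer, divided by the shorter length;
    with ``both_strands`` the maximum over ``b`` and its reverse
    complement is taken.
    """
    if not a or not b:
        raise ValueError("sequence_identity requires nonempty sequences")
    if len(a) <= len(b):
        short_s, long_s = a, b
    else:
        short_s, long_s = b, a
    short = _encode(short_s)
    ident = _identity_one_strand(short, _encode(long_s))
    if both_strands and ident < 1.0:
        ident = max(ident, _identity_one_strand(short, _encode(revcomp(long_s))))
    return ident


def cluster_reduce(
    assembly: AssemblySet,
    identity_threshold: float = DEFAULT_IDENTITY,
    both_strands: bool = True,
) -> tuple[AssemblySet, list[Cluster]]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed longest first (ties keep input order); each
    joins the first existing cluster whose representative it matches at
    >= the threshold, otherwise it founds a new cluster. Representatives
    are returned in founding order.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must lie in (0, 1]")
    ordered = sorted(
        enumerate(assembly), key=lambda item: (-item[1].length, item[0])
    )
    clusters: list[Cluster] = []
    for _, contig in ordered:
        placed = False
        for cluster in clusters:
            if (
                sequence_identity(contig.seq, cluster.representative.seq, both_strands)
                >= identity_threshold
            ):
                cluster.members.append(contig.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(contig, [contig.id]))
    representatives = AssemblySet(
        f"{assembly.label}.nr", (c.representative for c in clusters)
    )
    return representatives, clusters


def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float) -> int:
    """Longest suffix(a)-prefix(b) overlap >= min_overlap whose ungapped
    identity is >= min_identity; 0 if none."""
    ea, eb = _encode(a), _encode(b)
    for olen in range(min(len(a), len(b)), min_overlap - 1, -1):
        matches = int((ea[-olen:] == eb[:olen]).sum())
        if matches / olen >= min_identity:
            return olen
    return 0


def _consensus(a: str, b: str, olen: int, a_is_longer: bool) -> str:
    """Merge a and b across their overlap; disagreeing columns take the
    base from the longer parent."""
    overlap_a, overlap_b = a[-olen:], b[:olen]
    if overlap_a == overlap_b:
        middle = overlap_a
    else:
        src = overlap_a if a_is_longer else overlap_b
        middle = src
    return a[:-olen] + middle + b[olen:]


@dataclass
class _Piece:
    seq: str
    n_inputs: int


def meta_assemble(
    assembly: AssemblySet,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_overlap_identity: float = DEFAULT_OVERLAP_IDENTITY,
    both_strands: bool = True,
) -> MetaAssemblyResult:
    """Greedy overlap merging into consensus sequences.

    Repeatedly the pair with the longest qualifying suffix-prefix
    overlap (>= ``min_overlap`` bases at >= ``min_overlap_identity``,
    considering both strands when requested) is replaced by its
    consensus, until no qualifying overlap remains. Inputs that never
    merge come back as singletons. The greedy longest-overlap order is
    a deterministic simplification of full overlap-layout-consensus
    scoring.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not (0 < min_overlap_identity <= 1):
        raise ValueError("min_overlap_identity must lie in (0, 1]")
    pieces = [_Piece(c.seq, 1) for c in assembly]

    def find_best() -> tuple[int, int, int, bool] | None:
        # returns (i, j, overlap_len, j_revcomped) with suffix(i)-prefix(j)
        best: tuple[int, int, int, bool] | None = None
        for i in range(len(pieces)):
            for j in range(len(pieces)):
                if i == j:
                    continue
                olen = _best_overlap(
                    pieces[i].seq, pieces[j].seq, min_overlap, min_overlap_identity
                )
                if olen and (best is None or olen > best[2]):
                    best = (i, j, olen, False)
                if both_strands:
                    olen = _best_overlap(
                        pieces[i].seq,
                        revcomp(pieces[j].seq),
                        min_overlap,
                        min_overlap_identity,
                    )
                    if olen and (best is None or olen > best[2]):
                        best = (i, j, olen, True)
        return best

    while True:
        hit = find_best()
        if hit is None:
            break
        i, j, olen, rc = hit
        a = pieces[i]
        b_seq = revcomp(pieces[j].seq) if rc else pieces[j].seq
        merged = _consensus(a.seq, b_seq, olen, a_is_longer=len(a.seq) >= len(b_seq))
        n_inputs = a.n_inputs + pieces[j].n_inputs
        for k in sorted((i, j), reverse=True):
            pieces.pop(k)
        pieces.append(_Piece(merged, n_inputs))

    contigs = [
        Contig(f"meta_contig_{k + 1}", p.seq)
        for k, p in enumerate(p for p in pieces if p.n_inputs >= 2)
    ]
    singletons = [
        Contig(f"meta_singleton_{k + 1}", p.seq)
        for k, p in enumerate(p for p in pieces if p.n_inputs == 1)
    ]
    return MetaAssemblyResult(contigs, singletons)


def finalize_merge(result: MetaAssemblyResult, label: str = "merged") -> AssemblySet:
    """Pool consensus contigs then singletons into the final assembly."""
    final = AssemblySet(label)
    for k, contig in enumerate(result.contigs + result.singletons, start=1):
        final.add(Contig(f"{label}_{k}", contig.seq))
    return final
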