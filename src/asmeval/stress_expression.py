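"""Stress-candidate classification and Pfaffl relative expression.

Candidate stress-responsive transcripts are the queries of a best-hit
table built against a curated set of abiotic-stress proteins at an
e-value cutoff; coverage counts how many of those reference proteins
the assembly recovers.

Relative expression from qRT-PCR follows the efficiency-corrected
Pfaffl model::

    ratio = E_target ** dCt_target / E_ref ** dCt_ref,
    dCt   = mean Ct(control) - mean Ct(treated)

so a ratio > 1 means up-regulation under treatment. Fold changes are
reported with the signed convention (ratio if >= 1, else -1/ratio), and
significance comes from a randomization test that permutes condition
labels jointly for target and reference gene — a documented stand-in
for the proprietary fixed-reallocation scheme of REST-style software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ortholog_metrics import BestHitTable

__all__ = [
    "StressCandidateReport",
    "CtTable",
    "ExpressionResult",
    "stress_candidates",
    "pfaffl_ratio",
    "signed_fold",
    "randomization_test",
    "expression_analysis",
]

CT_COLUMNS = ["gene", "condition", "timepoint", "replicate", "ct"]
CONDITIONS = ("control", "treated")


@dataclass(frozen=True)
class StressCandidateReport:
    candidates: tuple[str, ...]
    covered: tuple[str, ...]
    n_candidates: int
    n_covered: int
    n_reference_proteins: int


def stress_candidates(
    best_hit_table: BestHitTable, stress_protein_ids: Iterable[str]
) -> StressCandidateReport:
    """Classify queries of a best-hit table as stress candidates.

    Candidates are all queries present in the table (each has an
    accepted hit by construction); covered proteins are the distinct
    subjects. A subject outside the declared stress set is an error,
    guarding against tables built from a mixed database.
    """
    stress_set = set(stress_protein_ids)
    covered: set[str] = set()
    for query, hit in best_hit_table.entries.items():
        if hit.subject not in stress_set:
            raise ValueError(
                f"best hit of {query!r} is {hit.subject!r}, which is not in "
                "the declared stress-protein set"
            )
        covered.add(hit.subject)
    return StressCandidateReport(
        candidates=tuple(sorted(best_hit_table.entries)),
        covered=tuple(sorted(covered)),
        n_candidates=len(best_hit_table.entries),
        n_covered=len(covered),
        n_reference_proteins=len(stress_set),
    )


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


@dataclass
class CtTable:
    """Replicate quantification cycles plus per-gene amplification
    efficiencies (E in (1, 2]; 2 = perfect doubling per cycle)."""

    data: pd.DataFrame
    efficiencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        bad_cond = set(self.data["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
        for gene, eff in self.efficiencies.items():
            if not (1.0 < eff <= 2.0):
                raise ValueError(f"gene {gene!r}: efficiency {eff} outside (1, 2]")

    def efficiency(self, gene: str) -> float:
        return self.efficiencies.get(gene, 2.0)

    def cts(self, gene: str, condition: str, timepoint) -> np.ndarray:
        mask = (
            (self.data["gene"] == gene)
            & (self.data["condition"] == condition)
            & (self.data["timepoint"] == timepoint)
        )
        return self.data.loc[mask, "ct"].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, efficiencies: dict[str, float] | None = None
    ) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t"), efficiencies or {})


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    timepoint: object
    ratio: float
    signed: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# Pfaffl quantification
# ---------------------------------------------------------------------------


def _mean_cts(table: CtTable, gene: str, timepoint) -> tuple[float, float]:
    out = []
    for condition in CONDITIONS:
        cts = table.cts(gene, condition, timepoint)
        if cts.size == 0:
            raise ValueError(
                f"gene {gene!r} has no {condition!r} replicates at "
                f"timepoint {timepoint!r}"
            )
        out.append(float(cts.mean()))
    return out[0], out[1]


def pfaffl_ratio(table: CtTable, gene: str, ref_gene: str, timepoint) -> float:
    """Efficiency-corrected expression ratio of ``gene`` normalised to
    ``ref_gene`` at one timepoint (replicate Ct means, control - treated)."""
    e_gene, e_ref = table.efficiency(gene), table.efficiency(ref_gene)
    for g, e in ((gene, e_gene), (ref_gene, e_ref)):
        if e <= 1.0:
            raise ValueError(f"gene {g!r}: efficiency must be > 1")
    ctrl_g, trt_g = _mean_cts(table, gene, timepoint)
    ctrl_r, trt_r = _mean_cts(table, ref_gene, timepoint)
    return e_gene ** (ctrl_g - trt_g) / e_ref ** (ctrl_r - trt_r)


def signed_fold(ratio: float) -> float:
    """Signed fold-change convention: ratio if >= 1, else -1/ratio,
    so |signed| >= 1 always and -2.0 means two-fold down-regulation."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1.0 else -1.0 / ratio


def randomization_test(
    table: CtTable,
    gene: str,
    ref_gene: str,
    timepoint,
    n_permutations: int = 2000,
    seed: int = 0,
) -> float:
    """Permutation p-value for differential expression at one timepoint.

    Condition labels are shuffled jointly for the target and reference
    gene (each replicate keeps its target/reference Ct pair); the
    p-value is the fraction of permuted datasets whose |log ratio|
    reaches the observed one, with the +1/(n+1) correction so p is
    never zero.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    pairs = []  # (gene_ct, ref_ct) per replicate, control first
    n_by_cond = []
    for condition in CONDITIONS:
        g = table.cts(gene, condition, timepoint)
        r = table.cts(ref_gene, condition, timepoint)
        if g.size < 2 or r.size < 2:
            raise ValueError(
                f"randomization test needs >= 2 replicates per condition "
                f"({gene!r}/{ref_gene!r} at {timepoint!r})"
            )
        if g.size != r.size:
            raise ValueError("target and reference replicate counts differ")
        pairs.extend(zip(g, r))
        n_by_cond.append(g.size)
    n_ctrl = n_by_cond[0]
    pairs_arr = np.asarray(pairs)  # shape (n_ctrl + n_trt, 2)

    e_gene, e_ref = table.efficiency(gene), table.efficiency(ref_gene)

    def log_ratio(ctrl_idx: np.ndarray, trt_idx: np.ndarray) -> float:
        d_g = pairs_arr[ctrl_idx, 0].mean() - pairs_arr[trt_idx, 0].mean()
        d_r = pairs_arr[ctrl_idx, 1].mean() - pairs_arr[trt_idx, 1].mean()
        return d_g * math.log(e_gene) - d_r * math.log(e_ref)

    n_total = pairs_arr.shape[0]
    observed = abs(log_ratio(np.arange(n_ctrl), np.arange(n_ctrl, n_total)))
    rng = np.random.default_rng(seed)
    n_extreme = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        stat = abs(log_ratio(perm[:n_ctrl], perm[n_ctrl:]))
        if stat >= observed - 1e-12:
            n_extreme += 1
    return (n_extreme + 1) / (n_permutations + 1)


def expression_analysis(
    table: CtTable,
    genes: Sequence[str],
    ref_gene: str,
    timepoints: Sequence | None = None,
    n_permutations: int = 2000,
    seed: int = 0,
) -> list[ExpressionResult]:
    """Pfaffl ratio, signed fold change and permutation p-value for each
    gene and timepoint; the reference gene itself is not reported."""
    if timepoints is None:
        timepoints = sorted(set(table.data["timepoint"]))
    results = []
    for k, gene in enumerate(genes):
        if gene == ref_gene:
            continue
        for j, tp in enumerate(timepoints):
            ratio = pfaffl_ratio(table, gene, ref_gene, tp)
            p = randomization_test(
                table, gene, ref_gene, tp, n_permutations,
                seed=seed + 10_000 * k + j,
            )
            results.append(
                ExpressionResult(gene, tp, ratio, signed_fold(ratio), p, n_permutations)
            )
    return results
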