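"""Vaccine-candidate peptide shortlisting.

Candidates are eluted peptides whose source gene is upregulated in tumor
(log fold change above threshold), whose predicted binding affinity is
below a nanomolar bound, and which recur across replicates.  Survivors are
ranked deterministically: tumor-tissue evidence first (when a tissue is
prioritized), then the preferred length (9mers), then ascending affinity,
then descending replicate count, then sequence.  The final table can be
exported with an N-terminal poly-lysine tail for electrostatic loading
onto an adenovirus capsid.

Inequalities are deliberately strict or not per the stated criteria:
affinity strictly below the bound, log fold change strictly above, and
replicate count at-or-above.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .binding_predictor import BindingPrediction
from .peptidome_io import SampleRun

logger = logging.getLogger(__name__)

FILTER_ORDER = ("expression", "affinity", "replicates")


@dataclass(frozen=True)
class CandidateCriteria:
    """Thresholds of the selection pipeline."""

    affinity_max_nM: float = 50.0
    min_log_fc: float = 2.0
    min_replicates: int = 3
    preferred_length: int = 9
    top_k: int = 15
    require_upregulated: bool = True
    prioritize_tissue: str | None = None

    def __post_init__(self) -> None:
        if self.affinity_max_nM <= 0 or self.min_replicates <= 0:
            raise ValueError("thresholds must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class CandidateRow:
    """One ranked candidate peptide."""

    peptide: str
    best_allele: str
    affinity_nM: float
    rank_percentile: float
    n_replicates: int
    genes: tuple[str, ...]
    log_fc: float
    is_preferred_length: bool
    tissue_evidence: bool
    position: int


@dataclass
class SelectionResult:
    rows: list[CandidateRow]
    filter_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": r.position,
                    "peptide": r.peptide,
                    "best_allele": r.best_allele,
                    "affinity_nM": r.affinity_nM,
                    "rank": r.rank_percentile,
                    "n_replicates": r.n_replicates,
                    "genes": ";".join(r.genes),
                    "log_fc": r.log_fc,
                    "preferred_length": r.is_preferred_length,
                    "tissue_evidence": r.tissue_evidence,
                }
                for r in self.rows
            ]
        )


def replicate_count(peptide: str, runs: Sequence[SampleRun]) -> int:
    """Number of runs whose peptide set contains the exact sequence."""
    return sum(1 for run in runs if peptide in run.sequences)


def _filter_predicates(
    criteria: CandidateCriteria,
) -> dict[str, str]:
    # names -> description, used for the survivor log
    return {
        "expression": f"log_fc > {criteria.min_log_fc}",
        "affinity": f"affinity_nM < {criteria.affinity_max_nM}",
        "replicates": f"n_replicates >= {criteria.min_replicates}",
    }


def select_candidates(
    runs: Sequence[SampleRun],
    predictions: Mapping[str, BindingPrediction],
    expression: Mapping[str, float],
    peptide_genes: Mapping[str, Sequence[str]],
    criteria: CandidateCriteria = CandidateCriteria(),
    filter_order: Sequence[str] = FILTER_ORDER,
) -> SelectionResult:
    """Filter, rank and truncate candidate peptides.

    The filters (upregulated gene, affinity bound, replicate count) commute
    — ``filter_order`` only affects the logged survivor counts.  Peptides
    without a prediction, or (under ``require_upregulated``) without a
    mapped+measured gene, are excluded and counted, not an error.
    Multi-gene peptides use the maximum log fold change among their genes.
    """
    if set(filter_order) != set(FILTER_ORDER):
        raise ValueError(f"filter_order must be a permutation of {FILTER_ORDER}")

    universe = sorted({seq for run in runs for seq in run.sequences})
    counts: dict[str, int] = {"universe": len(universe)}

    entries = []
    n_no_prediction = n_no_gene = 0
    for pep in universe:
        pred = predictions.get(pep)
        if pred is None:
            n_no_prediction += 1
            continue
        genes = tuple(sorted(peptide_genes.get(pep, ())))
        fcs = [expression[g] for g in genes if g in expression]
        if criteria.require_upregulated and not fcs:
            n_no_gene += 1
            continue
        entries.append(
            {
                "peptide": pep,
                "pred": pred,
                "genes": genes,
                "log_fc": max(fcs) if fcs else float("nan"),
                "n_replicates": replicate_count(pep, runs),
            }
        )
    counts["no_prediction"] = n_no_prediction
    counts["no_mapped_gene"] = n_no_gene
    counts["evaluable"] = len(entries)

    def passes(entry: dict, name: str) -> bool:
        if name == "expression":
            if not criteria.require_upregulated:
                return True
            return entry["log_fc"] > criteria.min_log_fc
        if name == "affinity":
            return entry["pred"].affinity_nM < criteria.affinity_max_nM
        if name == "replicates":
            return entry["n_replicates"] >= criteria.min_replicates
        raise ValueError(name)

    descriptions = _filter_predicates(criteria)
    survivors = entries
    for name in filter_order:
        survivors = [e for e in survivors if passes(e, name)]
        counts[name] = len(survivors)
        logger.info(
            "filter %s (%s): %d survivor(s)", name, descriptions[name], len(survivors)
        )

    tissue_peptides: set[str] = set()
    if criteria.prioritize_tissue is not None:
        for run in runs:
            if run.tissue_label == criteria.prioritize_tissue:
                tissue_peptides |= run.sequences

    def sort_key(entry: dict):
        pep = entry["peptide"]
        return (
            pep not in tissue_peptides if criteria.prioritize_tissue else False,
            len(pep) != criteria.preferred_length,
            entry["pred"].affinity_nM,
            -entry["n_replicates"],
            pep,
        )

    survivors.sort(key=sort_key)
    rows = [
        CandidateRow(
            peptide=e["peptide"],
            best_allele=e["pred"].allele,
            affinity_nM=e["pred"].affinity_nM,
            rank_percentile=e["pred"].rank_percentile,
            n_replicates=e["n_replicates"],
            genes=e["genes"],
            log_fc=e["log_fc"],
            is_preferred_length=len(e["peptide"]) == criteria.preferred_length,
            tissue_evidence=e["peptide"] in tissue_peptides,
            position=i + 1,
        )
        for i, e in enumerate(survivors[: criteria.top_k])
    ]
    counts["final"] = len(rows)
    return SelectionResult(rows=rows, filter_counts=counts)


def export_polyk(
    candidates: Sequence[CandidateRow], k: int = 6
) -> pd.DataFrame:
    """Candidate sequences with an N-terminal poly-lysine tail of length k.

    The original sequence is kept in its own column; peptides that start
    with lysine are flagged, since stripping k leading K residues would not
    recover them unambiguously.
    """
    if k < 1:
        raise ValueError("poly-K tail length must be >= 1")
    return pd.DataFrame(
        [
            {
                "peptide": r.peptide,
                "polyk_sequence": "K" * k + r.peptide,
                "starts_with_K": r.peptide.startswith("K"),
            }
            for r in candidates
        ],
        columns=["peptide", "polyk_sequence", "starts_with_K"],
    )
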