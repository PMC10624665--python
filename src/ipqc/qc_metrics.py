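"""Per-run QC battery for eluted-peptide datasets.

Four assessments make up the dashboard: the peptide length distribution
(MHC class I ligandomes peak at nine residues), the fraction of peptides
predicted to bind the sample's own haplotype (rank percentile at most 2,
i.e. strong or weak binders), allele-specificity deconvolution (each
peptide attributed to its best-ranking allele), and exclusive replicate
overlaps in UpSet semantics.  Motif summaries (position frequency matrices
with per-position information content) describe the deconvoluted groups.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding_predictor import N_RESIDUES, PredictorBackend, encode_peptides
from .peptidome_io import SampleRun

DEFAULT_LENGTH_WINDOW = (8, 13)


@dataclass
class LengthDistribution:
    """Unique-peptide counts and percentages per length for one run."""

    run_id: str
    counts: dict[int, int]
    percentages: dict[int, float]
    fraction_8_13: float
    fraction_9_of_all: float
    fraction_9_of_8_13: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "length": sorted(self.counts),
                "count": [self.counts[k] for k in sorted(self.counts)],
                "percentage": [self.percentages[k] for k in sorted(self.counts)],
            }
        )


def length_distribution(run: SampleRun) -> LengthDistribution:
    """Distribution of unique peptide lengths as counts and percentages."""
    if len(run) == 0:
        raise ValueError(f"empty run {run.run_id}")
    lengths = [len(seq) for seq in run.sequences]
    total = len(lengths)
    counts: dict[int, int] = {}
    for L in lengths:
        counts[L] = counts.get(L, 0) + 1
    percentages = {L: 100.0 * c / total for L, c in counts.items()}
    lo, hi = DEFAULT_LENGTH_WINDOW
    n_window = sum(c for L, c in counts.items() if lo <= L <= hi)
    n_nine = counts.get(9, 0)
    return LengthDistribution(
        run_id=run.run_id,
        counts=counts,
        percentages=percentages,
        fraction_8_13=100.0 * n_window / total,
        fraction_9_of_all=100.0 * n_nine / total,
        fraction_9_of_8_13=(100.0 * n_nine / n_window) if n_window else float("nan"),
    )


def _peptides_in_scope(run: SampleRun, scope: str) -> list[str]:
    if scope == "all_8_13":
        lo, hi = DEFAULT_LENGTH_WINDOW
        return sorted(s for s in run.sequences if lo <= len(s) <= hi)
    if scope == "only_9":
        return sorted(s for s in run.sequences if len(s) == 9)
    raise ValueError(f"unknown scope {scope!r}")


def binder_fraction(
    run: SampleRun, predictor: PredictorBackend, scope: str = "all_8_13"
) -> float:
    """Percentage of in-scope peptides classified SB or WB for the run's
    haplotype (best-allele rank at most 2%).  NaN when the scope is empty."""
    if not run.haplotype:
        raise ValueError(f"run {run.run_id} has no haplotype")
    peptides = _peptides_in_scope(run, scope)
    if not peptides:
        return float("nan")
    table = predictor.predict_table(peptides, run.haplotype)
    n_binders = int(table["binder_class"].isin(("SB", "WB")).sum())
    return 100.0 * n_binders / len(peptides)


@dataclass
class SpecificityComposition:
    """Per-allele SB/WB counts plus nB and unassignable tallies."""

    run_id: str
    per_allele: dict[str, dict[str, int]]
    n_nonbinder: int
    n_unassignable: int
    n_total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"allele": a, "SB": v.get("SB", 0), "WB": v.get("WB", 0)}
            for a, v in sorted(self.per_allele.items())
        ]
        return pd.DataFrame(rows, columns=["allele", "SB", "WB"])


def deconvolute_specificity(
    run: SampleRun,
    predictor: PredictorBackend,
    lengths: Sequence[int] | None = None,
) -> tuple[SpecificityComposition, pd.DataFrame]:
    """Assign each peptide to its best-ranking allele and tally SB/WB/nB.

    ``lengths`` restricts the analysis (default: the 8-13 window; the
    stacked-bar rendering conventionally uses 9mers only).  Returns the
    composition and the per-peptide assignment table.
    """
    if not run.haplotype:
        raise ValueError(f"run {run.run_id} has no haplotype")
    if lengths is None:
        lo, hi = DEFAULT_LENGTH_WINDOW
        lengths = range(lo, hi + 1)
    allowed = set(lengths)
    peptides = sorted(s for s in run.sequences if len(s) in allowed)
    table = predictor.predict_table(peptides, run.haplotype)
    per_allele: dict[str, dict[str, int]] = {}
    n_nb = n_unassignable = 0
    for row in table.itertuples(index=False):
        if row.allele == "none":
            n_unassignable += 1
        elif row.binder_class == "nB":
            n_nb += 1
        else:
            per_allele.setdefault(row.allele, {}).setdefault(row.binder_class, 0)
            per_allele[row.allele][row.binder_class] += 1
    composition = SpecificityComposition(
        run_id=run.run_id,
        per_allele=per_allele,
        n_nonbinder=n_nb,
        n_unassignable=n_unassignable,
        n_total=len(peptides),
    )
    return composition, table


def replicate_overlap_sets(
    runs: Sequence[SampleRun],
) -> dict[frozenset[str], int]:
    """Exclusive intersection sizes over runs (UpSet semantics).

    Each peptide is counted once, in exactly the subset of runs that
    contain it; the returned sizes therefore sum to the size of the union.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for overlap sets")
    ids = [r.run_id for r in runs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate run ids")
    membership: dict[str, set[str]] = {}
    for run in runs:
        for seq in run.sequences:
            membership.setdefault(seq, set()).add(run.run_id)
    sizes: dict[frozenset[str], int] = {}
    for subset in membership.values():
        key = frozenset(subset)
        sizes[key] = sizes.get(key, 0) + 1
    return sizes


def overlap_sets_table(sizes: Mapping[frozenset[str], int]) -> pd.DataFrame:
    rows = [
        {"runs": "&".join(sorted(k)), "degree": len(k), "count": v}
        for k, v in sizes.items()
    ]
    return (
        pd.DataFrame(rows, columns=["runs", "degree", "count"])
        .sort_values(["degree", "runs"])
        .reset_index(drop=True)
    )


@dataclass
class MotifSummary:
    """Position frequency matrix and per-position information content."""

    allele: str
    length: int
    n_peptides: int
    frequencies: np.ndarray = field(repr=False)  # (length, 20), rows sum to 1
    information_bits: np.ndarray = field(repr=False)  # (length,)
    sufficient: bool = True


MIN_MOTIF_GROUP = 10


def position_information(frequencies: np.ndarray) -> np.ndarray:
    """Information content log2(20) - H per position, in [0, log2 20] bits."""
    freqs = np.asarray(frequencies, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    return math.log2(N_RESIDUES) - entropy


def motif_summary(
    assignments: Mapping[str, Iterable[str]], length: int
) -> dict[str, MotifSummary]:
    """Summarise predictor-assigned peptide groups as motifs.

    Groups with fewer than 10 peptides of the requested length are reported
    as insufficient (``sufficient=False``, empty matrices).
    """
    out: dict[str, MotifSummary] = {}
    for allele, peptides in assignments.items():
        batch = [p for p in peptides if len(p) == length]
        if len(batch) < MIN_MOTIF_GROUP:
            out[allele] = MotifSummary(
                allele, length, len(batch),
                np.empty((0, N_RESIDUES)), np.empty(0), sufficient=False,
            )
            continue
        idx = encode_peptides(batch)
        counts = np.zeros((length, N_RESIDUES))
        for i in range(length):
            counts[i] = np.bincount(idx[:, i], minlength=N_RESIDUES)
        freqs = counts / len(batch)
        out[allele] = MotifSummary(
            allele, length, len(batch), freqs, position_information(freqs)
        )
    return out
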