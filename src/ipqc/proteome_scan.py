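"""In-silico predicted-presentation dataset and its comparison to observed
elution.

Every 9-residue window of a chosen set of source proteins is predicted
across the haplotype, yielding the set of peptides the cell *could*
present; comparing against the peptides actually eluted quantifies how
small a fraction of predicted strong binders is ever observed.  The module
also provides the presentation-vs-abundance association statistics: a
rank-sum comparison of the abundance of presented vs non-presented
proteins, and rank correlations of per-peptide intensity and binding rank
against the number of replicates in which a peptide was observed.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binding_predictor import PredictorBackend
from .peptidome_io import ProteinDb, SampleRun

WINDOW = 9
#: predicted "strong binder" rank bound for the scan summary; note this is
#: an inclusive bound (rank <= 0.5), unlike the SB class which is strict.
STRONG_RANK_MAX = 0.5


def scan_9mers(
    proteins: ProteinDb, subset: Sequence[str] | None = None
) -> dict[str, set[str]]:
    """Unique 9mer -> source accessions over sliding windows (stride 1).

    A protein of length L yields max(0, L - 8) windows; duplicate windows
    merge their source sets.
    """
    accessions = sorted(proteins.sequences) if subset is None else list(subset)
    out: dict[str, set[str]] = {}
    for acc in accessions:
        seq = proteins[acc]  # KeyError for unknown accession
        for i in range(len(seq) - WINDOW + 1):
            out.setdefault(seq[i : i + WINDOW], set()).add(acc)
    return out


def scan_table(
    scan: Mapping[str, set[str]],
    predictor: PredictorBackend,
    haplotype: Sequence[str],
    runs: Sequence[SampleRun] = (),
) -> pd.DataFrame:
    """Predict every scanned 9mer across the haplotype and mark observation.

    Columns: peptide, sources, best_allele, best_rank, affinity_nM,
    binder_class, observed, n_runs_observed, plus one ``rank_<allele>``
    column per haplotype allele.
    """
    peptides = sorted(scan)
    best = predictor.predict_table(peptides, haplotype)
    per_allele = predictor.predict_per_allele(peptides, haplotype)
    wide = per_allele.pivot(index="peptide", columns="allele", values="rank")
    df = best.rename(columns={"allele": "best_allele", "rank": "best_rank"})
    df["sources"] = [";".join(sorted(scan[p])) for p in df["peptide"]]
    n_obs = np.zeros(len(peptides), dtype=int)
    for run in runs:
        seqs = run.sequences
        n_obs += np.fromiter((p in seqs for p in df["peptide"]), dtype=int,
                             count=len(peptides))
    df["n_runs_observed"] = n_obs
    df["observed"] = n_obs >= 1
    for allele in wide.columns:
        df[f"rank_{allele}"] = wide[allele].reindex(df["peptide"]).to_numpy()
    return df


@dataclass(frozen=True)
class PredictedVsObserved:
    """Summary of the predicted-strong-binder vs eluted comparison."""

    n_scanned: int
    n_strong: int
    n_strong_observed: int
    fraction_strong_observed: float
    n_observed_not_strong: int


def predicted_vs_observed(
    scan_df: pd.DataFrame, eluted: Iterable[str]
) -> PredictedVsObserved:
    """Fraction of predicted strong binders (rank <= 0.5) actually eluted."""
    eluted_set = set(eluted)
    strong = scan_df["best_rank"] <= STRONG_RANK_MAX
    observed = scan_df["peptide"].isin(eluted_set)
    n_strong = int(strong.sum())
    n_strong_obs = int((strong & observed).sum())
    return PredictedVsObserved(
        n_scanned=len(scan_df),
        n_strong=n_strong,
        n_strong_observed=n_strong_obs,
        fraction_strong_observed=(n_strong_obs / n_strong) if n_strong else float("nan"),
        n_observed_not_strong=int((observed & ~strong).sum()),
    )


MIN_GROUP = 10


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    pvalue: float
    n_presented: int
    n_background: int


def compare_presented_abundance(
    abundance: Mapping[str, float], presented: Iterable[str]
) -> RankSumResult:
    """Two-sided Mann-Whitney test: abundance of presented vs non-presented
    proteins (both groups must have at least 10 members)."""
    presented_set = set(presented)
    a = [v for k, v in abundance.items() if k in presented_set]
    b = [v for k, v in abundance.items() if k not in presented_set]
    if len(a) < MIN_GROUP or len(b) < MIN_GROUP:
        raise ValueError(
            f"need >= {MIN_GROUP} proteins per group (got {len(a)}/{len(b)})"
        )
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return RankSumResult(float(stat), float(p), len(a), len(b))


def _spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class AbundanceStats:
    """Presentation-vs-abundance association battery for one cohort."""

    rank_sum: RankSumResult
    spearman_intensity_vs_replicates: tuple[float, float]
    spearman_rank_vs_replicates: tuple[float, float]
    n_peptides: int


def presentation_abundance_stats(
    protein_abundance: Mapping[str, float],
    runs: Sequence[SampleRun],
    peptide_ranks: Mapping[str, float] | None = None,
) -> AbundanceStats:
    """Association statistics between presentation, abundance and intensity.

    - Mann-Whitney (two-sided) on abundance of presented vs non-presented
      proteins (presented = any source accession of any eluted peptide).
    - Spearman of per-peptide mean intensity vs number of runs observed.
    - Spearman of best binding rank vs number of runs observed, when
      ``peptide_ranks`` is supplied.

    Degenerate (constant) vectors yield NaN correlations.  These are single
    planned comparisons; no multiplicity correction is applied.
    """
    presented_proteins: set[str] = set()
    n_obs: dict[str, int] = {}
    intensity_sum: dict[str, float] = {}
    intensity_n: dict[str, int] = {}
    for run in runs:
        for rec in run:
            presented_proteins.update(rec.source_proteins)
            n_obs[rec.sequence] = n_obs.get(rec.sequence, 0) + 1
            if rec.intensity is not None:
                intensity_sum[rec.sequence] = (
                    intensity_sum.get(rec.sequence, 0.0) + rec.intensity
                )
                intensity_n[rec.sequence] = intensity_n.get(rec.sequence, 0) + 1

    rank_sum = compare_presented_abundance(protein_abundance, presented_proteins)

    with_intensity = sorted(intensity_sum)
    mean_intensity = [intensity_sum[p] / intensity_n[p] for p in with_intensity]
    reps = [n_obs[p] for p in with_intensity]
    spearman_int = _spearman(mean_intensity, reps)

    if peptide_ranks is not None:
        common = sorted(set(n_obs) & set(peptide_ranks))
        spearman_rank = _spearman(
            [peptide_ranks[p] for p in common], [n_obs[p] for p in common]
        )
    else:
        spearman_rank = (float("nan"), float("nan"))

    return AbundanceStats(
        rank_sum=rank_sum,
        spearman_intensity_vs_replicates=spearman_int,
        spearman_rank_vs_replicates=spearman_rank,
        n_peptides=len(n_obs),
    )
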