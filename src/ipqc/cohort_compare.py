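"""Cross-sample analyses: pairwise peptide-set overlap with hierarchical
clustering, one-hot haplotype encoding, and annotation against reference
ligand sets.

Overlap between two peptide sets is reported as a percentage.  The default
normalisation divides the intersection by the smaller set
(Szymkiewicz-Simpson), which is symmetric and therefore clusterable; a
per-row normalisation is available for asymmetric questions.  Heatmap
capping (default 40%) is presentation-only — all computation uses the raw
percentages.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .peptidome_io import SampleRun, normalize_allele

DEFAULT_CAP = 40.0


@dataclass
class OverlapMatrix:
    """Pairwise overlap percentages between samples."""

    sample_ids: tuple[str, ...]
    raw: np.ndarray = field(repr=False)
    mode: str = "smaller_set"
    cap: float = DEFAULT_CAP

    @property
    def capped(self) -> np.ndarray:
        """Copy with values above the cap clipped, for rendering only."""
        return np.minimum(self.raw, self.cap)

    def to_frame(self, capped: bool = False) -> pd.DataFrame:
        data = self.capped if capped else self.raw
        return pd.DataFrame(data, index=self.sample_ids, columns=self.sample_ids)


def _as_items(
    samples: Mapping[str, Iterable[str]] | Sequence[SampleRun],
) -> list[tuple[str, frozenset[str]]]:
    if isinstance(samples, Mapping):
        return [(k, frozenset(v)) for k, v in samples.items()]
    return [(r.run_id, r.sequences) for r in samples]


def pairwise_overlap(
    samples: Mapping[str, Iterable[str]] | Sequence[SampleRun],
    mode: str = "smaller_set",
    cap: float = DEFAULT_CAP,
) -> OverlapMatrix:
    """Pairwise overlap percentage matrix between peptide sets.

    smaller_set: ``100 * |A & B| / min(|A|, |B|)`` (symmetric);
    row_set: ``100 * |A & B| / |A|`` per row A.  Empty sets are an error.
    """
    items = _as_items(samples)
    if len(items) < 2:
        raise ValueError("need at least 2 peptide sets")
    for name, s in items:
        if not s:
            raise ValueError(f"empty peptide set for sample {name!r}")
    if mode not in ("smaller_set", "row_set"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    n = len(items)
    mat = np.zeros((n, n))
    for i, (_, a) in enumerate(items):
        for j, (_, b) in enumerate(items):
            inter = len(a & b)
            denom = min(len(a), len(b)) if mode == "smaller_set" else len(a)
            mat[i, j] = 100.0 * inter / denom
    return OverlapMatrix(tuple(name for name, _ in items), mat, mode, cap)


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples on overlap distance."""

    sample_ids: tuple[str, ...]
    merge_tree: np.ndarray = field(repr=False)  # scipy linkage matrix
    leaf_order: tuple[str, ...] = ()
    newick: str = ""


def _to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        left, right, dist, _ = Z[node - n]
        branches = []
        for child in (int(left), int(right)):
            blen = dist - heights[child]
            branches.append(f"{render(child)}:{blen:.6g}")
        heights[node] = dist
        return f"({branches[0]},{branches[1]})"

    for k in range(n, 2 * n - 1):
        heights[k] = Z[k - n, 2]
    return render(2 * n - 2) + ";"


def cluster_overlap(matrix: OverlapMatrix, method: str = "average") -> ClusterResult:
    """Hierarchical clustering on distance = 100 - (uncapped) overlap.

    Requires the symmetric smaller_set normalisation; asymmetric row_set
    matrices are rejected.  Linkage method: average (UPGMA) or complete.
    """
    if matrix.mode != "smaller_set":
        raise ValueError(
            "clustering requires the symmetric smaller_set mode; "
            "recompute the matrix with mode='smaller_set'"
        )
    if method not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {method!r}")
    dist = 100.0 - matrix.raw
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=True), method=method)
    order = tuple(matrix.sample_ids[i] for i in leaves_list(Z))
    return ClusterResult(
        matrix.sample_ids, Z, order, _to_newick(Z, matrix.sample_ids)
    )


@dataclass
class HaplotypeEncoding:
    """Sample-by-allele binary presence matrix (shared alleles only)."""

    matrix: pd.DataFrame = field(repr=False)  # samples x reduced allele names
    aggregation: dict[str, str] = field(default_factory=dict)  # full -> column


def _group_key(allele: str) -> str | None:
    """Two-digit group of a human four-digit name (A02:01 -> A02)."""
    if ":" in allele and not allele.startswith("H2-"):
        return allele.split(":")[0]
    return None


def encode_haplotypes(
    samples: Sequence[tuple[str, Sequence[str]]],
    motif_groups: Mapping[str, str] | None = None,
) -> HaplotypeEncoding:
    """One-hot encode sample haplotypes for clustering.

    Four-digit names are reduced to their two-digit group (A02:01 -> A02)
    only when every allele aggregated under that group carries the same
    peptide-binding-motif label in ``motif_groups``; with no map supplied
    the reduction is applied unconditionally, with a warning.  Columns for
    alleles present in at most one sample are dropped.
    """
    normalized = [
        (sid, tuple(normalize_allele(a) for a in alleles)) for sid, alleles in samples
    ]
    if motif_groups is None:
        warnings.warn(
            "no motif-group map supplied; aggregating two-digit groups "
            "unconditionally", stacklevel=2,
        )
        motif_groups_norm: dict[str, str] | None = None
    else:
        motif_groups_norm = {normalize_allele(k): v for k, v in motif_groups.items()}

    all_alleles = sorted({a for _, alleles in normalized for a in alleles})
    by_group: dict[str, list[str]] = {}
    for a in all_alleles:
        key = _group_key(a)
        if key is not None:
            by_group.setdefault(key, []).append(a)

    aggregation: dict[str, str] = {}
    for a in all_alleles:
        key = _group_key(a)
        if key is None:
            aggregation[a] = a
            continue
        members = by_group[key]
        if motif_groups_norm is None:
            aggregation[a] = key
        else:
            labels = {motif_groups_norm.get(m, m) for m in members}
            aggregation[a] = key if len(labels) == 1 else a

    columns = sorted(set(aggregation.values()))
    data = pd.DataFrame(0, index=[sid for sid, _ in normalized], columns=columns)
    for sid, alleles in normalized:
        for a in alleles:
            data.loc[sid, aggregation[a]] = 1
    shared = data.columns[(data.sum(axis=0) >= 2)]
    data = data[list(shared)]
    aggregation = {k: v for k, v in aggregation.items() if v in set(shared)}
    return HaplotypeEncoding(matrix=data, aggregation=aggregation)


def cluster_haplotypes(encoding: HaplotypeEncoding, method: str = "average") -> ClusterResult:
    """Cluster samples on Hamming distance over the one-hot matrix."""
    mat = encoding.matrix.to_numpy(dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = linkage(pdist(mat, metric="hamming"), method=method)
    labels = tuple(encoding.matrix.index)
    order = tuple(labels[i] for i in leaves_list(Z))
    return ClusterResult(labels, Z, order, _to_newick(Z, labels))


def annotate_known(
    run: SampleRun,
    reference_sets: Mapping[str, Iterable[str]],
    length: int | None = 9,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Flag run peptides found in named reference ligand sets.

    Matching is exact on sequence.  ``length`` restricts the comparison
    (default 9mers, the convention for literature comparisons); ``None``
    uses all peptides.  Returns the per-peptide boolean table and per-set
    percentages (NaN for an empty reference set).
    """
    peptides = sorted(
        s for s in run.sequences if length is None or len(s) == length
    )
    table = pd.DataFrame({"peptide": peptides})
    percents: dict[str, float] = {}
    for name, ref in reference_sets.items():
        refset = {p.upper() for p in ref}
        flags = [p in refset for p in peptides]
        table[name] = flags
        if not refset or not peptides:
            percents[name] = float("nan")
        else:
            percents[name] = 100.0 * sum(flags) / len(peptides)
    return table, percents
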