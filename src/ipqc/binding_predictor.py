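"""Peptide-MHC binding scoring, empirical rank percentiles and SB/WB/nB
classification.

The built-in scorer is a per-allele, per-length position-specific scoring
matrix (PSSM) of log-odds against a residue background.  Because absolute
PSSM scores are not comparable across alleles, each allele is calibrated
against an empirical background: ``n_background`` random peptides are drawn
from the background distribution, scored and sorted, and a query peptide's
*rank percentile* is the percentage of background peptides scoring at least
as high.  This is the "% rank" convention of the mainstream MHC binding
predictors, and it makes ranks comparable across alleles so that the best
(lowest-rank) allele can be reported per peptide.

Class thresholds follow the standard convention: strong binder (SB) below
0.5% rank, weak binder (WB) from 0.5% to 2%, non-binder (nB) above 2%.

A surrogate affinity in nM is derived from the score quantile ``s`` within
the calibration sample as ``50000**(1 - s)``, the classical mapping between
a (0, 1] binding signal and the nanomolar scale; it exists so that
affinity-threshold criteria (e.g. "< 50 nM") are expressible with the
built-in scorer.  When an external predictor backend is plugged in, its
native nM values are used instead.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .peptidome_io import CANONICAL_AA

AA_TO_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}
N_RESIDUES = 20
SUPPORTED_LENGTHS = range(8, 14)

SB_MAX_RANK = 0.5   # rank < 0.5  -> strong binder
WB_MAX_RANK = 2.0   # 0.5 <= rank <= 2 -> weak binder
MAX_AFFINITY_NM = 50_000.0

_ENCODER = np.full(128, 255, dtype=np.uint8)
for _aa, _i in AA_TO_INDEX.items():
    _ENCODER[ord(_aa)] = _i


def encode_peptides(peptides: Sequence[str]) -> np.ndarray:
    """Encode equal-length peptides as an (n, L) array of residue indices."""
    arr = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    idx = _ENCODER[arr]
    if (idx == 255).any():
        raise ValueError("peptide contains non-canonical residue")
    return idx.reshape(len(peptides), -1)


def uniform_background() -> np.ndarray:
    return np.full(N_RESIDUES, 1.0 / N_RESIDUES)


def proteome_background(sequences: Iterable[str]) -> np.ndarray:
    """Residue frequencies estimated from protein sequences."""
    counts = np.zeros(N_RESIDUES)
    for seq in sequences:
        idx = _ENCODER[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        counts += np.bincount(idx[idx != 255], minlength=N_RESIDUES)
    if counts.sum() == 0:
        raise ValueError("no canonical residues in background sequences")
    return counts / counts.sum()


def classify_rank(rank_percentile: float) -> str:
    """SB/WB/nB class from a rank percentile (NaN -> nB)."""
    if not math.isfinite(rank_percentile):
        return "nB"
    if rank_percentile < SB_MAX_RANK:
        return "SB"
    if rank_percentile <= WB_MAX_RANK:
        return "WB"
    return "nB"


# ---------------------------------------------------------------------------
# PSSM model
# ---------------------------------------------------------------------------


@dataclass
class PssmModel:
    """Per-length position log-odds matrices for one allele.

    ``matrices[L]`` has shape (L, 20); entry ``[i, a]`` is
    ``log((count[i, a] + pc * bg[a]) / (N + pc) / bg[a])`` for training
    counts ``count``, pseudocount ``pc`` and background ``bg``.
    """

    allele: str
    matrices: dict[int, np.ndarray] = field(default_factory=dict)
    background: np.ndarray = field(default_factory=uniform_background)
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (N_RESIDUES,) or (bg <= 0).any():
            raise ValueError("background must be 20 strictly positive frequencies")
        if abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        self.background = bg
        for length, mat in self.matrices.items():
            if length not in SUPPORTED_LENGTHS:
                raise ValueError(f"unsupported peptide length {length}")
            if mat.shape != (length, N_RESIDUES):
                raise ValueError("matrix shape must be (length, 20)")

    @property
    def supported_lengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.matrices))

    def score_many(self, peptides: Sequence[str]) -> np.ndarray:
        """Vectorised scores for equal-length peptides."""
        if not peptides:
            return np.empty(0)
        length = len(peptides[0])
        if length not in self.matrices:
            raise ValueError(f"length {length} not supported by model {self.allele}")
        idx = encode_peptides(peptides)
        mat = self.matrices[length]
        return mat[np.arange(length), idx].sum(axis=1)

    def score_encoded(self, idx: np.ndarray) -> np.ndarray:
        length = idx.shape[1]
        mat = self.matrices[length]
        return mat[np.arange(length), idx].sum(axis=1)


def build_pssm(
    binders: Sequence[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    allele: str = "synthetic",
) -> PssmModel:
    """Estimate a PSSM from equal-length binder sequences.

    Requires at least 10 sequences of a single supported length.  The
    returned model holds one per-length matrix; use :func:`extend_pssm` to
    accumulate further lengths onto an existing model.
    """
    if not binders:
        raise ValueError("no binder sequences provided")
    lengths = {len(s) for s in binders}
    if len(lengths) != 1:
        raise ValueError(f"mixed binder lengths: {sorted(lengths)}")
    if len(binders) < 10:
        raise ValueError("need at least 10 binder sequences")
    length = lengths.pop()
    bg = uniform_background() if background is None else np.asarray(background, float)
    idx = encode_peptides(binders)
    counts = np.zeros((length, N_RESIDUES))
    for i in range(length):
        counts[i] = np.bincount(idx[:, i], minlength=N_RESIDUES)
    n = len(binders)
    with np.errstate(divide="ignore"):
        mat = np.log((counts + pseudocount * bg) / (n + pseudocount) / bg)
    return PssmModel(allele=allele, matrices={length: mat},
                     background=bg, pseudocount=pseudocount)


def extend_pssm(model: PssmModel, binders: Sequence[str]) -> PssmModel:
    """Add a matrix for a further length to an existing model (in place)."""
    addition = build_pssm(binders, model.pseudocount, model.background, model.allele)
    (length,) = addition.supported_lengths
    if length in model.matrices:
        raise ValueError(f"model already supports length {length}")
    model.matrices[length] = addition.matrices[length]
    return model


def score_peptide(model: PssmModel, peptide: str) -> float:
    """Sum of per-position log-odds entries for one peptide."""
    return float(model.score_many([peptide])[0])


# ---------------------------------------------------------------------------
# rank calibration
# ---------------------------------------------------------------------------


@dataclass
class RankCalibration:
    """Sorted background score samples defining rank percentiles.

    ``rank(p) = 100 * #{background scores >= score(p)} / n_background``.
    The background sample is reproducible from ``(seed, n_background)``.
    """

    allele: str
    samples: dict[int, np.ndarray]
    n_background: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_background < 1000:
            raise ValueError("n_background must be >= 1000")

    def rank_of_scores(self, length: int, scores: np.ndarray) -> np.ndarray:
        sample = self.samples[length]
        n_below = np.searchsorted(sample, scores, side="left")
        return 100.0 * (self.n_background - n_below) / self.n_background

    def quantile_of_scores(self, length: int, scores: np.ndarray) -> np.ndarray:
        """Fraction of background scores strictly below each score."""
        sample = self.samples[length]
        return np.searchsorted(sample, scores, side="left") / self.n_background


def sample_background_peptides(
    rng: np.random.Generator, n: int, length: int, background: np.ndarray
) -> np.ndarray:
    """(n, length) residue-index array drawn i.i.d. from the background."""
    return rng.choice(N_RESIDUES, size=(n, length), p=background)


def calibrate_ranks(
    model: PssmModel, n_background: int = 100_000, seed: int = 0
) -> RankCalibration:
    """Draw, score and sort a background sample per supported length."""
    if n_background < 1000:
        raise ValueError("n_background must be >= 1000")
    rng = np.random.default_rng(seed)
    samples = {}
    for length in model.supported_lengths:
        idx = sample_background_peptides(rng, n_background, length, model.background)
        samples[length] = np.sort(model.score_encoded(idx))
    return RankCalibration(model.allele, samples, n_background, seed)


def affinity_from_quantile(s: np.ndarray | float) -> np.ndarray | float:
    """Surrogate affinity ``50000**(1 - s)`` (nM), strictly decreasing in s."""
    return MAX_AFFINITY_NM ** (1.0 - np.asarray(s, dtype=float))


#: score quantile above which the surrogate affinity drops below 50 nM
AFFINITY_50NM_QUANTILE = 1.0 - math.log(50.0) / math.log(MAX_AFFINITY_NM)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingPrediction:
    """Best-allele (or per-allele) binding call for one peptide."""

    peptide: str
    allele: str
    rank_percentile: float
    affinity_nM: float
    binder_class: str


@runtime_checkable
class PredictorBackend(Protocol):
    """Contract for pluggable binding predictors (built-in PSSM or external
    tools): per-(peptide, allele) affinity in nM and rank percentile."""

    def predict_table(self, peptides: Sequence[str], haplotype: Sequence[str]) -> pd.DataFrame:
        """Best-allele call per peptide: columns peptide, allele, rank,
        affinity_nM, binder_class."""
        ...

    def predict_per_allele(self, peptides: Sequence[str], haplotype: Sequence[str]) -> pd.DataFrame:
        """Long table with one row per (peptide, allele)."""
        ...


class PssmPredictor:
    """Built-in predictor: per-allele PSSMs plus rank calibrations.

    Best-allele deconvolution picks the minimal rank percentile across the
    haplotype; ties break to the alphabetically first allele.  Peptides
    whose length no haplotype allele supports are returned unassignable
    (allele ``"none"``, class nB).
    """

    def __init__(
        self,
        models: dict[str, PssmModel],
        calibrations: dict[str, RankCalibration],
    ) -> None:
        if set(models) != set(calibrations):
            raise ValueError("models and calibrations must cover the same alleles")
        self.models = models
        self.calibrations = calibrations

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(sorted(self.models))

    def _alleles_for(self, haplotype: Sequence[str]) -> list[str]:
        known = [a for a in dict.fromkeys(haplotype) if a in self.models]
        return sorted(known)

    def predict_per_allele(
        self, peptides: Sequence[str], haplotype: Sequence[str]
    ) -> pd.DataFrame:
        alleles = self._alleles_for(haplotype)
        peptides = list(peptides)
        by_length: dict[int, list[int]] = {}
        for i, p in enumerate(peptides):
            by_length.setdefault(len(p), []).append(i)
        rows = []
        for length, indices in sorted(by_length.items()):
            batch = [peptides[i] for i in indices]
            for allele in alleles:
                model = self.models[allele]
                if length not in model.matrices:
                    continue
                scores = model.score_many(batch)
                cal = self.calibrations[allele]
                ranks = cal.rank_of_scores(length, scores)
                affinities = affinity_from_quantile(cal.quantile_of_scores(length, scores))
                for pep, r, aff in zip(batch, ranks, affinities):
                    rows.append((pep, allele, float(r), float(aff)))
        df = pd.DataFrame(rows, columns=["peptide", "allele", "rank", "affinity_nM"])
        if not df.empty:
            df["binder_class"] = [classify_rank(r) for r in df["rank"]]
        else:
            df["binder_class"] = pd.Series(dtype=str)
        return df

    def predict_table(
        self, peptides: Sequence[str], haplotype: Sequence[str]
    ) -> pd.DataFrame:
        """Best-allele call per input peptide (input order preserved)."""
        peptides = list(peptides)
        per_allele = self.predict_per_allele(peptides, haplotype)
        best: dict[str, tuple[float, str, float]] = {}
        for row in per_allele.itertuples(index=False):
            cur = best.get(row.peptide)
            # min rank; ties to the alphabetically first allele (rows arrive
            # in sorted allele order, so strict < keeps the first)
            if cur is None or row.rank < cur[0]:
                best[row.peptide] = (row.rank, row.allele, row.affinity_nM)
        records = []
        for pep in peptides:
            if pep in best:
                rank, allele, aff = best[pep]
                records.append((pep, allele, rank, aff, classify_rank(rank)))
            else:
                records.append((pep, "none", float("nan"), float("nan"), "nB"))
        return pd.DataFrame(
            records, columns=["peptide", "allele", "rank", "affinity_nM", "binder_class"]
        )

    def predict_best(self, peptide: str, haplotype: Sequence[str]) -> BindingPrediction:
        row = self.predict_table([peptide], haplotype).iloc[0]
        return BindingPrediction(
            peptide, row["allele"], float(row["rank"]),
            float(row["affinity_nM"]), row["binder_class"],
        )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {}
        for allele in self.alleles:
            model = self.models[allele]
            cal = self.calibrations[allele]
            payload[allele] = {
                "pseudocount": model.pseudocount,
                "background": model.background.tolist(),
                "matrices": {str(L): m.tolist() for L, m in model.matrices.items()},
                "calibration": {"n_background": cal.n_background, "seed": cal.seed},
            }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PssmPredictor":
        payload = json.loads(text)
        models, calibrations = {}, {}
        for allele, entry in payload.items():
            model = PssmModel(
                allele=allele,
                matrices={int(L): np.asarray(m) for L, m in entry["matrices"].items()},
                background=np.asarray(entry["background"]),
                pseudocount=entry["pseudocount"],
            )
            models[allele] = model
            cal_meta = entry["calibration"]
            calibrations[allele] = calibrate_ranks(
                model, cal_meta["n_background"], cal_meta["seed"]
            )
        return cls(models, calibrations)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PssmPredictor":
        return cls.from_json(Path(path).read_text())


def predict(
    peptide: str, haplotype: Sequence[str], predictor: PredictorBackend
) -> tuple[BindingPrediction, list[BindingPrediction]]:
    """Best binding call plus the per-allele list for one peptide."""
    per_allele = predictor.predict_per_allele([peptide], haplotype)
    all_preds = [
        BindingPrediction(row.peptide, row.allele, row.rank, row.affinity_nM, row.binder_class)
        for row in per_allele.itertuples(index=False)
    ]
    best_df = predictor.predict_table([peptide], haplotype).iloc[0]
    best = BindingPrediction(
        peptide, best_df["allele"], float(best_df["rank"]),
        float(best_df["affinity_nM"]), best_df["binder_class"],
    )
    return best, all_preds
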