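"""Self-contained synthetic fixtures with known ground truth.

The generator emulates the statistical structure of an MHC class I
immunopeptidomics experiment: a random proteome, per-allele anchor motifs
(canonical P2 + C-terminal anchor layout), runs that mix motif-consistent
peptides with fully random noise at a 9mer-peaked length distribution,
proteolytic "ladder" contaminants (nested offset-shifted fragments of one
protein), log-normal intensities, and tumor-vs-healthy expression tables.
Every generator is a pure function of its configuration and seed, and each
run ships a ground-truth table (generating allele, noise flag, source
protein) sufficient to score any downstream recovery metric without
re-inference.

Anchors are modelled as near-obligatory (default concentration 0.99): the
anchor residue is drawn with that probability, independently per anchor
position, and the background residue distribution is used everywhere else.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding_predictor import (
    AA_TO_INDEX,
    N_RESIDUES,
    PssmPredictor,
    build_pssm,
    calibrate_ranks,
    extend_pssm,
    uniform_background,
)
from .peptidome_io import CANONICAL_AA, PeptideRecord, ProteinDb, SampleRun

_CHARS = np.frombuffer(CANONICAL_AA.encode("ascii"), dtype="S1")

DEFAULT_LENGTH_DIST: dict[int, float] = {
    8: 0.08, 9: 0.55, 10: 0.12, 11: 0.10, 12: 0.08, 13: 0.07,
}
NOISE_LENGTH_DIST: dict[int, float] = {L: 1 / 6 for L in range(8, 14)}


@dataclass(frozen=True)
class AlleleMotif:
    """Synthetic allele: anchor positions (1-based; -1 = C-terminus) with a
    single preferred residue each, drawn at the given concentration."""

    name: str
    anchors: tuple[tuple[int, str], ...] = ((2, "L"), (-1, "V"))
    concentration: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 < self.concentration <= 1.0:
            raise ValueError("anchor concentration must be in (0, 1]")
        if self.concentration <= 1.0 / N_RESIDUES:
            raise ValueError("anchor concentration must exceed the background")
        for pos, res in self.anchors:
            if pos == 0 or res not in AA_TO_INDEX:
                raise ValueError(f"bad anchor ({pos}, {res})")

    def anchor_indices(self, length: int) -> list[tuple[int, int]]:
        """(0-based position, residue index) pairs for a peptide length."""
        out = []
        for pos, res in self.anchors:
            idx = pos - 1 if pos > 0 else length + pos
            if not 0 <= idx < length:
                raise ValueError(f"anchor position {pos} outside length {length}")
            out.append((idx, AA_TO_INDEX[res]))
        return out


DEFAULT_ALLELES: tuple[AlleleMotif, ...] = (
    AlleleMotif("A02:01", ((2, "L"), (-1, "V"))),
    AlleleMotif("B07:02", ((2, "P"), (-1, "L"))),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a typical cell-line run: ~1000 unique peptides, 15%
    non-binder noise, a length distribution peaked at nine residues (55% of
    motif peptides), two alleles with disjoint near-obligatory anchors, and
    a 200-protein random proteome.
    """

    seed: int = 0
    n_proteins: int = 200
    protein_length_range: tuple[int, int] = (150, 500)
    alleles: tuple[AlleleMotif, ...] = DEFAULT_ALLELES
    n_peptides: int = 1000
    allele_proportions: tuple[float, ...] | None = None  # default: equal split
    noise_fraction: float = 0.15
    length_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DIST)
    )
    noise_length_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(NOISE_LENGTH_DIST)
    )
    background: tuple[float, ...] = tuple(uniform_background())
    embed_in_proteome: bool = False
    intensity_log_mean: float = 10.0
    intensity_log_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        props = self.mixture_proportions()
        if abs(sum(props) + 0 - 1.0) > 1e-9:
            raise ValueError("proportions plus noise fraction must sum to 1")
        for dist in (self.length_dist, self.noise_length_dist):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("length distribution must sum to 1")

    def mixture_proportions(self) -> tuple[float, ...]:
        """Per-component proportions: one per allele, then noise; sums to 1."""
        n = len(self.alleles)
        if self.allele_proportions is None:
            motif = (1.0 - self.noise_fraction) / n if n else 0.0
            allele_props = (motif,) * n
        else:
            allele_props = self.allele_proportions
        return (*allele_props, self.noise_fraction)

    @property
    def haplotype(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.alleles)


def config_from_dict(data: Mapping) -> SyntheticConfig:
    """Build a config from a YAML-style mapping."""
    data = dict(data)
    if "alleles" in data:
        data["alleles"] = tuple(
            AlleleMotif(
                a["name"],
                tuple((int(p), r) for p, r in a.get("anchors", ((2, "L"), (-1, "V")))),
                a.get("concentration", 0.99),
            )
            for a in data["alleles"]
        )
    for key in ("protein_length_range", "allele_proportions", "background"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    for key in ("length_dist", "noise_length_dist"):
        if key in data:
            data[key] = {int(k): float(v) for k, v in data[key].items()}
    return SyntheticConfig(**data)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % 2**31 for s in state]


def _indices_to_strings(indices: np.ndarray) -> list[str]:
    if indices.size == 0:
        return []
    length = indices.shape[1]
    return [
        b.decode("ascii")
        for b in _CHARS[indices].reshape(len(indices), length).view(f"S{length}").ravel()
    ]


def _draw_background(
    rng: np.random.Generator, n: int, length: int, background: np.ndarray
) -> np.ndarray:
    return rng.choice(N_RESIDUES, size=(n, length), p=background)


def draw_motif_peptides(
    rng: np.random.Generator,
    allele: AlleleMotif,
    n: int,
    length: int,
    background: np.ndarray,
) -> list[str]:
    """Sample peptides from an allele's motif: anchor residue with the
    configured concentration at each anchor position, background elsewhere."""
    idx = _draw_background(rng, n, length, background)
    for pos, res_idx in allele.anchor_indices(length):
        mask = rng.random(n) < allele.concentration
        idx[mask, pos] = res_idx
    return _indices_to_strings(idx)


def generate_proteome(config: SyntheticConfig, seed: int | None = None) -> ProteinDb:
    """Random proteome: i.i.d. residues from the background distribution,
    lengths uniform over the configured range, accessions SYN0001.."""
    if config.n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.protein_length_range
    background = np.asarray(config.background)
    sequences = {}
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        idx = _draw_background(rng, 1, length, background)
        sequences[f"SYN{i + 1:04d}"] = _indices_to_strings(idx)[0]
    return ProteinDb(sequences)


def generate_run(
    config: SyntheticConfig,
    proteome: ProteinDb | None = None,
    sample_id: str = "s1",
    replicate_id: str = "r1",
    tissue_label: str = "cell_line",
    seed: int | None = None,
) -> tuple[SampleRun, pd.DataFrame]:
    """One synthetic replicate plus its ground-truth table.

    Components (one per allele, plus noise) are drawn multinomially at the
    configured proportions; lengths come from the motif or noise length
    distribution.  Each peptide is attributed to a uniformly chosen source
    protein of the proteome (or a placeholder accession without one).  With
    ``embed_in_proteome`` every peptide is an actual proteome window
    instead (used when scan completeness is under test); such peptides
    carry no generating allele.

    Ground-truth columns: peptide, allele ("" for noise/embedded),
    is_noise, length, source.  Duplicate sequences are collapsed in the run
    (max intensity) and deduplicated in the truth table (first label kept).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    background = np.asarray(config.background)
    truth_rows: list[tuple[str, str, bool, int, str]] = []

    accessions = sorted(proteome.sequences) if proteome is not None else None

    def pick_source(n: int) -> list[str]:
        if accessions is None:
            return [f"SRC{int(i) + 1:04d}" for i in rng.integers(0, config.n_proteins, n)]
        return [accessions[int(i)] for i in rng.integers(0, len(accessions), n)]

    if config.embed_in_proteome:
        if proteome is None:
            raise ValueError("embed_in_proteome requires a proteome")
        lengths_support = sorted(config.length_dist)
        probs = np.array([config.length_dist[L] for L in lengths_support])
        lengths = rng.choice(lengths_support, size=config.n_peptides, p=probs)
        prot_idx = rng.integers(0, len(accessions), config.n_peptides)
        for L, pi in zip(lengths, prot_idx):
            acc = accessions[int(pi)]
            seq = proteome[acc]
            start = int(rng.integers(0, len(seq) - int(L) + 1))
            pep = seq[start : start + int(L)]
            truth_rows.append((pep, "", True, int(L), acc))
    else:
        proportions = config.mixture_proportions()
        comp_counts = rng.multinomial(config.n_peptides, proportions)
        components: list[AlleleMotif | None] = [*config.alleles, None]
        for comp, n_comp in zip(components, comp_counts):
            if n_comp == 0:
                continue
            dist = config.length_dist if comp is not None else config.noise_length_dist
            lengths_support = sorted(dist)
            probs = np.array([dist[L] for L in lengths_support])
            per_length = rng.multinomial(n_comp, probs)
            for L, n_batch in zip(lengths_support, per_length):
                if n_batch == 0:
                    continue
                if comp is None:
                    peptides = _indices_to_strings(
                        _draw_background(rng, n_batch, L, background)
                    )
                    label, is_noise = "", True
                else:
                    peptides = draw_motif_peptides(rng, comp, n_batch, L, background)
                    label, is_noise = comp.name, False
                for pep, src in zip(peptides, pick_source(n_batch)):
                    truth_rows.append((pep, label, is_noise, L, src))

    intensities = rng.lognormal(
        config.intensity_log_mean, config.intensity_log_sigma, len(truth_rows)
    )
    run = SampleRun(
        sample_id=sample_id,
        replicate_id=replicate_id,
        haplotype=config.haplotype,
        tissue_label=tissue_label,
    )
    for (pep, _, _, _, src), intensity in zip(truth_rows, intensities):
        run.add(PeptideRecord(pep, (src,), float(intensity), sample_id, replicate_id))

    truth = pd.DataFrame(
        truth_rows, columns=["peptide", "allele", "is_noise", "length", "source"]
    ).drop_duplicates(subset="peptide", keep="first").reset_index(drop=True)
    return run, truth


DEFAULT_LADDER_FRAGMENTS = 20
DEFAULT_FRAGMENT_LENGTH = 15  # proteolytic contaminants skew long


def inject_contaminant_ladder(
    run: SampleRun,
    proteome: ProteinDb,
    accession: str,
    n_fragments: int = DEFAULT_LADDER_FRAGMENTS,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    start: int = 0,
) -> tuple[SampleRun, list[str]]:
    """Add a proteolytic ladder: ``n_fragments`` windows of one protein at
    consecutive offsets.  Returns the augmented run (a copy) and the
    injected sequences.  Errors if the protein is too short."""
    seq = proteome[accession]
    needed = start + n_fragments + fragment_length - 1
    if len(seq) < needed:
        raise ValueError(
            f"protein {accession} too short ({len(seq)} < {needed}) for ladder"
        )
    augmented = SampleRun(
        sample_id=run.sample_id,
        replicate_id=run.replicate_id,
        haplotype=run.haplotype,
        tissue_label=run.tissue_label,
    )
    for rec in run:
        augmented.add(rec)
    injected = []
    for offset in range(start, start + n_fragments):
        frag = seq[offset : offset + fragment_length]
        injected.append(frag)
        augmented.add(
            PeptideRecord(frag, (accession,), None, run.sample_id, run.replicate_id)
        )
    return augmented, injected


def generate_expression_table(
    genes: Sequence[str],
    fraction_upregulated: float = 0.3,
    logfc_high_range: tuple[float, float] = (3.0, 6.0),
    logfc_low_range: tuple[float, float] = (-1.0, 1.5),
    seed: int = 0,
    threshold: float = 2.0,
) -> tuple[dict[str, float], frozenset[str]]:
    """Gene -> log fold change with labelled ground truth.

    The upregulated fraction is drawn uniformly from the high range, the
    rest from the low range; the ranges must sit on opposite sides of the
    threshold so the pass set equals the upregulated label set exactly.
    """
    if not logfc_low_range[1] <= threshold < logfc_high_range[0]:
        raise ValueError("logFC ranges must be disjoint across the threshold")
    if not 0.0 <= fraction_upregulated <= 1.0:
        raise ValueError("fraction_upregulated must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n_up = round(fraction_upregulated * len(genes))
    up = set(rng.choice(len(genes), size=n_up, replace=False).tolist())
    table = {}
    for i, gene in enumerate(genes):
        lo, hi = logfc_high_range if i in up else logfc_low_range
        table[gene] = float(rng.uniform(lo, hi))
    return table, frozenset(genes[i] for i in up)


def fit_predictor(
    config: SyntheticConfig,
    n_train: int = 300,
    n_background: int = 20_000,
    pseudocount: float = 1.0,
    seed: int | None = None,
) -> PssmPredictor:
    """Train the built-in PSSM predictor on motif-sampled binders.

    For each configured allele and each supported length, ``n_train``
    peptides are drawn from the allele's motif and a per-length PSSM is
    estimated; rank calibration uses ``n_background`` background peptides
    with a deterministically derived seed.
    """
    base_seed = config.seed if seed is None else seed
    lengths = sorted(config.length_dist)
    seeds = _child_seeds(base_seed, 2 * len(config.alleles))
    background = np.asarray(config.background)
    models, calibrations = {}, {}
    for i, allele in enumerate(config.alleles):
        train_rng = np.random.default_rng(seeds[2 * i])
        model = None
        for length in lengths:
            binders = draw_motif_peptides(train_rng, allele, n_train, length, background)
            if model is None:
                model = build_pssm(binders, pseudocount, background, allele.name)
            else:
                extend_pssm(model, binders)
        models[allele.name] = model
        calibrations[allele.name] = calibrate_ranks(model, n_background, seeds[2 * i + 1])
    return PssmPredictor(models, calibrations)


def generate_candidate_cohort(
    seed: int = 0,
    n_true: int = 15,
    n_distractors_per_class: int = 10,
    n_runs: int = 4,
) -> tuple[list[SampleRun], dict, dict[str, float], dict[str, list[str]], frozenset[str]]:
    """Cohort with planted true vaccine candidates and one-fault distractors.

    ``n_true`` 9mers satisfy every default selection criterion (affinity
    below 50 nM, source-gene log fold change above 2, found in at least 3
    of ``n_runs`` replicates); each distractor violates exactly one of the
    three criteria.  Returns (runs, predictions, expression, peptide->gene
    map, true-candidate set).
    """
    from .binding_predictor import BindingPrediction, classify_rank

    rng = np.random.default_rng(seed)
    background = uniform_background()

    def fresh_peptides(n: int, taken: set[str]) -> list[str]:
        out: list[str] = []
        while len(out) < n:
            for pep in _indices_to_strings(_draw_background(rng, n, 9, background)):
                if pep not in taken and pep not in out:
                    out.append(pep)
                    if len(out) == n:
                        break
        return out

    taken: set[str] = set()
    groups = {}
    for name in ("true", "bad_affinity", "bad_logfc", "bad_replicates"):
        n = n_true if name == "true" else n_distractors_per_class
        groups[name] = fresh_peptides(n, taken)
        taken.update(groups[name])

    predictions: dict[str, BindingPrediction] = {}
    expression: dict[str, float] = {}
    peptide_genes: dict[str, list[str]] = {}
    membership: dict[str, list[int]] = {}

    def plant(pep: str, gene: str, affinity_ok: bool, logfc_ok: bool, reps_ok: bool):
        affinity = float(rng.uniform(5, 45) if affinity_ok else rng.uniform(80, 500))
        rank = float(rng.uniform(0.01, 0.4) if affinity_ok else rng.uniform(2.5, 20))
        predictions[pep] = BindingPrediction(pep, "A02:01", rank, affinity,
                                             classify_rank(rank))
        expression[gene] = float(rng.uniform(3, 5) if logfc_ok else rng.uniform(-1, 1.5))
        peptide_genes[pep] = [gene]
        n_in = int(rng.integers(3, n_runs + 1)) if reps_ok else int(rng.integers(1, 3))
        membership[pep] = sorted(rng.choice(n_runs, size=n_in, replace=False).tolist())

    gene_counter = iter(range(1, 10_000))
    for name, peptides in groups.items():
        for pep in peptides:
            plant(
                pep, f"G{next(gene_counter):04d}",
                affinity_ok=name != "bad_affinity",
                logfc_ok=name != "bad_logfc",
                reps_ok=name != "bad_replicates",
            )

    runs = []
    for i in range(n_runs):
        run = SampleRun("s1", f"r{i + 1}", haplotype=("A02:01",), tissue_label="tumor")
        for pep, idxs in membership.items():
            if i in idxs:
                run.add(PeptideRecord(pep, (), None, "s1", f"r{i + 1}"))
        runs.append(run)
    return runs, predictions, expression, peptide_genes, frozenset(groups["true"])


def generate_cohort(
    config: SyntheticConfig,
    n_replicates: int,
    proteome: ProteinDb | None = None,
    sample_id: str = "s1",
    tissue_label: str = "cell_line",
) -> tuple[list[SampleRun], pd.DataFrame]:
    """Several replicates of one sample, with per-replicate derived seeds."""
    seeds = _child_seeds(config.seed, n_replicates + 1)[1:]
    runs, truths = [], []
    for i, s in enumerate(seeds):
        run, truth = generate_run(
            config, proteome, sample_id, f"r{i + 1}", tissue_label, seed=s
        )
        truth = truth.assign(replicate_id=f"r{i + 1}")
        runs.append(run)
        truths.append(truth)
    return runs, pd.concat(truths, ignore_index=True)
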