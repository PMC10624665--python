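"""Proteolytic-contaminant detection and removal via the protein coverage
ratio.

Proteolytic contaminants in an eluted-peptide run show up as a "ladder" of
nested, offset-shifted fragments from one source protein — far more
sequence coverage than genuine MHC presentation produces.  The statistic
used to detect them is the *protein coverage ratio*: for a protein P of
length L(P) bearing eluted class I peptides p,

    ratio(P) = (1 / L(P)) * sum over p of L(p)

i.e. the average number of eluted-peptide residues per amino acid of the
protein.  A cutoff is calibrated from runs known to be clean (e.g. cell
lines): each clean run contributes the 95th percentile of its own ratio
distribution, and the cutoff is the mean of those percentiles.  Proteins
above the cutoff are flagged; a peptide is removed only if *every* protein
it maps to is flagged, so ligands shared with an unflagged protein survive.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptidome_io import ProteinDb, SampleRun

logger = logging.getLogger(__name__)

CLEAN_RUN_MIN_PROTEINS = 20
CUTOFF_PERCENTILE = 95.0


@dataclass(frozen=True)
class CoverageRatioResult:
    """Coverage-ratio statistic for one protein in one run."""

    accession: str
    protein_length: int
    n_peptides: int
    sum_peptide_lengths: int
    ratio: float
    flagged: bool = False
    cutoff_used: float = float("nan")


@dataclass(frozen=True)
class CutoffCalibration:
    """Clean-run 95th percentiles and their mean, used as the flag cutoff."""

    clean_run_ids: tuple[str, ...]
    percentiles: tuple[float, ...]
    cutoff: float
    quantile_method: str = "linear"


def protein_coverage_ratio(
    run: SampleRun, proteins: ProteinDb
) -> list[CoverageRatioResult]:
    """Coverage ratio for every protein with at least one mapped peptide.

    Peptides mapping to k proteins contribute their length to all k.
    Source accessions absent from the database are skipped with a warning.
    Results are sorted by accession.
    """
    sums: dict[str, int] = {}
    counts: dict[str, int] = {}
    missing: set[str] = set()
    for record in run:
        for acc in record.source_proteins:
            if acc not in proteins:
                missing.add(acc)
                continue
            sums[acc] = sums.get(acc, 0) + record.length
            counts[acc] = counts.get(acc, 0) + 1
    if missing:
        logger.warning(
            "run %s: %d source accession(s) not in protein db, skipped",
            run.run_id, len(missing),
        )
    return [
        CoverageRatioResult(
            accession=acc,
            protein_length=proteins.length(acc),
            n_peptides=counts[acc],
            sum_peptide_lengths=sums[acc],
            ratio=sums[acc] / proteins.length(acc),
        )
        for acc in sorted(sums)
    ]


def coverage_table(results: Sequence[CoverageRatioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": r.accession,
                "protein_length": r.protein_length,
                "n_peptides": r.n_peptides,
                "sum_peptide_lengths": r.sum_peptide_lengths,
                "ratio": r.ratio,
                "flagged": r.flagged,
            }
            for r in results
        ],
        columns=["protein", "protein_length", "n_peptides",
                 "sum_peptide_lengths", "ratio", "flagged"],
    )


def calibrate_cutoff(
    clean_runs: Sequence[SampleRun], proteins: ProteinDb
) -> CutoffCalibration:
    """Mean of per-clean-run 95th percentiles of the ratio distribution.

    Runs covering fewer than 20 proteins are excluded with a warning; the
    quantile uses linear interpolation (the common type-7 default), which
    is recorded in the calibration for reproducibility.
    """
    if not clean_runs:
        raise ValueError("need at least one clean run")
    ids, percentiles = [], []
    for run in clean_runs:
        ratios = np.array([r.ratio for r in protein_coverage_ratio(run, proteins)])
        if ratios.size < CLEAN_RUN_MIN_PROTEINS:
            logger.warning(
                "clean run %s excluded: only %d covered protein(s)",
                run.run_id, ratios.size,
            )
            continue
        ids.append(run.run_id)
        percentiles.append(
            float(np.percentile(ratios, CUTOFF_PERCENTILE, method="linear"))
        )
    if not ids:
        raise ValueError("all clean runs excluded (too few covered proteins)")
    return CutoffCalibration(
        clean_run_ids=tuple(ids),
        percentiles=tuple(percentiles),
        cutoff=float(np.mean(percentiles)),
    )


def flag_and_clean(
    run: SampleRun, proteins: ProteinDb, cutoff: float
) -> tuple[SampleRun, list[CoverageRatioResult]]:
    """Flag proteins with ratio above the cutoff and curate the run.

    A peptide is removed iff all of its source proteins are flagged;
    peptides with any unflagged (or unknown) source are retained.  Returns
    the curated run and the per-protein flag report.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    results = protein_coverage_ratio(run, proteins)
    flagged = {r.accession for r in results if r.ratio > cutoff}
    report = [
        CoverageRatioResult(
            r.accession, r.protein_length, r.n_peptides, r.sum_peptide_lengths,
            r.ratio, flagged=r.accession in flagged, cutoff_used=cutoff,
        )
        for r in results
    ]
    curated = SampleRun(
        sample_id=run.sample_id,
        replicate_id=run.replicate_id,
        haplotype=run.haplotype,
        tissue_label=run.tissue_label,
    )
    n_removed = 0
    for record in run:
        sources = set(record.source_proteins)
        if sources and sources <= flagged:
            n_removed += 1
            continue
        curated.add(record)
    logger.info(
        "run %s: flagged %d protein(s), removed %d peptide(s) at cutoff %.4g",
        run.run_id, len(flagged), n_removed, cutoff,
    )
    return curated, report
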