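"""Consolidated QC report: the dashboard battery as a static JSON/TSV
bundle (length distributions, binder fractions, specificity composition,
replicate overlaps), reproducible from the echoed configuration."""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from pathlib import Path

from . import __version__
from .binding_predictor import PredictorBackend, PssmPredictor
from .peptidome_io import SampleRun
from .qc_metrics import (
    binder_fraction,
    deconvolute_specificity,
    length_distribution,
    overlap_sets_table,
    replicate_overlap_sets,
)


def _nan_to_none(x: float) -> float | None:
    return None if x != x else x


def run_qc(
    runs: Sequence[SampleRun],
    predictor: PredictorBackend,
    deconvolution_lengths: Sequence[int] = (9,),
    config_echo: Mapping | None = None,
) -> dict:
    """Compute the full QC battery for a set of runs.

    Returns a JSON-serialisable report with, per run: the length
    distribution, binder fractions for the 8-13 window and for 9mers, and
    the specificity composition; plus the exclusive replicate-overlap
    table when two or more runs are given.
    """
    if not runs:
        raise ValueError("no runs provided")
    per_run = []
    for run in runs:
        dist = length_distribution(run)
        comp, _ = deconvolute_specificity(run, predictor, deconvolution_lengths)
        per_run.append(
            {
                "run_id": run.run_id,
                "n_peptides": len(run),
                "haplotype": list(run.haplotype),
                "tissue_label": run.tissue_label,
                "length_counts": {str(k): v for k, v in sorted(dist.counts.items())},
                "length_percentages": {
                    str(k): dist.percentages[k] for k in sorted(dist.percentages)
                },
                "fraction_8_13": dist.fraction_8_13,
                "fraction_9_of_all": dist.fraction_9_of_all,
                "fraction_9_of_8_13": _nan_to_none(dist.fraction_9_of_8_13),
                "binder_fraction_8_13": _nan_to_none(
                    binder_fraction(run, predictor, "all_8_13")
                ),
                "binder_fraction_9": _nan_to_none(
                    binder_fraction(run, predictor, "only_9")
                ),
                "specificity": {
                    "per_allele": comp.per_allele,
                    "nB": comp.n_nonbinder,
                    "unassignable": comp.n_unassignable,
                    "total": comp.n_total,
                },
            }
        )
    report: dict = {
        "tool": "ipqc",
        "version": __version__,
        "config": dict(config_echo) if config_echo else {},
        "runs": per_run,
    }
    if isinstance(predictor, PssmPredictor):
        report["calibration_seeds"] = {
            a: {"seed": c.seed, "n_background": c.n_background}
            for a, c in sorted(predictor.calibrations.items())
        }
    if len(runs) >= 2:
        sizes = replicate_overlap_sets(runs)
        report["replicate_overlap"] = [
            {"runs": sorted(k), "count": v}
            for k, v in sorted(sizes.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write report.json plus per-table TSVs; returns the JSON path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    if "replicate_overlap" in report:
        sizes = {
            frozenset(entry["runs"]): entry["count"]
            for entry in report["replicate_overlap"]
        }
        overlap_sets_table(sizes).to_csv(out / "replicate_overlap.tsv", sep="\t", index=False)
    return path
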