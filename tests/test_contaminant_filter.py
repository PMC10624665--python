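"""Coverage-ratio statistic, cutoff calibration and curation rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ipqc.contaminant_filter import (
    calibrate_cutoff,
    flag_and_clean,
    protein_coverage_ratio,
)
from ipqc.peptidome_io import PeptideRecord, ProteinDb, SampleRun
from ipqc.synthetic_data import SyntheticConfig, generate_proteome, generate_run


def make_run(peptide_sources, sample="s1", rep="r1"):
    """peptide_sources: iterable of (sequence, tuple-of-accessions)."""
    run = SampleRun(sample, rep)
    for seq, sources in peptide_sources:
        run.add(PeptideRecord(seq, tuple(sources), None, sample, rep))
    return run


def naive_coverage_ratios(run, proteins):
    """Independent oracle: per-protein loop over all peptides."""
    out = {}
    for acc in proteins.sequences:
        total = sum(
            rec.length for rec in run if acc in rec.source_proteins
        )
        if total:
            out[acc] = total / proteins.length(acc)
    return out


class TestCoverageRatio:
    def test_hand_evaluated_ratio(self):
        """Protein of length 100 with peptides of lengths 9, 9, 10 -> 0.28."""
        db = ProteinDb({"P": "A" * 100})
        run = make_run([("C" * 9, ["P"]), ("D" * 9, ["P"]), ("E" * 10, ["P"])])
        (res,) = protein_coverage_ratio(run, db)
        assert res.ratio == pytest.approx(0.28)
        assert res.n_peptides == 3 and res.sum_peptide_lengths == 28

    def test_ladder_profile_ratio(self):
        """30 overlapping 9mers on a 60-residue protein -> 270/60 = 4.5."""
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        db = ProteinDb({"LAD": seq})
        windows = [(seq[i : i + 9], ["LAD"]) for i in range(30)]
        assert len({w for w, _ in windows}) == 30  # all distinct
        (res,) = protein_coverage_ratio(make_run(windows), db)
        assert res.ratio == pytest.approx(4.5)

    def test_uncovered_protein_absent(self):
        db = ProteinDb({"P": "A" * 50, "Q": "C" * 50})
        results = protein_coverage_ratio(make_run([("D" * 9, ["P"])]), db)
        assert [r.accession for r in results] == ["P"]

    def test_missing_accession_skipped_with_warning(self, caplog):
        db = ProteinDb({"P": "A" * 50})
        run = make_run([("D" * 9, ["P", "GHOST"])])
        with caplog.at_level("WARNING"):
            (res,) = protein_coverage_ratio(run, db)
        assert res.accession == "P"
        assert "not in protein db" in caplog.text

    def test_multimapped_peptide_counts_everywhere(self):
        db = ProteinDb({"P": "A" * 50, "Q": "C" * 100})
        results = protein_coverage_ratio(make_run([("D" * 10, ["P", "Q"])]), db)
        ratios = {r.accession: r.ratio for r in results}
        assert ratios == {"P": pytest.approx(0.2), "Q": pytest.approx(0.1)}

    def test_matches_naive_oracle_on_synthetic_runs(self, proteome, config):
        for seed in range(20):
            run, _ = generate_run(config, proteome, seed=seed)
            expected = naive_coverage_ratios(run, proteome)
            got = {r.accession: r.ratio for r in protein_coverage_ratio(run, proteome)}
            assert got == expected


class TestCutoffCalibration:
    def _run_with_ratios(self, ratios, rep):
        # one protein of length 100 per ratio; one peptide of the right length
        db_entries, peptides = {}, []
        for i, ratio in enumerate(ratios):
            acc = f"P{i:03d}"
            db_entries[acc] = "A" * 100
            peptides.append(("C" * int(round(ratio * 100)), [acc]))
        return ProteinDb(db_entries), make_run(peptides, rep=rep)

    def test_quantile_oracle_on_explicit_multiset(self):
        ratios = [0.01] * 95 + [0.5] * 5
        db, run = self._run_with_ratios(ratios, "r1")
        cal = calibrate_cutoff([run], db)
        assert cal.cutoff == pytest.approx(np.percentile(ratios, 95))
        # type-7 interpolation sits between the boundary values
        assert 0.01 < cal.cutoff < 0.5

    def test_identical_runs_mean_equals_each(self):
        ratios = list(np.linspace(0.01, 1.0, 50))
        db, run1 = self._run_with_ratios(ratios, "r1")
        _, run2 = self._run_with_ratios(ratios, "r2")
        cal = calibrate_cutoff([run1, run2], db)
        assert cal.cutoff == pytest.approx(cal.percentiles[0])

    def test_single_run_cutoff_is_its_percentile(self):
        ratios = [i / 100 for i in range(2, 62, 2)]
        db, run = self._run_with_ratios(ratios, "r1")
        cal = calibrate_cutoff([run], db)
        assert cal.cutoff == pytest.approx(np.percentile(ratios, 95))

    def test_sparse_run_excluded_then_error(self, caplog):
        db, run = self._run_with_ratios([0.1] * 5, "r1")
        with pytest.raises(ValueError, match="excluded"):
            calibrate_cutoff([run], db)
        assert "excluded" in caplog.text


class TestFlagAndClean:
    def test_no_flags_identity(self):
        db = ProteinDb({"P": "A" * 100})
        run = make_run([("C" * 9, ["P"])])
        curated, report = flag_and_clean(run, db, cutoff=1.0)
        assert curated.sequences == run.sequences
        assert not any(r.flagged for r in report)

    def test_ladder_exclusive_peptides_removed(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        db = ProteinDb({"LAD": seq, "OK": "W" * 200})
        windows = [(seq[i : i + 9], ["LAD"]) for i in range(30)]
        run = make_run(windows + [("M" * 9, ["OK"])])
        curated, report = flag_and_clean(run, db, cutoff=0.4)
        flagged = {r.accession for r in report if r.flagged}
        assert flagged == {"LAD"}
        assert curated.sequences == {"M" * 9}

    def test_shared_peptide_with_unflagged_source_retained(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        db = ProteinDb({"LAD": seq, "OK": "W" * 200})
        windows = [(seq[i : i + 9], ["LAD"]) for i in range(30)]
        shared = ("M" * 9, ["LAD", "OK"])
        run = make_run(windows + [shared])
        curated, _ = flag_and_clean(run, db, cutoff=0.4)
        assert "M" * 9 in curated.sequences
        assert all(pep == "M" * 9 for pep in curated.sequences)

    def test_nonpositive_cutoff_rejected(self):
        db = ProteinDb({"P": "A" * 100})
        with pytest.raises(ValueError):
            flag_and_clean(make_run([("C" * 9, ["P"])]), db, cutoff=0.0)

    @given(seed=st.integers(0, 30))
    def test_cleaning_idempotent(self, seed):
        config = SyntheticConfig(seed=seed, n_proteins=30, n_peptides=120,
                                 protein_length_range=(80, 200))
        proteome = generate_proteome(config)
        run, _ = generate_run(config, proteome)
        once, _ = flag_and_clean(run, proteome, cutoff=0.3)
        twice, _ = flag_and_clean(once, proteome, cutoff=0.3)
        assert twice.sequences == once.sequences


def test_clean_run_tail_fraction_near_five_percent(proteome, config):
    """~5% of proteins in a clean run exceed that run's own 95th-percentile
    cutoff (tolerance +/- 2% at >= 200 covered proteins)."""
    big = SyntheticConfig(seed=config.seed, n_proteins=250, n_peptides=2500)
    db = generate_proteome(big)
    run, _ = generate_run(big, db)
    results = protein_coverage_ratio(run, db)
    assert len(results) >= 200
    ratios = np.array([r.ratio for r in results])
    cutoff = np.percentile(ratios, 95)
    frac = (ratios > cutoff).mean()
    assert 0.03 <= frac <= 0.07
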