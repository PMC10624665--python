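"""Candidate filtering, deterministic ranking and poly-K export."""

import itertools

import pytest

from ipqc.binding_predictor import BindingPrediction, classify_rank
from ipqc.candidate_selection import (
    CandidateCriteria,
    CandidateRow,
    export_polyk,
    replicate_count,
    select_candidates,
)
from ipqc.peptidome_io import PeptideRecord, SampleRun
from ipqc.synthetic_data import generate_candidate_cohort


def make_runs(membership, n_runs=4, tissue="cell_line"):
    """membership: peptide -> list of run indices containing it."""
    runs = []
    for i in range(n_runs):
        run = SampleRun("s1", f"r{i + 1}", tissue_label=tissue)
        for pep, idxs in membership.items():
            if i in idxs:
                run.add(PeptideRecord(pep, (), None, "s1", f"r{i + 1}"))
        runs.append(run)
    return runs


def pred(pep, affinity, rank=0.2, allele="A02:01"):
    return BindingPrediction(pep, allele, rank, affinity, classify_rank(rank))


class TestReplicateCount:
    def test_membership_cases(self):
        runs = make_runs({"AAAAAAAAA": [0, 1, 2], "CCCCCCCCC": []})
        assert replicate_count("AAAAAAAAA", runs) == 3
        assert replicate_count("CCCCCCCCC", runs) == 0
        assert replicate_count("AAAAAAAAA", runs[:1]) == 1

    def test_present_in_all(self):
        runs = make_runs({"AAAAAAAAA": [0, 1, 2, 3]})
        assert replicate_count("AAAAAAAAA", runs) == 4


class TestSelectCandidates:
    def _toy(self):
        """Six peptides; exactly two satisfy all three default criteria."""
        peptides = {
            "PASSAAAAA": dict(aff=20, fc=3.0, reps=[0, 1, 2]),
            "PASSCCCCC": dict(aff=40, fc=4.0, reps=[0, 1, 2, 3]),
            "HIGHAFFIN": dict(aff=80, fc=3.0, reps=[0, 1, 2]),
            "LWFCAAAAA": dict(aff=20, fc=1.0, reps=[0, 1, 2]),
            "FEWERREPS": dict(aff=20, fc=3.0, reps=[0]),
            "EDGECASEA": dict(aff=50, fc=2.0, reps=[0, 1]),  # fails all strictly
        }
        runs = make_runs({p: v["reps"] for p, v in peptides.items()})
        predictions = {p: pred(p, v["aff"]) for p, v in peptides.items()}
        expression = {f"G_{p}": v["fc"] for p, v in peptides.items()}
        genes = {p: [f"G_{p}"] for p in peptides}
        return runs, predictions, expression, genes

    def test_brute_force_oracle_two_survivors(self):
        runs, predictions, expression, genes = self._toy()
        result = select_candidates(runs, predictions, expression, genes)
        assert {r.peptide for r in result.rows} == {"PASSAAAAA", "PASSCCCCC"}

    def test_strict_inequalities_at_boundaries(self):
        """affinity == 50, log_fc == 2 and 2 replicates all fail."""
        runs, predictions, expression, genes = self._toy()
        result = select_candidates(runs, predictions, expression, genes)
        assert "EDGECASEA" not in {r.peptide for r in result.rows}

    def test_filter_order_invariance(self):
        runs, predictions, expression, genes = self._toy()
        reference = None
        for order in itertools.permutations(("expression", "affinity", "replicates")):
            result = select_candidates(
                runs, predictions, expression, genes, filter_order=order
            )
            survivors = {r.peptide for r in result.rows}
            reference = survivors if reference is None else reference
            assert survivors == reference

    def test_tightening_thresholds_monotone(self):
        runs, predictions, expression, genes = self._toy()
        base = len(select_candidates(runs, predictions, expression, genes).rows)
        for criteria in (
            CandidateCriteria(affinity_max_nM=25),
            CandidateCriteria(min_log_fc=3.5),
            CandidateCriteria(min_replicates=4),
        ):
            n = len(select_candidates(runs, predictions, expression, genes, criteria).rows)
            assert n <= base

    def test_preferred_length_ranks_first(self):
        membership = {"AAAAAAAAA": [0, 1, 2], "CCCCCCCCCC": [0, 1, 2]}
        runs = make_runs(membership)
        predictions = {p: pred(p, 20) for p in membership}
        expression = {"G": 3.0}
        genes = {p: ["G"] for p in membership}
        result = select_candidates(runs, predictions, expression, genes)
        assert result.rows[0].peptide == "AAAAAAAAA"  # the 9mer
        assert result.rows[0].is_preferred_length

    def test_tissue_prioritization(self):
        membership = {"AAAAAAAAA": [0, 1, 2], "CCCCCCCCC": [1, 2, 3]}
        runs = make_runs({"AAAAAAAAA": [0, 1, 2]}, n_runs=3, tissue="cell_line")
        tumor = make_runs({"CCCCCCCCC": [0, 1, 2]}, n_runs=3, tissue="tumor")
        for i, run in enumerate(tumor):
            run.replicate_id = f"t{i + 1}"
        all_runs = runs + tumor
        predictions = {p: pred(p, 20) for p in membership}
        expression = {"G": 3.0}
        genes = {p: ["G"] for p in membership}
        criteria = CandidateCriteria(prioritize_tissue="tumor")
        result = select_candidates(all_runs, predictions, expression, genes, criteria)
        assert result.rows[0].peptide == "CCCCCCCCC"
        assert result.rows[0].tissue_evidence

    def test_unmapped_peptide_excluded_and_counted(self):
        runs = make_runs({"AAAAAAAAA": [0, 1, 2]})
        predictions = {"AAAAAAAAA": pred("AAAAAAAAA", 20)}
        result = select_candidates(runs, predictions, {}, {})
        assert result.rows == []
        assert result.filter_counts["no_mapped_gene"] == 1

    def test_multi_gene_uses_max_log_fc(self):
        runs = make_runs({"AAAAAAAAA": [0, 1, 2]})
        predictions = {"AAAAAAAAA": pred("AAAAAAAAA", 20)}
        expression = {"G1": 1.0, "G2": 5.0}
        genes = {"AAAAAAAAA": ["G1", "G2"]}
        result = select_candidates(runs, predictions, expression, genes)
        assert len(result.rows) == 1 and result.rows[0].log_fc == 5.0


def test_planted_cohort_recovered_exactly():
    """15 planted true candidates among one-fault distractors come back
    exactly, in a deterministic order."""
    runs, predictions, expression, genes, true_set = generate_candidate_cohort(seed=4)
    result = select_candidates(runs, predictions, expression, genes)
    assert {r.peptide for r in result.rows} == true_set
    again = select_candidates(runs, predictions, expression, genes)
    assert [r.peptide for r in again.rows] == [r.peptide for r in result.rows]
    # sorted primarily by ascending affinity for all-9mer candidates
    affs = [r.affinity_nM for r in result.rows]
    assert affs == sorted(affs)


class TestExportPolyk:
    def test_concatenation(self):
        rows = [CandidateRow("SIINFEKL", "A02:01", 20.0, 0.2, 3, ("G",), 3.0,
                             False, False, 1)]
        df = export_polyk(rows, k=6)
        assert df.iloc[0]["polyk_sequence"] == "KKKKKKSIINFEKL"

    def test_zero_k_rejected(self):
        with pytest.raises(ValueError):
            export_polyk([], k=0)

    def test_leading_lysine_flagged(self):
        rows = [CandidateRow("KLAAAAAAA", "A02:01", 20.0, 0.2, 3, ("G",), 3.0,
                             True, False, 1)]
        df = export_polyk(rows, k=3)
        assert bool(df.iloc[0]["starts_with_K"])
        assert df.iloc[0]["polyk_sequence"][3:] == "KLAAAAAAA"
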