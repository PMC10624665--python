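"""Length distributions, binder fractions, deconvolution and UpSet overlap."""

import math

import numpy as np
import pandas as pd
import pytest

from ipqc.peptidome_io import PeptideRecord, SampleRun
from ipqc.qc_metrics import (
    binder_fraction,
    deconvolute_specificity,
    length_distribution,
    motif_summary,
    position_information,
    replicate_overlap_sets,
)


def make_run(sequences, sample="s1", rep="r1", haplotype=("A02:01",)):
    run = SampleRun(sample, rep, haplotype=haplotype)
    for seq in sequences:
        run.add(PeptideRecord(seq, (), None, sample, rep))
    return run


class FixedRankPredictor:
    """Stub backend assigning one fixed rank to every peptide."""

    def __init__(self, rank):
        self.rank = rank

    def predict_table(self, peptides, haplotype):
        from ipqc.binding_predictor import classify_rank

        return pd.DataFrame(
            {
                "peptide": list(peptides),
                "allele": haplotype[0],
                "rank": self.rank,
                "affinity_nM": 100.0,
                "binder_class": classify_rank(self.rank),
            }
        )

    def predict_per_allele(self, peptides, haplotype):
        return self.predict_table(peptides, haplotype)


class TestLengthDistribution:
    def test_direct_arithmetic(self):
        run = make_run(["AAAAAAAAA", "CCCCCCCCC", "DDDDDDDDD", "EEEEEEEEEE"])
        dist = length_distribution(run)
        assert dist.percentages[9] == pytest.approx(75.0)
        assert dist.fraction_8_13 == pytest.approx(100.0)
        assert dist.fraction_9_of_all == pytest.approx(75.0)

    def test_all_long_peptides_outside_window(self):
        run = make_run(["A" * 15, "C" * 15])
        assert length_distribution(run).fraction_8_13 == 0.0

    def test_empty_run_errors(self):
        with pytest.raises(ValueError):
            length_distribution(make_run([]))

    def test_generated_run_percentages_sum_to_100(self, run_and_truth):
        run, _ = run_and_truth
        dist = length_distribution(run)
        assert sum(dist.percentages.values()) == pytest.approx(100.0, abs=1e-6)
        assert dist.fraction_9_of_all <= dist.fraction_8_13

    def test_generated_9mer_fraction_matches_generator(self, run_and_truth, config):
        run, truth = run_and_truth
        dist = length_distribution(run)
        expected = 100.0 * (
            (1 - config.noise_fraction) * config.length_dist[9]
            + config.noise_fraction * config.noise_length_dist[9]
        )
        # binomial tolerance at n = 1000
        assert dist.fraction_9_of_all == pytest.approx(expected, abs=5.0)


class TestBinderFraction:
    def test_saturation_all_binders(self):
        run = make_run(["AAAAAAAAA", "CCCCCCCCC"])
        assert binder_fraction(run, FixedRankPredictor(0.1)) == 100.0

    def test_saturation_no_binders(self):
        run = make_run(["AAAAAAAAA", "CCCCCCCCC"])
        assert binder_fraction(run, FixedRankPredictor(50.0)) == 0.0

    def test_empty_scope_is_missing(self):
        run = make_run(["A" * 15])
        assert math.isnan(binder_fraction(run, FixedRankPredictor(0.1)))

    def test_missing_haplotype_errors(self):
        run = make_run(["AAAAAAAAA"], haplotype=())
        with pytest.raises(ValueError):
            binder_fraction(run, FixedRankPredictor(0.1))

    def test_motif_fraction_recovered(self, run_and_truth, predictor, config):
        """Run with 85% motif peptides -> binder fraction near 85%."""
        run, _ = run_and_truth
        frac = binder_fraction(run, predictor, "all_8_13")
        assert frac == pytest.approx(100 * (1 - config.noise_fraction), abs=4.0)

    def test_nine_mers_at_least_as_binder_rich(self, run_and_truth, predictor):
        run, _ = run_and_truth
        assert binder_fraction(run, predictor, "only_9") >= binder_fraction(
            run, predictor, "all_8_13"
        )


class TestDeconvolution:
    def test_single_allele_gets_every_binder(self, run_and_truth):
        run, _ = run_and_truth
        comp, _ = deconvolute_specificity(run, FixedRankPredictor(0.3))
        assert set(comp.per_allele) == {"A02:01"}
        assert comp.per_allele["A02:01"]["SB"] == comp.n_total

    def test_unassignable_length_counted(self, predictor):
        run = make_run(["A" * 13], haplotype=("A02:01",))
        # restrict models to 9mers by querying a length no model covers
        comp, table = deconvolute_specificity(run, predictor, lengths=(13,))
        assert comp.n_total == 1
        # 13 is covered by default models; use a truly uncovered length
        run14 = make_run(["A" * 13 + "A"], haplotype=("A02:01",))
        comp14, _ = deconvolute_specificity(run14, predictor, lengths=(14,))
        assert comp14.n_unassignable == 1

    def test_two_motif_counts_match_generator(self, run_and_truth, predictor, config):
        run, truth = run_and_truth
        comp, _ = deconvolute_specificity(run, predictor)
        total_assigned = sum(sum(v.values()) for v in comp.per_allele.values())
        for allele in config.haplotype:
            observed = sum(comp.per_allele[allele].values())
            expected = (truth["allele"] == allele).sum()
            assert observed == pytest.approx(expected, rel=0.10)
        assert total_assigned + comp.n_nonbinder + comp.n_unassignable == comp.n_total


class TestOverlapSets:
    def test_exclusive_semantics_brute_force(self):
        a = make_run(["W" * 9, "Y" * 9], rep="r1")
        b = make_run(["Y" * 9, "Q" * 9], rep="r2")
        sizes = replicate_overlap_sets([a, b])
        assert sizes == {
            frozenset({"s1/r1"}): 1,
            frozenset({"s1/r2"}): 1,
            frozenset({"s1/r1", "s1/r2"}): 1,
        }

    def test_identical_runs_only_full_subset(self):
        a = make_run(["W" * 9, "Y" * 9], rep="r1")
        b = make_run(["W" * 9, "Y" * 9], rep="r2")
        sizes = replicate_overlap_sets([a, b])
        assert sizes == {frozenset({"s1/r1", "s1/r2"}): 2}

    def test_disjoint_runs_only_singletons(self):
        a = make_run(["W" * 9], rep="r1")
        b = make_run(["Y" * 9], rep="r2")
        sizes = replicate_overlap_sets([a, b])
        assert set(sizes) == {frozenset({"s1/r1"}), frozenset({"s1/r2"})}

    def test_sizes_sum_to_union(self, config, proteome):
        from ipqc.synthetic_data import generate_cohort

        runs, _ = generate_cohort(config, 3, proteome)
        sizes = replicate_overlap_sets(runs)
        union = set().union(*(r.sequences for r in runs))
        assert sum(sizes.values()) == len(union)

    def test_fewer_than_two_runs_errors(self):
        with pytest.raises(ValueError):
            replicate_overlap_sets([make_run(["W" * 9])])


class TestMotifSummary:
    def test_identical_peptides_full_information(self):
        out = motif_summary({"A": ["LWHAMKVRC"] * 12}, 9)
        np.testing.assert_allclose(out["A"].information_bits, math.log2(20))

    def test_uniform_positions_zero_information(self):
        peptides = [aa * 9 for aa in "ACDEFGHIKLMNPQRSTVWY"]
        out = motif_summary({"A": peptides}, 9)
        np.testing.assert_allclose(out["A"].information_bits, 0.0, atol=1e-12)

    def test_anchor_information_closed_form(self):
        """A 0.9/0.1 two-residue position carries log2(20) - H(0.9, 0.1) bits."""
        peptides = ["L" + aa + "A" * 7 for aa in "ACDEFGHIK"] + ["VAAAAAAAA"]
        out = motif_summary({"A": peptides}, 9)
        h = -(0.9 * math.log2(0.9) + 0.1 * math.log2(0.1))
        assert out["A"].information_bits[0] == pytest.approx(math.log2(20) - h)

    def test_small_group_reported_insufficient(self):
        out = motif_summary({"A": ["LWHAMKVRC"] * 5}, 9)
        assert not out["A"].sufficient

    def test_frequency_rows_stochastic(self, run_and_truth):
        run, truth = run_and_truth
        groups = truth[~truth["is_noise"]].groupby("allele")["peptide"].apply(list)
        out = motif_summary(groups.to_dict(), 9)
        for summary in out.values():
            assert summary.sufficient
            np.testing.assert_allclose(summary.frequencies.sum(axis=1), 1.0)
            assert (summary.information_bits >= -1e-12).all()


def test_position_information_bounds():
    freqs = np.full((3, 20), 0.05)
    np.testing.assert_allclose(position_information(freqs), 0.0, atol=1e-12)
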