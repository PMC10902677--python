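"""Alignment summaries, rarefaction curves, Shannon / Inverse Simpson."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from repseq import (Repertoire, RepertoireError, alignment_summary,
                    build_experiment, diversity_table, inverse_simpson,
                    rarefaction_curve, recompute_fractions, shannon_index)
from repseq.preprocess import standard_pipeline
from repseq.io import read_mixcr_clones
from conftest import make_rep, rep_from_fractions


def singleton_rep(n, count=1):
    return make_rep([(f"c{i}", count, "GCT" * 8, f"PEP{i:04d}")
                     for i in range(n)])


class TestAlignmentSummary:
    def test_defaults_to_table_totals(self):
        exp = build_experiment([singleton_rep(10)])
        row = alignment_summary(exp).iloc[0]
        assert (row["total_reads"], row["aligned_reads"],
                row["retained_after_trim"]) == (10, 10, 10)

    def test_upstream_totals_pass_through(self):
        rep = singleton_rep(12, count=100)  # retained 1200
        exp = build_experiment([rep])
        row = alignment_summary(exp, {"s": (2000, 1500)}).iloc[0]
        assert row["total_reads"] == 2000
        assert row["aligned_reads"] == 1500
        assert row["retained_after_trim"] == 1200

    def test_unknown_sample_in_upstream_errors(self):
        exp = build_experiment([singleton_rep(5)])
        with pytest.raises(RepertoireError, match="unknown"):
            alignment_summary(exp, {"nope": (10, 10)})


class TestRarefaction:
    def test_all_singletons_every_read_is_new(self):
        curve = rarefaction_curve(singleton_rep(100), n_bins=100, seed=0)
        assert curve.unique_counts.tolist() == list(range(1, 101))
        assert curve.depths.tolist() == list(range(1, 101))

    def test_single_clone_saturates_immediately(self):
        rep = make_rep([("c1", 500, "GCT" * 8, "PEPTIDE")])
        curve = rarefaction_curve(rep, n_bins=100, seed=0)
        assert curve.unique_counts.tolist() == [1] * 100

    def test_fixed_seed_is_deterministic(self, small_campaign):
        tab = small_campaign.round_table(0)
        rep = make_rep([(r.cloneId, r.readCount, r.nSeqCDR3, r.aaSeqCDR3)
                        for r in tab.itertuples()])
        a = rarefaction_curve(rep, seed=42)
        b = rarefaction_curve(rep, seed=42)
        assert a.unique_counts.tolist() == b.unique_counts.tolist()

    def test_endpoints_and_monotone(self, small_campaign):
        tab = small_campaign.round_table(1)
        rep = make_rep([(r.cloneId, r.readCount, r.nSeqCDR3, r.aaSeqCDR3)
                        for r in tab.itertuples()])
        curve = rarefaction_curve(rep, n_bins=100, seed=7)
        assert len(curve.depths) == 100
        assert (np.diff(curve.unique_counts) >= 0).all()
        assert curve.depths[-1] == rep.total_reads
        assert curve.unique_counts[-1] == rep.df["aa_seq"].nunique()

    def test_single_bin_is_totals_point(self):
        rep = singleton_rep(30, count=3)
        curve = rarefaction_curve(rep, n_bins=1, seed=0)
        assert curve.depths.tolist() == [90]
        assert curve.unique_counts.tolist() == [30]

    def test_more_bins_than_reads_errors(self):
        with pytest.raises(RepertoireError, match="n_bins"):
            rarefaction_curve(singleton_rep(5), n_bins=10, seed=0)


class TestDiversityIndices:
    def test_uniform_four_clones_shannon_ln4(self):
        rep = recompute_fractions(singleton_rep(4))
        assert shannon_index(rep) == pytest.approx(math.log(4), abs=1e-12)
        assert shannon_index(rep, base=2) == pytest.approx(2.0, abs=1e-12)

    def test_single_clone_extremes(self):
        rep = recompute_fractions(singleton_rep(1))
        assert shannon_index(rep) == 0.0
        assert inverse_simpson(rep) == pytest.approx(1.0)

    def test_hand_evaluations(self):
        rep = rep_from_fractions([0.5, 0.25, 0.25])
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert shannon_index(rep) == pytest.approx(expected, abs=1e-12)
        assert shannon_index(rep) == pytest.approx(1.0397, abs=1e-4)
        rep2 = rep_from_fractions([0.5, 0.3, 0.2])
        assert inverse_simpson(rep2) == pytest.approx(1 / 0.38, abs=1e-9)
        assert inverse_simpson(rep2) == pytest.approx(2.6316, abs=1e-4)

    @pytest.mark.parametrize("n", [1, 2, 5, 17, 100])
    def test_uniform_closed_forms(self, n):
        rep = recompute_fractions(singleton_rep(n))
        assert shannon_index(rep) == pytest.approx(math.log(n), abs=1e-9)
        assert inverse_simpson(rep) == pytest.approx(n, rel=1e-9)

    @given(st.lists(st.integers(1, 500), min_size=1, max_size=50))
    def test_bounds_and_uniform_maximum(self, counts):
        rep = recompute_fractions(
            make_rep([(f"c{i}", c, "GCT" * 8, f"PEP{i:03d}")
                      for i, c in enumerate(counts)]))
        n = len(counts)
        h, d = shannon_index(rep), inverse_simpson(rep)
        assert -1e-9 <= h <= math.log(n) + 1e-9
        assert 1 - 1e-9 <= d <= n + 1e-9

    def test_unnormalized_fractions_rejected(self):
        rep = rep_from_fractions([0.2, 0.2])
        with pytest.raises(RepertoireError, match="fractions"):
            shannon_index(rep)


class TestDiversityTable:
    def test_matches_per_sample_calls(self):
        reps = [recompute_fractions(singleton_rep(n)) for n in (4, 9, 25)]
        for i, rep in enumerate(reps):
            rep.sample_name = f"s{i}"
        exp = build_experiment(reps)
        table = diversity_table(exp, metric="shannon")
        assert table["value"].tolist() == pytest.approx(
            [shannon_index(r) for r in reps])

    def test_enrichment_lowers_diversity_across_rounds(self, campaign_dir):
        reps = []
        for t in range(3):
            rep = read_mixcr_clones(campaign_dir[f"round_{t}"])
            clean, _ = standard_pipeline(rep)
            reps.append(clean)
        values = diversity_table(build_experiment(reps),
                                 metric="shannon")["value"]
        assert values.is_monotonic_decreasing

    def test_empty_sample_named_in_error(self):
        rep = singleton_rep(3)
        empty = rep.with_frame(rep.df.iloc[0:0])
        empty.sample_name = "void"
        exp = build_experiment([recompute_fractions(rep), empty])
        with pytest.raises(RepertoireError, match="void"):
            diversity_table(exp)
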