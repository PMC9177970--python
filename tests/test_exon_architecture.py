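"""Split mapping, contingency statistics and enrichment bookkeeping."""

import math

import numpy as np
import pytest
from scipy import stats

from splicecode.exon_architecture import (
    SplitEvent,
    chi2_contingency,
    count_motif_exons,
    donor_class,
    loop_to_splice_site_distances,
    map_splits,
    split_enrichment,
    split_position_clusters,
)
from splicecode.formats import GeneModel, MotifRecord


def motif(loop_start=10, gene="g1", motif_class="CANONICAL"):
    """A 36-nt loop centred in a 108-nt motif starting 36 nt earlier (clipped
    at the CDS start when necessary)."""
    motif_start = max(1, loop_start - 36)
    length = (loop_start + 35 + 36) - motif_start + 1
    return MotifRecord(gene, motif_class, motif_start, length, loop_start, 36)


def events_with(n_within: int, n_outside: int) -> list[SplitEvent]:
    ev = [SplitEvent("g", "m", 0, 1, True, 36) for _ in range(n_within)]
    ev += [SplitEvent("g", "m", 0, 40, False, 36) for _ in range(n_outside)]
    return ev


class TestMapSplits:
    def test_intron_just_before_loop_is_position_1(self):
        m = motif(loop_start=10)
        model = GeneModel("g1", [(1, 9), (10, 200)])
        (event,) = map_splits([model], [m])
        assert event.loop_relative_position == 1
        assert event.within_loop

    def test_intron_after_loop_end_is_outside(self):
        m = motif(loop_start=10)  # loop 10..45
        model = GeneModel("g1", [(1, 45), (46, 200)])
        (event,) = map_splits([model], [m])
        assert event.loop_relative_position == 37
        assert not event.within_loop

    def test_intron_after_nt_27_is_position_19(self):
        m = motif(loop_start=10)
        model = GeneModel("g1", [(1, 27), (28, 200)])
        (event,) = map_splits([model], [m])
        assert event.loop_relative_position == 19
        assert event.within_loop

    def test_upstream_convention_shifts_by_one(self):
        m = motif(loop_start=10)
        model = GeneModel("g1", [(1, 27), (28, 200)])
        (event,) = map_splits([model], [m], convention="upstream")
        assert event.loop_relative_position == 18

    def test_insertion_outside_motif_ignored(self):
        m = motif(loop_start=50)  # motif 14..121
        model = GeneModel("g1", [(1, 10), (11, 300)])
        assert map_splits([model], [m]) == []

    def test_motif_beyond_cds_is_error(self):
        m = motif(loop_start=50)
        model = GeneModel("g1", [(1, 100)])
        with pytest.raises(ValueError, match="beyond"):
            map_splits([model], [m])

    def test_exactly_motif_length_candidate_positions(self):
        m = motif(loop_start=40)  # motif 4..147, 144 nt
        events = []
        for p in range(1, 200):
            model = GeneModel("g1", [(1, p), (p + 1, 250)])
            events += map_splits([model], [m])
        assert len(events) == m.motif_length_nt
        assert sum(e.within_loop for e in events) == 36


class TestCountMotifExons:
    def test_single_exon_motif(self):
        m = motif(loop_start=40)
        model = GeneModel("g1", [(1, 250)])
        per_motif, contingency = count_motif_exons([model], [m])
        assert per_motif == {"g1:0": 1}
        assert contingency["CANONICAL"] == [1, 0, 0]

    def test_two_splits_give_three_exons(self):
        m = motif(loop_start=40)  # motif 4..147
        model = GeneModel("g1", [(1, 50), (51, 100), (101, 250)])
        per_motif, contingency = count_motif_exons([model], [m])
        assert per_motif["g1:0"] == 3
        assert contingency["CANONICAL"] == [0, 0, 1]

    def test_class_rows_sum_to_motif_counts(self, small_dataset):
        _, _, motifs, models = small_dataset
        _, contingency = count_motif_exons(models, motifs)
        total = sum(sum(row) for row in contingency.values())
        assert total == len(motifs)


class TestChi2:
    def test_published_2x3_table(self):
        chi2, dof, p = chi2_contingency([[79, 178, 39], [15, 47, 4]])
        assert chi2 == pytest.approx(3.7, abs=0.05)
        assert dof == 2
        assert p == pytest.approx(0.16, abs=0.005)

    def test_proportional_rows_give_zero(self):
        chi2, _, p = chi2_contingency([[10, 20, 30], [20, 40, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_2x2_diagonal(self):
        chi2, dof, _ = chi2_contingency([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert dof == 1

    def test_zero_marginal_is_error(self):
        with pytest.raises(ValueError):
            chi2_contingency([[0, 5], [0, 7]])

    def test_matches_direct_formula_on_random_tables(self):
        """Oracle: chi2 = sum (O-E)^2/E with E from the product of marginals."""
        rng = np.random.default_rng(12)
        for _ in range(1000):
            r, k = rng.integers(2, 5, size=2)
            table = rng.integers(1, 40, size=(r, k)).astype(float)
            chi2, dof, _ = chi2_contingency(table)
            total = table.sum()
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
            oracle = ((table - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(oracle, abs=1e-9)
            assert dof == (r - 1) * (k - 1)


class TestSplitEnrichment:
    @pytest.mark.parametrize(
        "n,expected", [(213, 71.0), (49, 16.33), (262, 87.33)])
    def test_uniform_expectations(self, n, expected):
        res = split_enrichment(events_with(n, 0))
        assert round(res.expected_within, 2) == expected

    def test_totals_conserved(self):
        res = split_enrichment(events_with(30, 70))
        assert res.observed_within + res.observed_outside == res.n_splits
        assert res.expected_within + res.expected_outside == pytest.approx(
            res.n_splits)

    def test_three_within_splits_exact_binomial(self):
        # n=3, p=1/3: the only outcome with point probability <= P(3)=1/27
        # is k=3 itself, so the two-sided p equals 1/27
        res = split_enrichment(events_with(3, 0))
        assert res.binomial_p == pytest.approx(1 / 27)

    def test_pct_within(self):
        res = split_enrichment(events_with(112, 150))
        assert round(res.pct_within, 1) == 42.7

    def test_positional_chi2_flags_single_position_pileup(self):
        events = [SplitEvent("g", "m", 0, 5, True, 36) for _ in range(120)]
        res = split_enrichment(events)
        assert res.chi2_p < 1e-10

    def test_empty_events_error(self):
        with pytest.raises(ValueError):
            split_enrichment([])


class TestSplitClusters:
    def test_single_position(self):
        events = [SplitEvent("g", "m", 0, 5, True, 36)] * 4
        assert split_position_clusters(events) == (1, 0)

    def test_empty(self):
        assert split_position_clusters([]) == (0, 0)

    def test_positions_between_clusters_ignored(self):
        events = [SplitEvent("g", "m", 0, 25, True, 36)]
        assert split_position_clusters(events) == (0, 0)

    def test_recovers_generator_ground_truth(self, small_config):
        from splicecode.synthetic import simulate_efhand_genes

        cfg = small_config
        proteins, cds, motifs, models = simulate_efhand_genes(cfg, 202)
        events = map_splits(models, motifs)
        n_distinct, c_distinct = split_position_clusters(events)
        sm = cfg.split_model
        observed_n = {e.loop_relative_position for e in events
                      if e.within_loop and e.loop_relative_position <= 18}
        assert observed_n <= set(sm.n_cluster_positions)
        assert n_distinct == len(observed_n)
        observed_c = {e.loop_relative_position for e in events
                      if e.within_loop and e.loop_relative_position >= 31}
        assert observed_c <= set(sm.c_cluster_positions)
        assert c_distinct == len(observed_c)


class TestLoopDistances:
    def test_loop_at_exon_start(self):
        m = motif(loop_start=101)
        model = GeneModel("g1", [(1, 100), (101, 400)])
        ((_, d3, d5),) = loop_to_splice_site_distances([model], [m])
        assert d3 == 0
        assert d5 == 400 - (101 + 35)

    def test_exon_length_400_is_filtered(self):
        m = motif(loop_start=101)
        model = GeneModel("g1", [(1, 400)])
        assert loop_to_splice_site_distances([model], [m]) == []

    def test_hand_arithmetic(self):
        m = MotifRecord("g1", "CANONICAL", 114, 108, 150, 36)
        model = GeneModel("g1", [(1, 100), (101, 300)])
        ((_, d3, d5),) = loop_to_splice_site_distances([model], [m])
        assert (d3, d5) == (49, 115)

    def test_split_loop_excluded(self):
        m = motif(loop_start=90)
        model = GeneModel("g1", [(1, 100), (101, 300)])
        assert loop_to_splice_site_distances([model], [m]) == []


class TestDonorClass:
    def test_classification(self):
        model = GeneModel("g1", [(1, 50), (51, 120), (121, 200), (201, 300)],
                          ["GT", "GC", "AT"])
        assert donor_class([model])["g1"] == ["GT", "GC", "OTHER"]

    def test_missing_annotation_is_other(self):
        model = GeneModel("g1", [(1, 50), (51, 120)])
        assert donor_class([model])["g1"] == ["OTHER"]


def test_uniform_split_binomial_p_values_are_calibrated():
    """Under uniform intron placement across the motif, exact binomial
    p-values over replicates are approximately uniform (KS sanity)."""
    rng = np.random.default_rng(31)
    pvals = []
    for _ in range(200):
        positions = rng.integers(1, 109, size=262)  # uniform over 108
        within = int((positions <= 36).sum())
        res = split_enrichment(events_with(within, 262 - within))
        pvals.append(res.binomial_p)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
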