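"""Gene statistics, threshold variants, replicate consensus, volcano collapse."""

import numpy as np
import pandas as pd
import pytest

import tecsuite as ts
from tecsuite.de import DEThresholds


# ----------------------------------------------------------------- eligibility

class TestEligibility:
    def _cells(self, counts):
        rows = []
        for (ct, sample), n in counts.items():
            rows += [{"cell_type": ct, "sample_id": sample}] * n
        return pd.DataFrame(rows)

    def test_thirty_cells_everywhere_is_eligible(self):
        cells = self._cells({("a", "s1"): 30, ("a", "s2"): 30})
        assert ts.eligible_cell_types(cells) == ["a"]

    def test_29_in_one_sample_is_ineligible(self):
        cells = self._cells({("a", "s1"): 30, ("a", "s2"): 29})
        assert ts.eligible_cell_types(cells) == []

    def test_matches_brute_force_count_check(self, rng):
        types = [f"t{i}" for i in range(6)]
        samples = [f"s{j}" for j in range(4)]
        cells = pd.DataFrame({
            "cell_type": rng.choice(types, 900),
            "sample_id": rng.choice(samples, 900),
        })
        expected = [
            ct for ct in sorted(types)
            if all(((cells["cell_type"] == ct) & (cells["sample_id"] == s)).sum() >= 30
                   for s in samples)
        ]
        assert ts.eligible_cell_types(cells) == expected

    def test_absent_sample_counts_as_zero(self):
        cells = self._cells({("a", "s1"): 50})
        assert ts.eligible_cell_types(cells, samples=["s1", "s2"]) == []


# ------------------------------------------------------------------ gene stats

class TestGeneStats:
    def test_identical_groups_have_zero_lfc(self, rng):
        X = rng.poisson(3.0, size=(40, 15)).astype(float)
        stats = ts.estimate_gene_stats(X, X, seed=1)
        assert np.allclose(stats["lfc_mean"], 0.0)
        assert np.allclose(stats["bayes_factor"], 0.0)

    def test_all_zero_gene_reports_zero_lfc_and_fraction(self, rng):
        X = np.zeros((10, 3))
        X[:, 0] = rng.poisson(2.0, 10) + 1
        stats = ts.estimate_gene_stats(X, X.copy(), seed=2)
        assert stats.loc[2, "lfc_mean"] == 0.0
        assert stats.loc[2, "frac_nonzero_a"] == 0.0

    def test_planted_fourfold_shift_is_detected(self):
        """500 cells/group, 4-fold mean shift: lfc within 0.3 of 2 and
        Bayes factor above 2.5 for >= 95% of planted genes."""
        rng = np.random.default_rng(11)
        n, g = 500, 100
        mu = 4.0
        A = rng.poisson(4 * mu, size=(n, g)).astype(float)
        B = rng.poisson(mu, size=(n, g)).astype(float)
        stats = ts.estimate_gene_stats(A, B, n_boot=500, seed=11)
        ok = ((stats["lfc_mean"] - 2.0).abs() < 0.3) & (stats["bayes_factor"] > 2.5)
        assert ok.mean() >= 0.95

    def test_deterministic_for_fixed_seed(self, rng):
        A = rng.poisson(2.0, size=(30, 10)).astype(float)
        B = rng.poisson(3.0, size=(25, 10)).astype(float)
        s1 = ts.estimate_gene_stats(A, B, seed=5)
        s2 = ts.estimate_gene_stats(A, B, seed=5)
        pd.testing.assert_frame_equal(s1, s2)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            ts.estimate_gene_stats(np.empty((0, 3)), np.ones((5, 3)))

    def test_peak_expression_is_the_pooled_99th_percentile(self, rng):
        A = rng.random((60, 4)) * 10
        B = rng.random((40, 4)) * 10
        stats = ts.estimate_gene_stats(A, B, seed=0)
        assert np.allclose(stats["peak_expr"],
                           np.percentile(np.vstack([A, B]), 99, axis=0))


# ------------------------------------------------------------------ DE filter

from oracles import brute_force_de_filter as brute_force_filter  # noqa: E402


def _random_stats(rng, n=200):
    return pd.DataFrame({
        "gene": [f"g{i}" for i in range(n)],
        "bayes_factor": rng.uniform(0, 6, n),
        "lfc_mean": rng.uniform(-3, 3, n),
        "frac_nonzero_a": rng.uniform(0, 1, n),
        "frac_nonzero_b": rng.uniform(0, 1, n),
        "peak_expr": rng.uniform(0, 2, n),
    })


class TestDEFilter:
    def test_bayes_factor_boundary_is_strict(self):
        stats = pd.DataFrame([{"gene": "g", "bayes_factor": 2.5, "lfc_mean": 2.0,
                               "frac_nonzero_a": 0.5, "frac_nonzero_b": 0.5,
                               "peak_expr": 2.0}])
        assert ts.apply_de_filter(stats, ts.GENOTYPE_THRESHOLDS).empty

    def test_clear_pass_with_direction(self):
        stats = pd.DataFrame([{"gene": "g", "bayes_factor": 3.0, "lfc_mean": 1.5,
                               "frac_nonzero_a": 0.5, "frac_nonzero_b": 0.5,
                               "peak_expr": 2.0}])
        calls = ts.apply_de_filter(stats, ts.GENOTYPE_THRESHOLDS)
        assert list(calls["direction"]) == ["up"]

    @pytest.mark.parametrize("thresholds", [
        ts.GENOTYPE_THRESHOLDS, ts.MARKER_THRESHOLDS, ts.MIMETIC_THRESHOLDS,
    ])
    def test_matches_brute_force_enumeration(self, rng, thresholds):
        stats = _random_stats(rng)
        calls = ts.apply_de_filter(stats, thresholds)
        assert list(calls["gene"]) == brute_force_filter(stats, thresholds)

    def test_raising_any_threshold_never_enlarges_the_passing_set(self, rng):
        stats = _random_stats(rng)
        base = set(ts.apply_de_filter(stats, ts.GENOTYPE_THRESHOLDS)["gene"])
        for kwargs in ({"bf_min": 3.5}, {"lfc_abs_min": 1.5},
                       {"frac_min": 0.3}, {"peak_min": 1.0}):
            t = DEThresholds(**{**dict(bf_min=2.5, lfc_abs_min=1.0,
                                       frac_min=0.05, peak_min=0.5), **kwargs})
            assert set(ts.apply_de_filter(stats, t)["gene"]) <= base

    def test_missing_required_statistic_is_named(self):
        stats = pd.DataFrame([{"gene": "g", "bayes_factor": 3.0,
                               "lfc_mean": 1.5, "frac_nonzero_a": 0.5,
                               "frac_nonzero_b": 0.5}])
        with pytest.raises(ValueError, match="peak_expr"):
            ts.apply_de_filter(stats, ts.GENOTYPE_THRESHOLDS)

    def test_marker_variant_reads_group_of_interest_fraction(self):
        stats = pd.DataFrame([{"gene": "g", "bayes_factor": 4.0, "lfc_mean": 2.0,
                               "frac_nonzero_a": 0.05, "frac_nonzero_b": 0.9}])
        assert ts.apply_de_filter(stats, ts.MARKER_THRESHOLDS).empty


# ------------------------------------------------------------------- consensus

def _calls(rows):
    return pd.DataFrame(rows, columns=["gene", "cell_type", "direction",
                                       "lfc_mean", "bayes_factor"])


class TestConsensus:
    def test_gene_in_all_replicates_and_no_batch_set_is_retained(self):
        rep1 = _calls([("g1", "a", "up", 2.0, 3.0)])
        rep2 = _calls([("g1", "a", "up", 1.8, 3.2)])
        final = ts.consensus_across_replicates([rep1, rep2], [])
        assert list(final["gene"]) == ["g1"]

    def test_opposite_directions_across_replicates_are_removed(self):
        rep1 = _calls([("g1", "a", "up", 2.0, 3.0)])
        rep2 = _calls([("g1", "a", "down", -1.8, 3.2)])
        assert ts.consensus_across_replicates([rep1, rep2], []).empty

    def test_batch_control_hit_is_removed(self):
        rep1 = _calls([("g1", "a", "up", 2.0, 3.0), ("g2", "a", "up", 2.0, 3.0)])
        rep2 = _calls([("g1", "a", "up", 1.8, 3.2), ("g2", "a", "up", 2.0, 3.0)])
        batch = _calls([("g2", "a", "up", 1.6, 2.9)])
        final = ts.consensus_across_replicates([rep1, rep2], [batch])
        assert list(final["gene"]) == ["g1"]

    def test_missing_from_one_replicate_is_removed(self):
        rep1 = _calls([("g1", "a", "up", 2.0, 3.0)])
        rep2 = _calls([])
        assert ts.consensus_across_replicates([rep1, rep2], []).empty

    def test_same_gene_different_cell_types_are_independent(self):
        rep1 = _calls([("g1", "a", "up", 2.0, 3.0), ("g1", "b", "up", 2.0, 3.0)])
        rep2 = _calls([("g1", "a", "up", 1.5, 3.0)])
        final = ts.consensus_across_replicates([rep1, rep2], [])
        assert list(zip(final["gene"], final["cell_type"])) == [("g1", "a")]

    def test_zero_replicate_contrasts_raise(self):
        with pytest.raises(ValueError):
            ts.consensus_across_replicates([], [])


class TestVolcanoCollapse:
    def test_single_subset_record_passes_through(self):
        calls = _calls([("g1", "a", "up", 1.2, 3.0)])
        out = ts.collapse_for_volcano(calls)
        assert out.loc[0, "lfc_mean"] == 1.2

    def test_magnitude_wins_over_sign(self):
        calls = _calls([("g1", "a", "up", 1.2, 5.0), ("g1", "b", "down", -2.0, 3.0)])
        out = ts.collapse_for_volcano(calls)
        assert out.loc[0, "lfc_mean"] == -2.0
        assert out.loc[0, "bayes_factor"] == 3.0  # the record's own BF

    def test_tie_breaks_by_bayes_factor_then_cell_type(self):
        calls = _calls([("g1", "b", "up", 2.0, 3.0), ("g1", "a", "up", 2.0, 4.0)])
        assert ts.collapse_for_volcano(calls).loc[0, "cell_type"] == "a"
        calls = _calls([("g1", "b", "up", 2.0, 3.0), ("g1", "a", "up", 2.0, 3.0)])
        assert ts.collapse_for_volcano(calls).loc[0, "cell_type"] == "a"


class TestCountDirections:
    def test_empty_set(self):
        assert ts.count_directions(pd.DataFrame()) == (0, 0)

    def test_simple_tally(self):
        calls = _calls([("g1", "a", "up", 1, 3), ("g2", "a", "up", 1, 3),
                        ("g3", "a", "up", 1, 3), ("g4", "a", "down", -1, 3),
                        ("g5", "a", "down", -1, 3)])
        assert ts.count_directions(calls) == (3, 2)


# ------------------------------------------------------------------ end-to-end

class TestConsensusDEPipeline:
    def test_recovers_planted_program(self, small_experiment):
        _, adata, truth = small_experiment
        est = ts.ConsensusDE(seed=3).fit(adata)
        final_genes = set(est.final_calls_["gene"])
        planted = set(truth.regulated_calls["gene"])
        assert len(final_genes & planted) / len(planted) >= 0.9
        assert len(final_genes - planted) / max(len(final_genes), 1) <= 0.05

    def test_batch_genes_are_removed_by_consensus(self, small_experiment):
        _, adata, truth = small_experiment
        est = ts.ConsensusDE(seed=3).fit(adata)
        assert not set(est.final_calls_["gene"]) & set(truth.batch_genes)
        # the controls actually fired: batch genes were detected somewhere
        batch_hits = set(pd.concat(est.batch_calls_)["gene"]) if est.batch_calls_ else set()
        assert set(truth.batch_genes) <= batch_hits

    def test_direction_matches_planted_sign(self, small_experiment):
        _, adata, truth = small_experiment
        est = ts.ConsensusDE(seed=3).fit(adata)
        merged = est.final_calls_.merge(truth.regulated_calls, on="gene")
        # induced by the factor = lower in the KO = "down" in the KO-vs-WT lfc
        expect = merged["direction_y"].map({"induced": "down", "repressed": "up"})
        assert (merged["direction_x"] == expect).all()
        assert (merged["tf_effect"] == merged["direction_y"]).all()

    def test_direction_consistent_with_lfc_sign(self, small_experiment):
        _, adata, _ = small_experiment
        est = ts.ConsensusDE(seed=3).fit(adata)
        up = est.final_calls_["direction"] == "up"
        assert (est.final_calls_.loc[up, "lfc_mean"] > 0).all()
        assert (est.final_calls_.loc[~up, "lfc_mean"] < 0).all()

    def test_requires_two_replicates(self):
        spec = ts.ExperimentSpec(replicates_per_genotype=1,
                                 n_cells_per_sample=100, n_genes=50, seed=1)
        adata, _ = ts.simulate_tec_experiment(spec)
        with pytest.raises(ValueError, match="2 replicate"):
            ts.ConsensusDE().fit(adata)
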