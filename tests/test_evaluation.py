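import numpy as np
import pytest

from c3net import (
    EvalResult,
    MIMatrix,
    Network,
    ScoredNetwork,
    compare_networks,
    edge_tpr,
    ensemble_summary,
    mean_score_per_edge,
    optimal_cutoff,
)

from oracles import brute_confusion, brute_optimal_cutoff


def net(ids, pairs) -> Network:
    return Network.from_edge_indices(ids, pairs)


IDS6 = [f"g{i}" for i in range(6)]


class TestCompareNetworks:
    def test_perfect_inference_scores_one(self):
        truth = net(IDS6, [(0, 1), (2, 3)])
        res = compare_networks(truth, truth)
        assert (res.TP, res.FP, res.FN) == (2, 0, 0)
        assert res.fscore == 1.0

    def test_reported_precision_of_74_over_99(self):
        # 74 true positives and 25 false positives give precision 0.75
        res = EvalResult(TP=74, FP=25, FN=3017)
        assert res.precision == pytest.approx(74 / 99)
        assert round(res.precision, 2) == 0.75

    def test_counts_match_set_arithmetic_oracle(self):
        rng = np.random.default_rng(40)
        all_pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        for _ in range(100):
            inf_pairs = {p for p in all_pairs if rng.random() < 0.4}
            true_pairs = {p for p in all_pairs if rng.random() < 0.4}
            res = compare_networks(net(IDS6, inf_pairs), net(IDS6, true_pairs))
            assert (res.TP, res.FP, res.FN) == brute_confusion(inf_pairs, true_pairs)

    def test_candidate_mask_discards_outside_edges(self):
        truth = net(IDS6, [(0, 1)])
        inferred = net(IDS6, [(0, 1), (4, 5)])
        full = compare_networks(inferred, truth)
        masked = compare_networks(inferred, truth, candidate_mask={(0, 1), (2, 3)})
        assert full.FP == 1 and masked.FP == 0
        assert masked.fscore == 1.0

    def test_gene_universe_mismatch_raises_with_ids(self):
        with pytest.raises(ValueError, match="gX"):
            compare_networks(net(IDS6, []), net(IDS6[:-1] + ["gX"], []))

    def test_empty_inferred_network_has_zero_fscore(self):
        res = compare_networks(net(IDS6, []), net(IDS6, [(0, 1)]))
        assert res.fscore == 0.0


class TestOptimalCutoff:
    def scored(self, ids, weights) -> ScoredNetwork:
        w = np.asarray(weights, dtype=float)
        return ScoredNetwork(ids, (w + w.T) / 2)

    def test_perfect_separation_reaches_f_one(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.9
        w[2, 3] = w[3, 2] = 0.8
        w[0, 2] = w[2, 0] = 0.1
        scores = ScoredNetwork(["a", "b", "c", "d"], w)
        truth = net(["a", "b", "c", "d"], [(0, 1), (2, 3)])
        thr, res = optimal_cutoff(scores, truth)
        assert res.fscore == 1.0
        assert 0.1 < thr <= 0.8

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(41)
        ids = [f"g{i}" for i in range(5)]
        pairs = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        for _ in range(100):
            w = np.zeros((5, 5))
            pair_scores = {}
            for i, j in pairs:
                s = float(rng.choice([0.0, 0.2, 0.4, 0.6, 0.8]))
                w[i, j] = w[j, i] = s
                pair_scores[(i, j)] = s
            true_pairs = {p for p in pairs if rng.random() < 0.35}
            if not true_pairs:
                continue
            truth = net(ids, true_pairs)
            thr, res = optimal_cutoff(ScoredNetwork(ids, w), truth)
            o_thr, o_f = brute_optimal_cutoff(pair_scores, true_pairs)
            assert res.fscore == pytest.approx(o_f, abs=1e-12)
            assert thr == pytest.approx(o_thr, abs=1e-12)

    def test_maximality_over_arbitrary_thresholds(self):
        rng = np.random.default_rng(42)
        ids = [f"g{i}" for i in range(6)]
        w = rng.uniform(size=(6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        scores = ScoredNetwork(ids, w)
        truth = net(ids, [(0, 1), (1, 2), (3, 4)])
        _, best = optimal_cutoff(scores, truth)
        for thr in rng.uniform(0, 1, size=25):
            res = compare_networks(scores.threshold(float(thr)), truth)
            assert best.fscore >= res.fscore - 1e-12

    def test_mask_closure_ignores_outside_pairs(self):
        ids = [f"g{i}" for i in range(4)]
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.9
        truth = net(ids, [(0, 1)])
        mask = {(0, 1), (1, 2)}
        base = optimal_cutoff(ScoredNetwork(ids, w.copy()), truth, candidate_mask=mask)
        w[2, 3] = w[3, 2] = 0.95  # outside the mask
        spiked = optimal_cutoff(ScoredNetwork(ids, w), truth, candidate_mask=mask)
        assert base == spiked

    def test_empty_truth_rejected(self):
        ids = ["a", "b", "c"]
        scores = ScoredNetwork(ids, np.zeros((3, 3)))
        with pytest.raises(ValueError):
            optimal_cutoff(scores, net(ids, []))


class TestEnsembleSummary:
    def test_single_result_repeats_its_value(self):
        res = EvalResult(TP=1, FP=1, FN=1)
        s = ensemble_summary([res])
        assert set(s.values()) == {res.fscore}

    def test_three_value_arithmetic(self):
        s = ensemble_summary([0.2, 0.4, 0.6])
        assert s == {"max": 0.6, "min": 0.2, "mean": pytest.approx(0.4), "median": 0.4}

    def test_matches_order_statistics_on_random_vector(self):
        rng = np.random.default_rng(43)
        fs = rng.uniform(size=300).tolist()
        s = ensemble_summary(fs)
        srt = sorted(fs)
        assert s["max"] == srt[-1] and s["min"] == srt[0]
        assert s["median"] == pytest.approx((srt[149] + srt[150]) / 2)
        assert s["mean"] == pytest.approx(sum(fs) / 300)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ensemble_summary([])


class TestEdgeTPR:
    def test_bin_assignment(self):
        ids = ["a", "b", "c"]
        truth = net(ids, [(0, 1), (1, 2), (0, 2)])
        always = net(ids, [(0, 1), (0, 2)])
        sometimes = net(ids, [(0, 1), (1, 2)])
        ensemble = [always] * 6 + [sometimes] * 4
        stats = edge_tpr(ensemble, truth)
        assert stats[(0, 1)] == (1.0, "black")
        assert stats[(1, 2)] == (0.4, "green")
        assert stats[(0, 2)] == (0.6, "blue")

    def test_never_recovered_edge_is_red(self):
        ids = ["a", "b", "c"]
        truth = net(ids, [(0, 1)])
        stats = edge_tpr([net(ids, [])] * 5, truth)
        assert stats[(0, 1)] == (0.0, "red")

    def test_boundaries_are_upper_closed(self):
        ids = ["a", "b"]
        truth = net(ids, [(0, 1)])
        present = net(ids, [(0, 1)])
        absent = net(ids, [])
        stats = edge_tpr([present] * 3 + [absent], truth)  # exactly 0.75
        assert stats[(0, 1)][1] == "blue"
        stats = edge_tpr([present] * 1 + [absent] * 3, truth)  # exactly 0.25
        assert stats[(0, 1)][1] == "red"


class TestMeanScorePerEdge:
    def test_single_edge_returns_its_score(self, worked_mi):
        network = net(list(worked_mi.gene_ids), [(0, 3)])
        assert mean_score_per_edge(worked_mi, network) == pytest.approx(0.8)

    def test_worked_example_star_average(self, worked_mi):
        star = net(list(worked_mi.gene_ids), [(0, 1), (0, 2), (0, 3)])
        assert mean_score_per_edge(worked_mi, star) == pytest.approx(0.8)

    def test_ignores_scores_of_non_edges(self, worked_mi):
        star = net(list(worked_mi.gene_ids), [(0, 1), (0, 2), (0, 3)])
        spiked = MIMatrix(list(worked_mi.gene_ids), worked_mi.values.copy())
        spiked.values[1, 2] = spiked.values[2, 1] = 99.0
        assert mean_score_per_edge(spiked, star) == pytest.approx(0.8)

    def test_empty_network_rejected(self, worked_mi):
        with pytest.raises(ValueError):
            mean_score_per_edge(worked_mi, net(list(worked_mi.gene_ids), []))
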