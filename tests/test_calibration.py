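import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from codac.calibration import (
    GoldStandard,
    WEIGHT_GRID,
    build_gold_standard,
    filter_similarity,
    optimize_weights,
    roc_auc,
    select_threshold,
    shuffle_bigraph,
    split_gold_standard,
)
from codac.errors import (
    DegenerateCalibrationError,
    ShuffleInfeasibleError,
    ValidationError,
)
from codac.graph import Bigraph
from codac.similarity import consensus

from conftest import random_bigraph
from test_similarity import sim_from_dict


# ----------------------------------------------------------------- oracles


def grid_scan_oracle(scores, gs):
    """Independent full scan of all 1001 thresholds.

    Same documented tie-break as the implementation: the middle grid index
    among thresholds achieving the maximal Training F1.
    """
    train_pos = [p for p in gs.positives if gs.split[p] == "train"]
    train_neg = [p for p in gs.negatives if gs.split[p] == "train"]
    f1s = []
    for i in range(1001):
        t = i / 1000.0
        tp = sum(1 for p in train_pos if scores.get(p, 0.0) > t)
        fp = sum(1 for p in train_neg if scores.get(p, 0.0) > t)
        fn = len(train_pos) - tp
        r = tp / (tp + fn) if tp + fn else 0.0
        pr = tp / (tp + fp) if tp + fp else 0.0
        f1s.append(2 * r * pr / (r + pr) if r + pr else 0.0)
    best = max(f1s)
    plateau = [i for i, v in enumerate(f1s) if v == best]
    idx = plateau[len(plateau) // 2]
    return idx / 1000.0, f1s[idx]


def mann_whitney_oracle(scores, positives):
    """AUC by counting all positive×background comparisons, ties 0.5."""
    pos = [scores.get(p, 0.0) for p in positives]
    bg = [v for p, v in scores.items() if p not in positives]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in bg)
    return wins / (len(pos) * len(bg))


def make_gold(pos_scores, neg_scores):
    """Gold standard whose training half is everything (test empty mirror)."""
    positives = {(f"x{i}", "y"): s for i, s in enumerate(pos_scores)}
    negatives = {(f"u{i}", "v"): s for i, s in enumerate(neg_scores)}
    gs = GoldStandard(
        positives=frozenset(positives),
        negatives=frozenset(negatives),
        split={p: "train" for p in [*positives, *negatives]},
    )
    return gs, {**positives, **negatives}


# ----------------------------------------------------------------- shuffle


class TestShuffleBigraph:
    def test_two_edge_graph_has_unique_shuffle(self):
        g = Bigraph.from_edges({("x1", "z1"), ("x2", "z2")})
        out = shuffle_bigraph(g, seed=0)
        assert out.edges == frozenset({("x1", "z2"), ("x2", "z1")})

    def test_complete_bipartite_is_infeasible(self):
        k22 = Bigraph.from_edges(
            {(x, z) for x in ("x1", "x2") for z in ("z1", "z2")}
        )
        with pytest.raises(ShuffleInfeasibleError):
            shuffle_bigraph(k22, seed=0, max_tries=10)

    def test_preserves_degrees_with_zero_overlap(self, rng):
        for trial in range(20):
            g = random_bigraph(rng, 8, 10, 0.25, "x", "z")
            if g.n_edges < 2:
                continue
            try:
                s = shuffle_bigraph(g, seed=trial)
            except ShuffleInfeasibleError:
                continue
            assert s.left_degrees() == g.left_degrees()
            assert s.right_degrees() == g.right_degrees()
            assert not (s.edges & g.edges)
            assert s.n_edges == g.n_edges

    def test_deterministic_given_seed(self):
        g = Bigraph.from_edges({(f"x{i}", f"z{i}") for i in range(10)})
        a, b = shuffle_bigraph(g, seed=5), shuffle_bigraph(g, seed=5)
        assert a.edges == b.edges
        assert not (a.edges & g.edges)

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValidationError, match="2 edges"):
            shuffle_bigraph(Bigraph.from_edges({("x", "z")}), seed=0)


# ----------------------------------------------------- gold standard build


class TestGoldStandard:
    def setup_method(self):
        entries = {(f"x{i}", f"y{j}"): 0.1 + 0.001 * (i + j) for i in range(20) for j in range(20)}
        self.shuffled = sim_from_dict("sh", entries)

    def test_counts_and_exclusion(self):
        e3 = {(f"x{i}", f"y{i}") for i in range(10)}
        gs = build_gold_standard(e3, self.shuffled, seed=1)
        assert gs.positives == frozenset(e3)
        assert len(gs.negatives) == len(e3)
        assert not gs.negatives & gs.positives

    def test_empty_known_set_rejected(self):
        with pytest.raises(DegenerateCalibrationError, match="no known"):
            build_gold_standard(set(), self.shuffled, seed=1)

    def test_insufficient_candidates_rejected(self):
        small = sim_from_dict("sh", {("x0", "y0"): 0.2})
        e3 = {("a1", "b1"), ("a2", "b2")}
        with pytest.raises(DegenerateCalibrationError, match="eligible"):
            build_gold_standard(e3, small, seed=1)

    def test_deterministic_given_seed(self):
        e3 = {(f"x{i}", f"y{i}") for i in range(10)}
        g1 = build_gold_standard(e3, self.shuffled, seed=3)
        g2 = build_gold_standard(e3, self.shuffled, seed=3)
        assert g1.negatives == g2.negatives

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValidationError, match=r"\|N\| must equal \|P\|"):
            GoldStandard(
                positives=frozenset({("a", "b")}),
                negatives=frozenset({("c", "d"), ("e", "f")}),
            )


class TestSplitGoldStandard:
    def _gold(self, n):
        return GoldStandard(
            positives=frozenset((f"x{i}", "y") for i in range(n)),
            negatives=frozenset((f"u{i}", "v") for i in range(n)),
        )

    @pytest.mark.parametrize("n, n_train", [(100, 50), (101, 51)])
    def test_equal_distributions(self, n, n_train):
        gs = split_gold_standard(self._gold(n), seed=0)
        tr_pos, tr_neg = gs.half("train")
        te_pos, te_neg = gs.half("test")
        assert len(tr_pos) == len(tr_neg) == n_train
        assert len(te_pos) == len(te_neg) == n - n_train

    def test_deterministic_given_seed(self):
        a = split_gold_standard(self._gold(21), seed=9)
        b = split_gold_standard(self._gold(21), seed=9)
        assert a.split == b.split

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError, match="at least 2"):
            split_gold_standard(self._gold(1), seed=0)


# -------------------------------------------------------------- threshold


class TestSelectThreshold:
    def test_perfect_separation_reaches_f1_one(self):
        gs, scores = make_gold([0.9, 0.8], [0.1, 0.2])
        res = select_threshold(scores, gs)
        assert res.f_train == pytest.approx(1.0)
        assert 0.2 <= res.threshold < 0.8
        assert res.precision == pytest.approx(1.0)
        assert res.recall == pytest.approx(1.0)

    def test_all_tied_scores(self):
        # one positive and one negative both at 0.5: any t < 0.5 predicts both
        # positive (F1 = 2/3); t >= 0.5 predicts nothing (F1 = 0)
        gs, scores = make_gold([0.5], [0.5])
        res = select_threshold(scores, gs)
        assert res.f_train == pytest.approx(2 / 3)
        assert res.threshold < 0.5

    def test_zero_scored_positives_degenerate(self):
        # nothing exceeds any threshold under the strict rule, so F1 is 0
        gs, scores = make_gold([0.0, 0.0], [0.0, 0.0])
        res = select_threshold(scores, gs)
        assert res.f_train == 0.0

    def test_no_training_positives_rejected(self):
        gs = GoldStandard(
            positives=frozenset({("a", "b")}),
            negatives=frozenset({("c", "d")}),
            split={("a", "b"): "test", ("c", "d"): "train"},
        )
        with pytest.raises(DegenerateCalibrationError, match="Training"):
            select_threshold({}, gs)

    def test_matches_full_grid_scan_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 30))
            pos = np.round(rng.random(n), 3)
            neg = np.round(rng.random(n) * rng.random(), 3)
            gs, scores = make_gold(pos.tolist(), neg.tolist())
            res = select_threshold(scores, gs)
            t_oracle, f1_oracle = grid_scan_oracle(scores, gs)
            assert res.threshold == pytest.approx(t_oracle, abs=1e-12)
            assert res.f_train == pytest.approx(f1_oracle, abs=1e-12)


# -------------------------------------------------------------------- AUC


class TestRocAuc:
    def test_perfect_ranking(self):
        scores = {("p", "1"): 0.9, ("p", "2"): 0.8, ("b", "1"): 0.2, ("b", "2"): 0.1}
        assert roc_auc(scores, {("p", "1"), ("p", "2")}) == pytest.approx(1.0)

    def test_all_tied_is_half(self):
        scores = {("p", "1"): 0.4, ("b", "1"): 0.4, ("b", "2"): 0.4}
        assert roc_auc(scores, {("p", "1")}) == pytest.approx(0.5)

    def test_mixed_example(self):
        # positives {0.9, 0.4} vs background {0.6, 0.1}: 3 of 4 wins
        scores = {("p", "1"): 0.9, ("p", "2"): 0.4, ("b", "1"): 0.6, ("b", "2"): 0.1}
        assert roc_auc(scores, {("p", "1"), ("p", "2")}) == pytest.approx(0.75)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateCalibrationError):
            roc_auc({("p", "1"): 0.5}, {("p", "1")})

    def test_matches_pairwise_counting_and_sklearn(self, rng):
        for _ in range(20):
            n_pos, n_bg = int(rng.integers(1, 30)), int(rng.integers(1, 30))
            # coarse scores force ties
            scores = {("p", str(i)): round(float(rng.random()), 1) for i in range(n_pos)}
            scores.update(
                {("b", str(i)): round(float(rng.random()), 1) for i in range(n_bg)}
            )
            positives = {p for p in scores if p[0] == "p"}
            got = roc_auc(scores, positives)
            assert got == pytest.approx(mann_whitney_oracle(scores, positives), abs=1e-12)
            y = [1 if p in positives else 0 for p in scores]
            v = [scores[p] for p in scores]
            assert got == pytest.approx(roc_auc_score(y, v), abs=1e-12)


# ---------------------------------------------------------- weight search


def random_instance(rng, n_pairs=30, separation=0.5):
    pos = {(f"x{i}", f"y{i}") for i in range(6)}
    entries_a, entries_b = {}, {}
    for i in range(n_pairs):
        pair = (f"x{i}", f"y{i}")
        bonus = separation if pair in pos else 0.0
        entries_a[pair] = min(1.0, float(rng.random() * 0.5 + bonus))
        entries_b[pair] = min(1.0, float(rng.random() * 0.5 + bonus * rng.random()))
    return [sim_from_dict("a", entries_a), sim_from_dict("b", entries_b)], pos


class TestOptimizeWeights:
    def test_single_dataset_weight_is_one(self):
        sims, pos = random_instance(np.random.default_rng(0))
        res = optimize_weights(sims[:1], pos)
        assert res.weights == {"a": 1.0}
        assert res.auc == pytest.approx(roc_auc(sims[0].to_dict(), pos))

    def test_identical_datasets_keep_equal_weights(self):
        sims, pos = random_instance(np.random.default_rng(1))
        twin = sim_from_dict("b", sims[0].to_dict())
        res = optimize_weights([sims[0], twin], pos)
        assert res.weights == {"a": 1.0, "b": 1.0}

    def test_informative_dataset_dominates(self):
        # dataset a ranks positives perfectly, dataset b inverts the ranking
        pos = {(f"x{i}", f"y{i}") for i in range(5)}
        pairs = [(f"x{i}", f"y{i}") for i in range(10)]
        a = {p: (1.0 - 0.05 * i if p in pos else 0.4 - 0.03 * i) for i, p in enumerate(pairs)}
        b = {p: (0.1 if p in pos else 0.9) for p in pairs}
        sims = [sim_from_dict("a", a), sim_from_dict("b", b)]
        equal_auc = roc_auc(consensus(sims, {"a": 1.0, "b": 1.0}).to_dict(), pos)
        res = optimize_weights(sims, pos, strategy="exhaustive")
        # the informative dataset outweighs the adversarial one, and the AUC
        # plateau once it dominates means the first maximum need not sit at
        # the extreme grid ratio
        assert res.weights["a"] > res.weights["b"]
        assert res.auc >= equal_auc
        assert res.auc == pytest.approx(1.0)

    def test_coordinate_ascent_matches_exhaustive_on_two_datasets(self, rng):
        for trial in range(5):
            sims, pos = random_instance(rng, separation=0.3)
            ex = optimize_weights(sims, pos, strategy="exhaustive")
            ca = optimize_weights(sims, pos, strategy="coordinate_ascent")
            assert ca.auc == pytest.approx(ex.auc, abs=1e-12)

    def test_never_below_equal_weights(self, rng):
        sims, pos = random_instance(rng, separation=0.2)
        equal_auc = roc_auc(consensus(sims, {"a": 1.0, "b": 1.0}).to_dict(), pos)
        res = optimize_weights(sims, pos, strategy="coordinate_ascent")
        assert res.auc >= equal_auc - 1e-12

    def test_exhaustive_rejected_above_three_datasets(self, rng):
        sims, pos = random_instance(rng)
        many = [sim_from_dict(f"d{i}", sims[0].to_dict()) for i in range(4)]
        with pytest.raises(ValidationError, match="combinations"):
            optimize_weights(many, pos, strategy="exhaustive")

    def test_weights_lie_on_grid(self, rng):
        sims, pos = random_instance(rng)
        res = optimize_weights(sims, pos)
        for w in res.weights.values():
            assert any(math.isclose(w, g) for g in WEIGHT_GRID)


# ----------------------------------------------------------------- filter


class TestFilterSimilarity:
    def _cs(self, entries):
        s = sim_from_dict("a", entries)
        return consensus([s], {"a": 1.0})

    def test_strict_threshold(self):
        cs = self._cs({("x", "y"): 0.5, ("u", "v"): 0.3})
        out = filter_similarity(cs, 0.3, e3=set())
        assert out.to_dict() == {("x", "y"): pytest.approx(0.5)}

    def test_known_pair_survives_below_threshold(self):
        cs = self._cs({("x", "y"): 0.001})
        out = filter_similarity(cs, 0.005, e3={("x", "y")})
        assert out.to_dict() == {("x", "y"): pytest.approx(0.001)}

    def test_kept_set_is_union_and_idempotent(self, rng):
        entries = {
            (f"x{i}", f"y{j}"): round(float(rng.random()), 3)
            for i in range(8)
            for j in range(8)
        }
        e3 = {("x0", "y0"), ("x1", "y5")}
        cs = self._cs(entries)
        t = 0.6
        out = filter_similarity(cs, t, e3)
        expected = {p for p, v in entries.items() if v > t} | {
            p for p in e3 if entries.get(p, 0.0) > 0
        }
        assert set(out.to_dict()) == expected
        again = filter_similarity(out, t, e3)
        assert again.to_dict() == out.to_dict()

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            filter_similarity(self._cs({("x", "y"): 0.5}), 1.5, set())
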