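"""Score calibration against a shuffled-graph gold standard.

The only ground truth available is the sparse set of known X–Y associations
(E3).  Those are the positive examples.  Negative examples are manufactured
by shuffling the X–Z and Y–Z layers under a degree-preserving null model
(every item keeps its degree, no shuffled edge may coincide with an original
one), scoring the shuffled graphs with the same cosine machinery, and
sampling |N| = |P| of the resulting chance-level pairs.  The gold standard
is split in half into Training/Test; the decision threshold is the grid
value maximising the Training F-measure, and dataset weights are chosen to
maximise the ROC AUC of known positives against all other scored pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.stats import rankdata

from .errors import DegenerateCalibrationError, ShuffleInfeasibleError, ValidationError
from .graph import Bigraph
from .similarity import ConsensusSimilarity, DatasetSimilarity, consensus

__all__ = [
    "GoldStandard",
    "CalibrationResult",
    "WeightSearchResult",
    "THRESHOLD_GRID",
    "WEIGHT_GRID",
    "shuffle_bigraph",
    "build_gold_standard",
    "split_gold_standard",
    "select_threshold",
    "roc_auc",
    "optimize_weights",
    "filter_similarity",
]

#: Decision-threshold grid: 0.0 to 1.0 in steps of 0.001.
THRESHOLD_GRID = np.round(np.arange(1001) / 1000.0, 3)

#: Dataset-weight grid: 1.0 to 10.0 in steps of 0.1.
WEIGHT_GRID = tuple(np.round(np.arange(10, 101) / 10.0, 1))

Pair = tuple[str, str]


@dataclass(frozen=True)
class GoldStandard:
    """Labelled calibration pairs: known positives and shuffled negatives.

    ``split`` maps each pair to ``"train"`` or ``"test"`` once
    :func:`split_gold_standard` has run; it is empty before that.
    """

    positives: frozenset[Pair]
    negatives: frozenset[Pair]
    split: Mapping[Pair, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValidationError("gold standard positives and negatives overlap")
        if len(self.negatives) != len(self.positives):
            raise ValidationError(
                f"|N| must equal |P| ({len(self.negatives)} != {len(self.positives)})"
            )

    def half(self, which: str) -> tuple[list[Pair], list[Pair]]:
        """(positives, negatives) of one split half, in sorted pair order."""
        pos = sorted(p for p in self.positives if self.split.get(p) == which)
        neg = sorted(p for p in self.negatives if self.split.get(p) == which)
        return pos, neg


@dataclass(frozen=True)
class CalibrationResult:
    """Selected decision threshold and the F-measures that justify it."""

    threshold: float
    f_train: float
    f_test: float
    precision: float
    recall: float


@dataclass(frozen=True)
class WeightSearchResult:
    """Dataset weights (on the 1.0–10.0 grid) and the AUC they achieve."""

    weights: dict[str, float]
    auc: float


def shuffle_bigraph(g: Bigraph, seed: int, max_tries: int = 50) -> Bigraph:
    """Degree-preserving edge shuffle with zero overlap with the original.

    Random double-edge swaps — replace edges (a, b), (c, d) by (a, d),
    (c, b) — preserve every node degree by construction; 10·|E| swap
    attempts randomise the graph, after which any residual edges that
    coincide with originals are removed by targeted swaps.  If a fully
    non-overlapping arrangement is not reached the procedure restarts, up
    to ``max_tries`` times, and then raises
    :class:`~codac.errors.ShuffleInfeasibleError` (which is also the correct
    outcome when no such arrangement exists at all, e.g. for a complete
    bipartite graph).
    """
    if g.n_edges < 2:
        raise ValidationError("shuffling needs at least 2 edges")
    rng = np.random.default_rng(seed)
    orig = frozenset(g.edges)
    base = sorted(orig)
    m = len(base)

    for _ in range(max_tries):
        cur = list(base)
        cur_set = set(cur)

        def try_swap(i: int, j: int, forbid_orig: bool) -> bool:
            (a, b), (c, d) = cur[i], cur[j]
            if a == c or b == d:
                return False
            e1, e2 = (a, d), (c, b)
            if e1 in cur_set or e2 in cur_set:
                return False
            if forbid_orig and (e1 in orig or e2 in orig):
                return False
            cur_set.discard(cur[i])
            cur_set.discard(cur[j])
            cur_set.add(e1)
            cur_set.add(e2)
            cur[i], cur[j] = e1, e2
            return True

        for _ in range(10 * m):
            i, j = rng.integers(0, m, size=2)
            if i != j:
                try_swap(int(i), int(j), forbid_orig=False)

        budget = 100 * m
        while budget > 0:
            overlap = [k for k, e in enumerate(cur) if e in orig]
            if not overlap:
                break
            k = int(rng.choice(overlap))
            j = int(rng.integers(0, m))
            if j != k:
                try_swap(k, j, forbid_orig=True)
            budget -= 1

        if not (cur_set & orig):
            return Bigraph(g.left_items, g.right_items, frozenset(cur_set))

    raise ShuffleInfeasibleError(
        f"no degree-preserving non-overlapping shuffle found in {max_tries} tries "
        f"({m} edges); the graph may admit none"
    )


def build_gold_standard(
    e3: Iterable[Pair],
    shuffled_sim: DatasetSimilarity | ConsensusSimilarity,
    seed: int,
) -> GoldStandard:
    """Positives = known associations; negatives sampled from shuffled scores.

    Negatives are drawn uniformly without replacement from the nonzero
    entries of the shuffled-graph similarity matrix (chance-level pairs with
    a real, nonzero score), excluding anything in ``e3``.
    """
    positives = frozenset(tuple(p) for p in e3)
    if not positives:
        raise DegenerateCalibrationError("no known associations: cannot calibrate")
    candidates = sorted(set((x, y) for x, y, _ in shuffled_sim.items()) - positives)
    if len(candidates) < len(positives):
        raise DegenerateCalibrationError(
            f"only {len(candidates)} eligible shuffled pairs for "
            f"{len(positives)} required negatives"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=len(positives), replace=False)
    negatives = frozenset(candidates[i] for i in idx)
    return GoldStandard(positives=positives, negatives=negatives)


def split_gold_standard(gs: GoldStandard, seed: int) -> GoldStandard:
    """Random half/half Training–Test split, stratified by label.

    Each half receives half of the positives and half of the negatives
    (Training takes the extra item on odd counts), so the two halves keep
    equal positive:negative distributions.
    """
    if len(gs.positives) < 2 or len(gs.negatives) < 2:
        raise ValidationError("need at least 2 positives and 2 negatives to split")
    rng = np.random.default_rng(seed)
    split: dict[Pair, str] = {}
    for pairs in (sorted(gs.positives), sorted(gs.negatives)):
        order = rng.permutation(len(pairs))
        n_train = math.ceil(len(pairs) / 2)
        for rank, i in enumerate(order):
            split[pairs[i]] = "train" if rank < n_train else "test"
    return replace(gs, split=split)


def _f_measure(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        denom = precision + recall
        return np.where(denom > 0, 2 * precision * recall / denom, 0.0)


def _counts_above(sorted_scores: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Number of scores strictly greater than each threshold."""
    return len(sorted_scores) - np.searchsorted(sorted_scores, thresholds, side="right")


def select_threshold(scores: Mapping[Pair, float], gs: GoldStandard) -> CalibrationResult:
    """Pick the grid threshold maximising the Training-half F-measure.

    A pair is predicted positive iff its score is strictly greater than the
    threshold; pairs missing from ``scores`` count as scored 0.  Ties on the
    maximal F-measure resolve to the *middle* of the optimal plateau (the
    median grid index among thresholds achieving the maximum): the lower
    plateau edge hugs the sampled negatives, whose maximum underestimates
    the tail of the much larger unlabelled background, while the upper edge
    hugs the training positives' minimum and generalises poorly when |P| is
    small — the midpoint keeps the margin to both.  The Test half provides
    an independent F-measure at the selected threshold.
    """
    train_pos, train_neg = gs.half("train")
    test_pos, test_neg = gs.half("test")
    if not train_pos:
        raise DegenerateCalibrationError("no positives in the Training half")

    def _scored(pairs: Sequence[Pair]) -> np.ndarray:
        return np.sort(np.array([scores.get(p, 0.0) for p in pairs], dtype=float))

    p_tr, n_tr = _scored(train_pos), _scored(train_neg)
    tp = _counts_above(p_tr, THRESHOLD_GRID).astype(float)
    fp = _counts_above(n_tr, THRESHOLD_GRID).astype(float)
    fn = len(p_tr) - tp
    f1 = _f_measure(tp, fp, fn)
    plateau = np.flatnonzero(f1 == f1.max())
    best = int(plateau[len(plateau) // 2])  # midpoint of the optimal plateau
    t = float(THRESHOLD_GRID[best])

    p_te, n_te = _scored(test_pos), _scored(test_neg)
    if len(p_te):
        tp_te = _counts_above(p_te, np.array([t])).astype(float)
        fp_te = _counts_above(n_te, np.array([t])).astype(float)
        f_test = float(_f_measure(tp_te, fp_te, len(p_te) - tp_te)[0])
    else:
        f_test = float("nan")

    precision = float(tp[best] / (tp[best] + fp[best])) if tp[best] + fp[best] > 0 else 0.0
    recall = float(tp[best] / len(p_tr))
    return CalibrationResult(
        threshold=t,
        f_train=float(f1[best]),
        f_test=f_test,
        precision=precision,
        recall=recall,
    )


def _auc_from_vector(values: np.ndarray, is_pos: np.ndarray) -> float:
    """Mann–Whitney AUC with ties credited 0.5, from midranks."""
    n_pos = int(is_pos.sum())
    n_bg = len(values) - n_pos
    if n_pos == 0 or n_bg == 0:
        raise DegenerateCalibrationError("AUC needs at least one positive and one background pair")
    ranks = rankdata(values)
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_bg))


def roc_auc(scores: Mapping[Pair, float], positives: Iterable[Pair]) -> float:
    """AUC of the score ranking: positives vs. all other scored pairs.

    Positives missing from ``scores`` are included at score 0 (ranked with
    the unscored mass), so weights that drop known positives are penalised.
    """
    positives = set(tuple(p) for p in positives)
    background = [p for p in scores if p not in positives]
    vals = np.array(
        [scores.get(p, 0.0) for p in sorted(positives)] + [scores[p] for p in background],
        dtype=float,
    )
    is_pos = np.zeros(len(vals), dtype=bool)
    is_pos[: len(positives)] = True
    return _auc_from_vector(vals, is_pos)


def _score_table(
    sims: Sequence[DatasetSimilarity], positives: set[Pair]
) -> tuple[np.ndarray, np.ndarray, list[Pair]]:
    """Dense (n_datasets × n_pairs) score table over the pair universe.

    The universe is every pair scored nonzero in any dataset, plus every
    positive (zero-filled where absent).
    """
    universe: set[Pair] = set(positives)
    per_ds: list[dict[Pair, float]] = []
    for s in sims:
        d = s.to_dict()
        per_ds.append(d)
        universe.update(d)
    pairs = sorted(universe)
    index = {p: i for i, p in enumerate(pairs)}
    table = np.zeros((len(sims), len(pairs)))
    for row, d in enumerate(per_ds):
        for p, v in d.items():
            table[row, index[p]] = v
    is_pos = np.array([p in positives for p in pairs], dtype=bool)
    return table, is_pos, pairs


def optimize_weights(
    sims: Sequence[DatasetSimilarity],
    positives: Iterable[Pair],
    strategy: str = "coordinate_ascent",
    seed: int = 0,
) -> WeightSearchResult:
    """Search the weight grid for the consensus ranking with maximal AUC.

    The consensus ranking depends on the weights only through their ratios
    (the weighted average divides by Σw), so AUC is evaluated on the
    weighted sum directly.

    ``exhaustive`` enumerates the full grid product and is allowed for at
    most 3 datasets.  ``coordinate_ascent`` (default) starts from all-equal
    weights and sweeps one weight at a time over the grid in dataset input
    order, taking the first grid value achieving the sweep maximum, until a
    full cycle changes nothing (capped at 20 cycles); its AUC can therefore
    never fall below the equal-weights AUC.  ``seed`` is accepted for
    interface uniformity; both strategies are deterministic.
    """
    positives = set(tuple(p) for p in positives)
    if not sims:
        raise ValidationError("weight search needs at least one dataset")
    if not positives:
        raise DegenerateCalibrationError("weight search needs positive examples")
    table, is_pos, _ = _score_table(sims, positives)
    if not is_pos.any() or is_pos.all():
        raise DegenerateCalibrationError("degenerate pair universe for AUC")
    ids = [s.dataset_id for s in sims]
    k = len(sims)
    grid = np.array(WEIGHT_GRID)

    def auc_of(w: np.ndarray) -> float:
        return _auc_from_vector(w @ table, is_pos)

    if k == 1:
        return WeightSearchResult(weights={ids[0]: 1.0}, auc=auc_of(np.array([1.0])))

    if strategy == "exhaustive":
        if k > 3:
            raise ValidationError(
                f"exhaustive search over {len(grid)}^{k} = {len(grid) ** k} weight "
                "combinations is not permitted for more than 3 datasets; use "
                "coordinate_ascent"
            )
        best_w, best_auc = None, -1.0
        for combo in itertools.product(grid, repeat=k):
            a = auc_of(np.array(combo))
            if a > best_auc:
                best_auc, best_w = a, combo
        return WeightSearchResult(
            weights={i: float(w) for i, w in zip(ids, best_w)}, auc=best_auc
        )

    if strategy != "coordinate_ascent":
        raise ValidationError(f"unknown weight search strategy {strategy!r}")

    w = np.ones(k)
    best_auc = auc_of(w)
    for _ in range(20):
        changed = False
        for d in range(k):
            sweep = np.empty(len(grid))
            for gi, val in enumerate(grid):
                trial = w.copy()
                trial[d] = val
                sweep[gi] = auc_of(trial)
            pick = float(grid[int(np.argmax(sweep))])  # first maximum
            if pick != w[d]:
                w[d] = pick
                changed = True
            best_auc = max(best_auc, float(sweep.max()))
        if not changed:
            break
    return WeightSearchResult(weights={i: float(v) for i, v in zip(ids, w)}, auc=auc_of(w))


def filter_similarity(
    cs: ConsensusSimilarity, t: float, e3: Iterable[Pair]
) -> ConsensusSimilarity:
    """Keep scores strictly above the threshold, plus known associations.

    An entry survives iff its score > ``t`` (strict, including at t = 0) or
    the pair is a known association — known pairs keep their score however
    small, so the output never loses curated knowledge.  Idempotent at the
    same threshold.
    """
    if not 0.0 <= t <= 1.0:
        raise ValidationError(f"threshold must lie in [0, 1], got {t!r}")
    e3 = set(tuple(p) for p in e3)
    coo = cs.values.tocoo()
    keep = np.array(
        [
            v > t or (cs.rows[i], cs.cols[j]) in e3
            for i, j, v in zip(coo.row, coo.col, coo.data)
        ],
        dtype=bool,
    )
    filtered = sparse.csr_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])), shape=cs.values.shape
    )
    return ConsensusSimilarity(
        rows=cs.rows, cols=cs.cols, values=filtered, weights=dict(cs.weights)
    )
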