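"""End-to-end association mining as a scikit-learn style estimator.

:class:`AssociationMiner` wires the stages together in the order the method
prescribes: cluster redundant Z items → (optionally) ancestor-propagate the
X–Z layers → cosine-score each evidence dataset → AUC-optimise dataset
weights → build the consensus matrix → construct and split the
shuffled-graph gold standard → select the decision threshold → filter →
attach hypergeometric p-values and quality classes → (optionally) reduce to
most-specific terms.

``fit`` learns the calibration (weights, threshold, gold standard);
``predict`` produces the enriched association records.  All randomness
derives from ``random_state`` through fixed stage offsets, so equal seeds
give identical results.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
from sklearn.base import BaseEstimator

from . import calibration as cal
from .errors import ValidationError
from .graph import Bigraph, ClusterMap, build_biadjacency, cluster_common_items, identity_cluster_map
from .ontology import Ontology, most_specific_filter, propagate_ontology
from .significance import AssociationRecord, annotate_predictions, bonferroni_alpha
from .similarity import DatasetSimilarity, consensus, cosine_similarity

__all__ = ["AssociationMiner", "mine_associations", "recovery_scores"]

Pair = tuple[str, str]

# Stage indices for seed derivation (SeedSequence spawn keys).
_SEED_SHUFFLE, _SEED_NEGATIVES, _SEED_SPLIT, _SEED_WEIGHTS = 0, 1, 2, 3


def _stage_seed(random_state: int, stage: int, sub: int = 0) -> int:
    ss = np.random.SeedSequence([int(random_state), stage, sub])
    return int(ss.generate_state(1)[0] % (2**31))


class AssociationMiner(BaseEstimator):
    """Discover direct X–Y associations from common neighbours in Z.

    Parameters
    ----------
    propagate
        Add each X term's annotations to its ontology ancestors before
        scoring (requires an ontology at fit time).  Off by default.
    most_specific
        Reduce predictions to the per-Y antichain of most-specific terms
        (requires an ontology).  Off by default.
    weight_strategy
        ``"coordinate_ascent"`` (default) or ``"exhaustive"`` (≤3 datasets).
    random_state
        Master seed; shuffling, negative sampling and the train/test split
        each use a seed derived from it.
    max_shuffle_tries
        Restart budget for the degree-preserving shuffle.

    Attributes (after ``fit``)
    --------------------------
    dataset_similarities_ : list of per-dataset cosine matrices
    weights_ : dict, AUC-optimal dataset weights on the 1–10 grid
    auc_ : float, AUC achieved by those weights
    consensus_ : ConsensusSimilarity, the weighted-average score matrix
    gold_standard_ : GoldStandard with train/test split
    calibration_ : CalibrationResult (threshold and F-measures)
    threshold_ : float, the selected decision threshold

    Examples
    --------
    >>> from codac.synthetic import SyntheticSpec, generate
    >>> data = generate(SyntheticSpec(seed=7))
    >>> miner = AssociationMiner(random_state=7)
    >>> records = miner.fit(data.datasets, data.e3_given,
    ...                     cluster_maps=data.cluster_map).predict()
    """

    def __init__(
        self,
        *,
        propagate: bool = False,
        most_specific: bool = False,
        weight_strategy: str = "coordinate_ascent",
        random_state: int = 0,
        max_shuffle_tries: int = 50,
    ):
        self.propagate = propagate
        self.most_specific = most_specific
        self.weight_strategy = weight_strategy
        self.random_state = random_state
        self.max_shuffle_tries = max_shuffle_tries

    # ------------------------------------------------------------------ fit

    def fit(
        self,
        datasets: Mapping[str, tuple[Bigraph, Bigraph]],
        known: Iterable[Pair],
        *,
        ontology: Ontology | None = None,
        cluster_maps: ClusterMap | Mapping[str, ClusterMap] | None = None,
    ) -> "AssociationMiner":
        """Calibrate weights and threshold from evidence datasets.

        Parameters
        ----------
        datasets
            Mapping of dataset id to its (X–Z, Y–Z) bigraph pair.
        known
            The known X–Y associations (calibration positives, E3).
        ontology
            Required when ``propagate`` or ``most_specific`` is set.
        cluster_maps
            A single shared :class:`ClusterMap`, a per-dataset mapping, or
            None for singleton (identity) clusters.
        """
        if not datasets:
            raise ValidationError("at least one dataset is required")
        known_pairs = frozenset(tuple(p) for p in known)
        if (self.propagate or self.most_specific) and ontology is None:
            raise ValidationError("propagate/most_specific require an ontology")

        self.known_ = known_pairs
        self.ontology_ = ontology
        self.dataset_ids_ = list(datasets)
        self.dataset_graphs_ = {}
        sims: list[DatasetSimilarity] = []
        for ds_id, (g1, g2) in datasets.items():
            cm = self._cluster_map_for(ds_id, (g1, g2), cluster_maps)
            g1c, g2c = cluster_common_items(g1, g2, cm)
            if self.propagate:
                g1c = propagate_ontology(g1c, ontology)
            # both layers share the dataset's full Z universe (its size is
            # the hypergeometric N_z downstream)
            z_order = tuple(sorted(set(g1c.right_items) | set(g2c.right_items)))
            g1c = Bigraph(g1c.left_items, z_order, g1c.edges)
            g2c = Bigraph(g2c.left_items, z_order, g2c.edges)
            self.dataset_graphs_[ds_id] = (g1c, g2c)
            m1 = build_biadjacency(g1c, z_order)
            m2 = build_biadjacency(g2c, z_order)
            sims.append(cosine_similarity(m1, m2, dataset_id=ds_id))
        self.dataset_similarities_ = sims

        search = cal.optimize_weights(
            sims,
            known_pairs,
            strategy=self.weight_strategy,
            seed=_stage_seed(self.random_state, _SEED_WEIGHTS),
        )
        self.weights_ = search.weights
        self.auc_ = search.auc
        self.consensus_ = consensus(sims, self.weights_)

        shuffled_sims = []
        for sub, ds_id in enumerate(self.dataset_ids_):
            g1c, g2c = self.dataset_graphs_[ds_id]
            g1s = cal.shuffle_bigraph(
                g1c, _stage_seed(self.random_state, _SEED_SHUFFLE, 2 * sub),
                max_tries=self.max_shuffle_tries,
            )
            g2s = cal.shuffle_bigraph(
                g2c, _stage_seed(self.random_state, _SEED_SHUFFLE, 2 * sub + 1),
                max_tries=self.max_shuffle_tries,
            )
            z_order = tuple(sorted(set(g1s.right_items) | set(g2s.right_items)))
            shuffled_sims.append(
                cosine_similarity(
                    build_biadjacency(g1s, z_order),
                    build_biadjacency(g2s, z_order),
                    dataset_id=ds_id,
                )
            )
        self.shuffled_consensus_ = consensus(shuffled_sims, self.weights_)

        gs = cal.build_gold_standard(
            known_pairs,
            self.shuffled_consensus_,
            _stage_seed(self.random_state, _SEED_NEGATIVES),
        )
        gs = cal.split_gold_standard(gs, _stage_seed(self.random_state, _SEED_SPLIT))
        self.gold_standard_ = gs

        # Positives are scored from the real consensus, negatives from the
        # shuffled consensus they were sampled from (their chance-level score).
        real = self.consensus_.to_dict()
        shuf = self.shuffled_consensus_.to_dict()
        self.gold_scores_ = {p: real.get(p, 0.0) for p in gs.positives}
        self.gold_scores_.update({p: shuf.get(p, 0.0) for p in gs.negatives})
        self.calibration_ = cal.select_threshold(self.gold_scores_, gs)
        self.threshold_ = self.calibration_.threshold
        return self

    @staticmethod
    def _cluster_map_for(ds_id, graphs, cluster_maps) -> ClusterMap:
        if cluster_maps is None:
            return identity_cluster_map(graphs)
        if isinstance(cluster_maps, ClusterMap):
            return cluster_maps
        try:
            return cluster_maps[ds_id]
        except KeyError:
            raise ValidationError(f"no cluster map for dataset {ds_id!r}") from None

    # -------------------------------------------------------------- predict

    def predict(self) -> list[AssociationRecord]:
        """Produce the enriched association records from the fitted state."""
        self._check_fitted()
        filtered = cal.filter_similarity(self.consensus_, self.threshold_, self.known_)
        records = annotate_predictions(filtered, self.dataset_graphs_, self.known_)
        self.n_kept_ = len(records)
        self.alpha_ = bonferroni_alpha(self.n_kept_) if self.n_kept_ else float("nan")
        if self.most_specific and records:
            keep = most_specific_filter({(r.x, r.y) for r in records}, self.ontology_)
            records = [r for r in records if (r.x, r.y) in keep]
        self.records_ = records
        self.class_counts_ = {
            q: sum(1 for r in records if r.quality == q) for q in ("Gold", "Silver", "Bronze")
        }
        return records

    def fit_predict(self, datasets, known, **fit_kwargs) -> list[AssociationRecord]:
        return self.fit(datasets, known, **fit_kwargs).predict()

    def _check_fitted(self) -> None:
        if not hasattr(self, "consensus_"):
            raise ValidationError("this AssociationMiner instance is not fitted yet")


def mine_associations(
    datasets: Mapping[str, tuple[Bigraph, Bigraph]],
    known: Iterable[Pair],
    **params,
) -> list[AssociationRecord]:
    """Functional one-shot wrapper around :class:`AssociationMiner`."""
    fit_kwargs = {k: params.pop(k) for k in ("ontology", "cluster_maps") if k in params}
    return AssociationMiner(**params).fit_predict(datasets, known, **fit_kwargs)


def recovery_scores(
    records: Iterable[AssociationRecord], heldout: Iterable[Pair]
) -> dict[str, float]:
    """Precision/recall/F1 of the novel predictions against held-out truth."""
    heldout = set(tuple(p) for p in heldout)
    novel = {(r.x, r.y) for r in records if not r.known}
    tp = len(novel & heldout)
    precision = tp / len(novel) if novel else 0.0
    recall = tp / len(heldout) if heldout else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_novel": float(len(novel)), "n_heldout": float(len(heldout))}
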