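"""Hypergeometric significance and Gold/Silver/Bronze quality classes.

A pair (x, y) with many common neighbours may still be unremarkable if both
items are promiscuously annotated.  Under the null that y's N_y neighbours
are drawn uniformly from the N_z items of Z, the number K of them that also
neighbour x is hypergeometric, and the edge's p-value is the upper tail
P(K ≥ K_xy).  With |E3*| kept edges tested, Bonferroni sets the family-wise
significance level at alpha = 0.05 / |E3*| (strict inequality p < alpha).

Quality classes summarise agreement across evidence datasets: Gold if every
dataset with data for the pair is significant, Silver if more than half
are, Bronze otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom

from .errors import ValidationError
from .graph import Bigraph, common_neighbour_counts
from .similarity import ConsensusSimilarity

__all__ = [
    "AssociationRecord",
    "hypergeometric_pvalue",
    "bonferroni_alpha",
    "classify_association",
    "annotate_predictions",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class DatasetEvidence:
    """Per-dataset counts feeding the hypergeometric test for one pair."""

    k_xy: int
    n_x: int
    n_y: int
    n_z: int
    p_value: float | None  # None when the dataset has no data for the pair


@dataclass(frozen=True)
class AssociationRecord:
    """A kept (x, y) edge with its score, evidence and quality class."""

    x: str
    y: str
    consensus_score: float
    known: bool
    per_dataset: Mapping[str, DatasetEvidence]
    quality: str  # "Gold" | "Silver" | "Bronze"


def hypergeometric_pvalue(n_z: int, n_x: int, n_y: int, k_xy: int) -> float:
    """Upper-tail probability P(K ≥ k_xy) of the common-neighbour count.

    K follows Hypergeometric(N=n_z, K=n_x, n=n_y): y's neighbours are an
    n_y-subset of Z drawn uniformly, of which K fall among x's n_x
    neighbours.  Evaluated through the survival function, which stays
    numerically safe for Z universes up to ~1e7 items.
    """
    if n_z < 1:
        raise ValidationError(f"n_z must be >= 1, got {n_z}")
    if not 0 <= n_x <= n_z:
        raise ValidationError(f"n_x={n_x} out of range [0, n_z={n_z}]")
    if not 0 <= n_y <= n_z:
        raise ValidationError(f"n_y={n_y} out of range [0, n_z={n_z}]")
    if not 0 <= k_xy <= min(n_x, n_y):
        raise ValidationError(f"k_xy={k_xy} out of range [0, min(n_x, n_y)={min(n_x, n_y)}]")
    if k_xy == 0:
        return 1.0
    return float(hypergeom.sf(k_xy - 1, n_z, n_x, n_y))


def bonferroni_alpha(n_edges: int) -> float:
    """Family-wise significance level 0.05 / (number of edges tested)."""
    if n_edges < 1:
        raise ValidationError("Bonferroni correction needs at least one tested edge")
    return 0.05 / n_edges


def classify_association(p_values: Mapping[str, float | None], alpha: float) -> str:
    """Gold / Silver / Bronze from per-dataset p-values.

    Datasets with no data (``None``) are excluded from both numerator and
    denominator.  Gold: all present p-values significant (p < alpha).
    Silver: more than half significant.  Bronze: the rest (exactly half is
    Bronze).  Invariant under dataset order.
    """
    present = [p for p in p_values.values() if p is not None]
    if not present:
        raise ValidationError("no dataset has data for this pair")
    n_sig = sum(1 for p in present if p < alpha)
    if n_sig == len(present):
        return "Gold"
    if n_sig * 2 > len(present):
        return "Silver"
    return "Bronze"


def annotate_predictions(
    cs_filtered: ConsensusSimilarity,
    datasets: Mapping[str, tuple[Bigraph, Bigraph]],
    e3: Iterable[Pair],
) -> list[AssociationRecord]:
    """Assemble one record per kept edge: counts, p-values, class, flags.

    ``datasets`` maps dataset id to the (X–Z, Y–Z) bigraph pair actually
    used for scoring (clustered, optionally propagated), from which the
    common-neighbour count K_xy, the degrees N_x and N_y, and the Z-universe
    size N_z are taken per dataset.  A dataset has data for a pair only if
    both x and y have at least one neighbour there; otherwise its p-value
    is absent.  alpha is computed once from the total number of kept edges.
    Records are sorted by descending consensus score, ties broken by
    (x, y) lexicographic order.
    """
    e3 = set(tuple(p) for p in e3)
    kept = [(x, y, v) for x, y, v in cs_filtered.items()]
    if not kept:
        return []
    alpha = bonferroni_alpha(len(kept))

    per_ds_counts: dict[str, dict[Pair, int]] = {}
    per_ds_degx: dict[str, dict[str, int]] = {}
    per_ds_degy: dict[str, dict[str, int]] = {}
    per_ds_nz: dict[str, int] = {}
    for ds_id, (g1, g2) in datasets.items():
        if set(g1.right_items) != set(g2.right_items):
            raise ValidationError(f"dataset {ds_id!r}: X–Z and Y–Z layers disagree on Z")
        per_ds_counts[ds_id] = common_neighbour_counts(g1, g2)
        per_ds_degx[ds_id] = g1.left_degrees()
        per_ds_degy[ds_id] = g2.left_degrees()
        per_ds_nz[ds_id] = len(g1.right_items)

    records = []
    for x, y, score in kept:
        evidence: dict[str, DatasetEvidence] = {}
        for ds_id in datasets:
            n_x = per_ds_degx[ds_id].get(x, 0)
            n_y = per_ds_degy[ds_id].get(y, 0)
            k = per_ds_counts[ds_id].get((x, y), 0)
            n_z = per_ds_nz[ds_id]
            if n_x == 0 or n_y == 0:
                evidence[ds_id] = DatasetEvidence(k, n_x, n_y, n_z, p_value=None)
            else:
                evidence[ds_id] = DatasetEvidence(
                    k, n_x, n_y, n_z, p_value=hypergeometric_pvalue(n_z, n_x, n_y, k)
                )
        quality = classify_association({d: e.p_value for d, e in evidence.items()}, alpha)
        records.append(
            AssociationRecord(
                x=x,
                y=y,
                consensus_score=score,
                known=(x, y) in e3,
                per_dataset=evidence,
                quality=quality,
            )
        )
    records.sort(key=lambda r: (-r.consensus_score, r.x, r.y))
    return records
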