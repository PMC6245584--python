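"""Rooted-DAG ontology support for the X vocabulary.

Gene Ontology terms live in a rooted directed acyclic graph (rDAG) linked
by is_a relations.  Two consequences matter for association mining: an
annotation to a term implicitly annotates all its ancestors (so the X–Z
layer may be ancestor-propagated before scoring), and predicted
associations should be counted only at their most-specific term (if a
domain is linked to a term and to one of its parents, only the child
carries information).

Only is_a parents are honoured; part_of and other OBO relations are
ignored by default (``relations`` argument of :func:`load_obo`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import ValidationError
from .graph import Bigraph

__all__ = ["Ontology", "load_obo", "propagate_ontology", "most_specific_filter"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, eq=False)
class Ontology:
    """Terms with names/namespaces and an acyclic is_a parent relation."""

    terms: Mapping[str, tuple[str, str]]  # id -> (name, namespace)
    parents: Mapping[str, frozenset[str]]  # id -> direct is_a parents

    def __post_init__(self) -> None:
        known = set(self.terms)
        for term, ps in self.parents.items():
            if term not in known:
                raise ValidationError(f"parent map references unknown term {term!r}")
            missing = set(ps) - known
            if missing:
                raise ValidationError(
                    f"term {term!r} has unknown parent(s) {sorted(missing)}"
                )
        dag = nx.DiGraph()
        dag.add_nodes_from(known)
        for term, ps in self.parents.items():
            dag.add_edges_from((term, p) for p in ps)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise ValidationError(f"is_a relation contains a cycle: {cycle}")
        object.__setattr__(self, "_dag", dag)

    @classmethod
    def from_parent_map(
        cls,
        parents: Mapping[str, Iterable[str]],
        names: Mapping[str, str] | None = None,
        namespace: str = "default",
    ) -> "Ontology":
        terms = {t: ((names or {}).get(t, t), namespace) for t in parents}
        return cls(terms=terms, parents={t: frozenset(p) for t, p in parents.items()})

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def ancestors(self, term: str) -> frozenset[str]:
        """Transitive is_a closure of ``term``, excluding the term itself."""
        if term not in self.terms:
            raise ValidationError(f"unknown ontology term {term!r}")
        return self._ancestors_cached(term)

    @lru_cache(maxsize=None)
    def _ancestors_cached(self, term: str) -> frozenset[str]:
        return frozenset(nx.descendants(self._dag, term))  # edges point child -> parent

    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))


def load_obo(path, namespace: str | None = None, relations: tuple[str, ...] = ("is_a",)) -> Ontology:
    """Read an OBO 1.2 flat file into an :class:`Ontology`.

    Obsolete terms are dropped (with a logged count).  When ``namespace`` is
    given, terms outside it are dropped too — each mining run works within a
    single namespace (MF, BP or CC for GO) — and is_a links referring to
    dropped terms vanish with them.
    """
    graph = obonet.read_obo(path)  # skips obsolete stanzas itself
    n_obsolete = graph.graph.get("n_obsolete", None)
    if n_obsolete:
        logger.info("dropped %s obsolete terms while reading %s", n_obsolete, path)
    terms: dict[str, tuple[str, str]] = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace", "default")
        if namespace is not None and ns != namespace:
            continue
        terms[node] = (data.get("name", node), ns)
    parents: dict[str, frozenset[str]] = {}
    for node in terms:
        ps = set()
        for _, parent, rel in graph.out_edges(node, keys=True):
            if rel in relations and parent in terms:
                ps.add(parent)
        parents[node] = frozenset(ps)
    logger.info("loaded %d terms (%d is_a links) from %s", len(terms),
                sum(len(p) for p in parents.values()), path)
    return Ontology(terms=terms, parents=parents)


def propagate_ontology(g: Bigraph, o: Ontology, on_missing: str = "skip") -> Bigraph:
    """Ancestor-propagate an X–Z annotation layer.

    For every edge (x, z), add (a, z) for every ancestor *a* of *x* that is
    already in the graph's left vocabulary — the vocabulary itself never
    grows.  Idempotent and monotone.  Left items missing from the ontology
    are skipped with a warning (``on_missing="skip"``) or rejected
    (``on_missing="error"``).
    """
    if on_missing not in ("skip", "error"):
        raise ValidationError(f"on_missing must be 'skip' or 'error', got {on_missing!r}")
    present = set(g.left_items)
    new_edges = set(g.edges)
    missing: set[str] = set()
    for x, z in g.edges:
        if x not in o:
            if on_missing == "error":
                raise ValidationError(f"left item {x!r} is not an ontology term")
            missing.add(x)
            continue
        for a in o.ancestors(x):
            if a in present:
                new_edges.add((a, z))
    if missing:
        logger.warning("%d left items missing from the ontology were not propagated", len(missing))
    return Bigraph(g.left_items, g.right_items, frozenset(new_edges))


def most_specific_filter(
    assocs: Iterable[tuple[str, str]], o: Ontology, on_missing: str = "skip"
) -> set[tuple[str, str]]:
    """Keep, per Y item, only associations to most-specific (non-parent) terms.

    (x, y) is dropped exactly when some other association (x', y) exists
    with x an ancestor of x' — the result is the per-y antichain of the
    ontology.  Terms unknown to the ontology are kept as-is (they cannot be
    anyone's ancestor) under ``on_missing="skip"``, or rejected.
    """
    if on_missing not in ("skip", "error"):
        raise ValidationError(f"on_missing must be 'skip' or 'error', got {on_missing!r}")
    assocs = set(tuple(a) for a in assocs)
    by_y: dict[str, set[str]] = {}
    for x, y in assocs:
        if x not in o and on_missing == "error":
            raise ValidationError(f"term {x!r} is not an ontology term")
        by_y.setdefault(y, set()).add(x)
    kept: set[tuple[str, str]] = set()
    for y, xs in by_y.items():
        covered: set[str] = set()
        for x in xs:
            if x in o:
                covered |= o.ancestors(x)
        kept.update((x, y) for x in xs if x not in covered)
    return kept
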