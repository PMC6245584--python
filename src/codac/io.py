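"""Plain-text readers and writers.

All tabular interchange is two- or three-column TSV (UTF-8, ``#`` comment
lines ignored, fields stripped of surrounding whitespace); ontologies are
OBO 1.2 flat files.  Identifier normalisation happens here and only here —
the core modules compare identifiers verbatim.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .calibration import CalibrationResult, GoldStandard
from .errors import ValidationError
from .graph import Bigraph, ClusterMap
from .ontology import Ontology
from .significance import AssociationRecord

Pair = tuple[str, str]


def _rows(path: str | Path, n_cols: int) -> Iterable[tuple[str, ...]]:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = tuple(f.strip() for f in line.split("\t"))
            if len(fields) < n_cols or any(not f for f in fields[:n_cols]):
                raise ValidationError(f"{path}:{ln}: expected {n_cols} tab-separated fields")
            yield fields[:n_cols]


def read_edge_tsv(path: str | Path) -> frozenset[Pair]:
    """Read a two-column (left_id, right_id) edge list."""
    return frozenset((a, b) for a, b in _rows(path, 2))


def read_bigraph_tsv(path: str | Path) -> Bigraph:
    """Read an edge list into a bigraph with sorted vocabularies."""
    return Bigraph.from_edges(read_edge_tsv(path))


def write_edge_tsv(edges: Iterable[Pair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")


def read_cluster_tsv(path: str | Path) -> ClusterMap:
    """Read a two-column (z_id, cid) cluster map."""
    mapping: dict[str, str] = {}
    for z, cid in _rows(path, 2):
        if z in mapping and mapping[z] != cid:
            raise ValidationError(f"{path}: Z item {z!r} assigned to two clusters")
        mapping[z] = cid
    return ClusterMap(mapping)


def write_cluster_tsv(cm: ClusterMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for z, cid in sorted(cm.mapping.items()):
            fh.write(f"{z}\t{cid}\n")


def write_obo(o: Ontology, path: str | Path) -> None:
    """Write a minimal OBO 1.2 file (id, name, namespace, is_a)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(o.terms):
            name, ns = o.terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {name}\nnamespace: {ns}\n")
            for parent in sorted(o.parents.get(term, ())):
                pname, _ = o.terms[parent]
                fh.write(f"is_a: {parent} ! {pname}\n")


def write_similarity_tsv(sim, path: str | Path) -> None:
    """Export a similarity matrix as (x_id, y_id, score), 6 decimal places."""
    with open(path, "w", encoding="utf-8") as fh:
        for x, y, v in sorted(sim.items()):
            fh.write(f"{x}\t{y}\t{v:.6f}\n")


def write_gold_standard_tsv(gs: GoldStandard, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# x\ty\tlabel\tsplit\n")
        for label, pairs in (("P", sorted(gs.positives)), ("N", sorted(gs.negatives))):
            for x, y in pairs:
                fh.write(f"{x}\t{y}\t{label}\t{gs.split.get((x, y), '')}\n")


def write_associations_tsv(
    records: Iterable[AssociationRecord],
    path: str | Path,
    dataset_ids: Iterable[str],
    term_names: Mapping[str, str] | None = None,
) -> None:
    """Write the prediction table: ids, score, class, flags, per-dataset p-values."""
    dataset_ids = list(dataset_ids)
    term_names = term_names or {}
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["x_id", "x_name", "y_id", "consensus_score", "quality", "known"]
        cols += [f"p_{d}" for d in dataset_ids]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.x,
                term_names.get(r.x, ""),
                r.y,
                f"{r.consensus_score:.6f}",
                r.quality,
                "known" if r.known else "novel",
            ]
            for d in dataset_ids:
                ev = r.per_dataset.get(d)
                row.append("" if ev is None or ev.p_value is None else f"{ev.p_value:.6e}")
            fh.write("\t".join(row) + "\n")


def write_manifest(
    path: str | Path,
    *,
    seed: int,
    weights: Mapping[str, float],
    auc: float,
    calibration: CalibrationResult,
    alpha: float,
    n_kept: int,
    class_counts: Mapping[str, int],
    extra: Mapping | None = None,
) -> None:
    """Serialise the run manifest (seeds, weights, threshold, metrics) as YAML."""
    manifest = {
        "seed": seed,
        "weights": {k: float(v) for k, v in sorted(weights.items())},
        "auc": float(auc),
        "threshold": float(calibration.threshold),
        "f_train": float(calibration.f_train),
        "f_test": float(calibration.f_test),
        "precision_train": float(calibration.precision),
        "recall_train": float(calibration.recall),
        "alpha": float(alpha),
        "n_kept_edges": int(n_kept),
        "class_counts": {k: int(v) for k, v in sorted(class_counts.items())},
    }
    if extra:
        manifest.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
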