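"""Synthetic tripartite fixtures with planted associations.

The generator emulates the statistical structure the miner is designed to
detect: a planted (x, y) association manifests as a correlated
neighbourhood in Z — a dedicated block of Z items each linked to x and to y
independently with probability ``signal`` (scaled per dataset by a quality
multiplier) — on top of a uniform background of spurious edges appearing
with probability ``noise``.  Around this core it also fabricates the two
auxiliary structures real runs consume: an artificial is_a ontology over
the X terms in which planted terms are leaves, and a cluster map created by
splitting each Z item into redundant copies that partition its edges
(clustering the copies back together restores the signal, which is exactly
the bias the clustering stage exists to remove).

Half of the planted pairs are declared "known" (the calibration positives);
the other half is held out as ground truth for recovery evaluation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .graph import Bigraph, ClusterMap
from .ontology import Ontology

__all__ = ["SyntheticSpec", "SyntheticData", "generate", "write_fixture"]

Pair = tuple[str, str]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters (defaults are the package's study conditions)."""

    n_x: int = 50
    n_y: int = 50
    n_z: int = 500
    n_planted: int = 60
    signal: float = 0.8
    noise: float = 0.01
    n_datasets: int = 3
    dataset_quality: tuple[float, ...] | None = None
    ontology_depth: int = 3
    ontology_branching: int = 3
    cluster_redundancy: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("signal", "noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability in [0, 1], got {v!r}")
        if min(self.n_x, self.n_y, self.n_z, self.n_datasets) < 1:
            raise ValidationError("n_x, n_y, n_z and n_datasets must be positive")
        if self.n_planted > self.n_x * self.n_y:
            raise ValidationError("more planted pairs than possible (x, y) combinations")
        if self.n_planted > self.n_z:
            raise ValidationError("need at least one Z item per planted pair")
        if self.cluster_redundancy < 0:
            raise ValidationError("cluster_redundancy must be non-negative")
        if self.dataset_quality is not None and len(self.dataset_quality) != self.n_datasets:
            raise ValidationError("dataset_quality must have one multiplier per dataset")
        if self.signal <= self.noise:
            warnings.warn(
                "signal <= noise: planted associations will not be recoverable",
                stacklevel=2,
            )

    @property
    def qualities(self) -> tuple[float, ...]:
        return self.dataset_quality or (1.0,) * self.n_datasets


@dataclass(frozen=True)
class SyntheticData:
    """One generated fixture: datasets, truth, ontology and cluster map."""

    spec: SyntheticSpec
    datasets: dict[str, tuple[Bigraph, Bigraph]]  # id -> (X–Z, Y–Z)
    e3_true: frozenset[Pair]
    e3_given: frozenset[Pair]
    e3_heldout: frozenset[Pair]
    ontology: Ontology
    cluster_map: ClusterMap


def _make_ontology(
    x_ids: list[str], planted_x: set[str], depth: int, branching: int, rng: np.random.Generator
) -> Ontology:
    """Layered random rDAG over the X terms with planted terms as leaves."""
    internal = [x for x in x_ids if x not in planted_x]
    leaves = [x for x in x_ids if x in planted_x]
    parents: dict[str, set[str]] = {x: set() for x in x_ids}
    layers: list[list[str]] = []
    i, size = 0, 1
    for _ in range(max(depth, 1)):
        if i >= len(internal):
            break
        layers.append(internal[i : i + size])
        i += size
        size *= max(branching, 1)
    if i < len(internal):  # leftovers join the deepest layer
        layers[-1].extend(internal[i:])
    for li in range(1, len(layers)):
        for term in layers[li]:
            above = layers[li - 1]
            parents[term].add(above[int(rng.integers(len(above)))])
            if len(above) > 1 and rng.random() < 0.3:  # occasional 2nd parent: a DAG, not a tree
                parents[term].add(above[int(rng.integers(len(above)))])
    attach = layers[-1] if layers else []
    for leaf in leaves:
        if attach:
            parents[leaf].add(attach[int(rng.integers(len(attach)))])
            if len(attach) > 1 and rng.random() < 0.3:
                parents[leaf].add(attach[int(rng.integers(len(attach)))])
    return Ontology.from_parent_map({t: ps for t, ps in parents.items()}, namespace="synthetic")


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one fixture; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    x_ids = [f"X{i:03d}" for i in range(spec.n_x)]
    y_ids = [f"Y{j:03d}" for j in range(spec.n_y)]
    z_ids = [f"Z{k:04d}" for k in range(spec.n_z)]

    flat = rng.choice(spec.n_x * spec.n_y, size=spec.n_planted, replace=False)
    planted = sorted((x_ids[f // spec.n_y], y_ids[f % spec.n_y]) for f in flat)
    blocks = np.array_split(np.arange(spec.n_z), spec.n_planted)

    # Redundant copies of each Z item; the copy named like the base item keeps
    # singletons mapped to themselves in the cluster map.
    n_copies = 1 + rng.poisson(spec.cluster_redundancy, size=spec.n_z)
    copies: list[list[str]] = [
        [z] + [f"{z}r{c}" for c in range(1, int(n))] for z, n in zip(z_ids, n_copies)
    ]
    cluster_map = ClusterMap({cp: z for z, cps in zip(z_ids, copies) for cp in cps})
    all_copies = tuple(cp for cps in copies for cp in cps)

    datasets: dict[str, tuple[Bigraph, Bigraph]] = {}
    for d, q in enumerate(spec.qualities):
        p_signal = min(spec.signal * q, 1.0)
        xz = rng.random((spec.n_x, spec.n_z)) < spec.noise
        yz = rng.random((spec.n_y, spec.n_z)) < spec.noise
        for (px, py), block in zip(planted, blocks):
            xi, yj = x_ids.index(px), y_ids.index(py)
            xz[xi, block] |= rng.random(len(block)) < p_signal
            yz[yj, block] |= rng.random(len(block)) < p_signal

        def scatter(mask: np.ndarray, left_ids: list[str]) -> frozenset[Pair]:
            edges = []
            for li, zi in np.argwhere(mask):
                cps = copies[zi]
                cp = cps[int(rng.integers(len(cps)))] if len(cps) > 1 else cps[0]
                edges.append((left_ids[li], cp))
            return frozenset(edges)

        g1 = Bigraph(tuple(x_ids), all_copies, scatter(xz, x_ids))
        g2 = Bigraph(tuple(y_ids), all_copies, scatter(yz, y_ids))
        datasets[f"D{d + 1}"] = (g1, g2)

    ontology = _make_ontology(
        x_ids, {x for x, _ in planted}, spec.ontology_depth, spec.ontology_branching, rng
    )
    order = rng.permutation(len(planted))
    n_given = math.ceil(len(planted) / 2)
    e3_given = frozenset(planted[i] for i in order[:n_given])
    e3_true = frozenset(planted)
    return SyntheticData(
        spec=spec,
        datasets=datasets,
        e3_true=e3_true,
        e3_given=e3_given,
        e3_heldout=e3_true - e3_given,
        ontology=ontology,
        cluster_map=cluster_map,
    )


def write_fixture(data: SyntheticData, outdir: str | Path) -> Path:
    """Write the fixture as the TSV/OBO files the pipeline consumes.

    Layout: ``<id>_xz.tsv`` and ``<id>_yz.tsv`` per dataset, ``known.tsv``
    (declared associations), ``truth.tsv`` (all planted pairs with a
    given/heldout column), ``clusters.tsv`` and ``ontology.obo``.  Sorted
    line order makes equal seeds produce byte-identical files.
    """
    from . import io  # local import: io depends on graph, not on synthetic

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ds_id, (g1, g2) in sorted(data.datasets.items()):
        io.write_edge_tsv(g1.edges, outdir / f"{ds_id}_xz.tsv")
        io.write_edge_tsv(g2.edges, outdir / f"{ds_id}_yz.tsv")
    io.write_edge_tsv(data.e3_given, outdir / "known.tsv")
    with open(outdir / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("# x\ty\tstatus\n")
        for x, y in sorted(data.e3_true):
            status = "given" if (x, y) in data.e3_given else "heldout"
            fh.write(f"{x}\t{y}\t{status}\n")
    io.write_cluster_tsv(data.cluster_map, outdir / "clusters.tsv")
    io.write_obo(data.ontology, outdir / "ontology.obo")
    return outdir
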