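"""Network construction: populations with contiguous id ranges and random
fixed in-degree connectivity, plus lesion and restoration edits.

Each projection is realized by sampling, for every target neuron, exactly K
distinct source neurons uniformly without replacement (no autapses, no
multapses). Per-projection RNG substreams are derived from the master seed
so that removing one projection never reshuffles the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .params import (
    POPULATION_SIZES,
    POPULATIONS,
    ConditionBundle,
    ConfigurationError,
    ProjectionSpec,
)

#: composite lesion names that remove both directions of a loop
LOOP_LESIONS = {
    "STN<->GPe-TI": ("GPe-TI->STN", "STN->GPe-TI"),
    "GPe-TA<->GPe-TI": ("GPe-TA->GPe-TI", "GPe-TI->GPe-TA"),
}


@dataclass
class Population:
    """One neuron population occupying a contiguous global id range."""

    name: str
    size: int
    kind: str            # "LIF" | "AdEx"
    first_id: int

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.first_id, self.first_id + self.size)

    @property
    def slice(self) -> slice:
        return slice(self.first_id, self.first_id + self.size)


@dataclass
class ProjectionEdges:
    """Realized adjacency of one projection.

    ``sources`` has shape (n_targets, K): row t lists the K distinct global
    source ids of target neuron ``targets[t]``.
    """

    spec: ProjectionSpec
    targets: np.ndarray   # (n_targets,) global ids
    sources: np.ndarray   # (n_targets, K) global ids

    @property
    def n_edges(self) -> int:
        return self.sources.size


@dataclass
class Network:
    """Populations plus realized connectivity for one condition bundle."""

    bundle: ConditionBundle
    populations: dict            # name -> Population
    projections: dict            # projection name -> ProjectionEdges
    seed: int
    lesions: tuple = ()
    restored: tuple = ()
    recalibrate_baseline: bool = field(default=False)

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations.values())

    def population_of(self, gid: int) -> str:
        for name, pop in self.populations.items():
            if pop.first_id <= gid < pop.first_id + pop.size:
                return name
        raise ConfigurationError(f"global id {gid} out of range")

    def in_degree(self, proj_name: str) -> np.ndarray:
        edges = self.projections[proj_name]
        return np.full(len(edges.targets), edges.sources.shape[1])

    def provenance_hash(self) -> str:
        h = hashlib.sha256()
        h.update(repr(sorted(self.bundle.to_dict().items())).encode())
        h.update(str(self.seed).encode())
        h.update(repr(self.lesions).encode())
        h.update(repr(self.restored).encode())
        for name in sorted(self.projections):
            h.update(name.encode())
            h.update(self.projections[name].sources.tobytes())
        return h.hexdigest()[:16]

    def export_edge_lists(self, directory) -> None:
        """One delimited edge-list file per projection + populations manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = ["name\tsize\tkind\tfirst_id"]
        for name, pop in self.populations.items():
            manifest.append(f"{name}\t{pop.size}\t{pop.kind}\t{pop.first_id}")
        (directory / "populations.tsv").write_text("\n".join(manifest) + "\n")
        for name, edges in self.projections.items():
            fname = name.replace("->", "__to__") + ".tsv"
            rows = ["source\ttarget"]
            for t, srcs in zip(edges.targets, edges.sources):
                rows.extend(f"{s}\t{t}" for s in srcs)
            (directory / fname).write_text("\n".join(rows) + "\n")


def _projection_seed(master_seed: int, proj_name: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{proj_name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def build_populations() -> dict:
    pops = {}
    first = 0
    for name in POPULATIONS:
        size = POPULATION_SIZES[name]
        kind = "AdEx" if name in ("GPe-TA", "GPe-TI", "SNr") else "LIF"
        pops[name] = Population(name=name, size=size, kind=kind, first_id=first)
        first += size
    return pops


def _sample_projection(spec: ProjectionSpec, pops: dict,
                       master_seed: int) -> ProjectionEdges:
    src_pop, tgt_pop = pops[spec.source], pops[spec.target]
    if spec.K > src_pop.size:
        raise ConfigurationError(
            f"in-degree {spec.K} exceeds source size for {spec.name}"
        )
    rng = np.random.default_rng(_projection_seed(master_seed, spec.name))
    recurrent = spec.source == spec.target
    sources = np.empty((tgt_pop.size, spec.K), dtype=np.int32)
    # Uniform sampling without replacement per target; for a recurrent
    # projection the target itself is excluded (no autapses).
    pool_size = src_pop.size
    for row, tgt_local in enumerate(range(tgt_pop.size)):
        if recurrent:
            choice = rng.choice(pool_size - 1, size=spec.K, replace=False)
            choice[choice >= tgt_local] += 1
        else:
            choice = rng.choice(pool_size, size=spec.K, replace=False)
        sources[row] = choice + src_pop.first_id
    return ProjectionEdges(spec=spec, targets=tgt_pop.ids.astype(np.int32),
                           sources=sources)


def build_network(bundle: ConditionBundle, seed: int) -> Network:
    """Instantiate the 6539-neuron network for a condition bundle.

    Deterministic given ``seed``: identical seeds give edge-for-edge
    identical networks.
    """
    pops = build_populations()
    projections = {
        name: _sample_projection(spec, pops, seed)
        for name, spec in bundle.projections.items()
    }
    return Network(bundle=bundle, populations=pops, projections=projections,
                   seed=seed)


def _resolve_projection_names(network: Network, name: str) -> tuple:
    if name in LOOP_LESIONS:
        return LOOP_LESIONS[name]
    if name in network.projections:
        return (name,)
    raise ConfigurationError(f"unknown projection {name!r}")


def apply_lesion(network: Network, projection_name: str) -> Network:
    """Remove all edges of the named projection (loop names remove both
    directions); everything else is untouched."""
    names = _resolve_projection_names(network, projection_name)
    projections = {k: v for k, v in network.projections.items()
                   if k not in names}
    return replace(network, projections=projections,
                   lesions=network.lesions + tuple(names))


def restore_projection(network: Network, projection_name: str,
                       normal_bundle: ConditionBundle) -> Network:
    """Set the named projection's weight and delay back to the healthy
    values; flags that baseline rates should be recalibrated downstream."""
    names = _resolve_projection_names(network, projection_name)
    projections = dict(network.projections)
    bundle_projections = dict(network.bundle.projections)
    for name in names:
        if name not in normal_bundle.projections:
            raise ConfigurationError(f"unknown projection {name!r}")
        normal_spec = normal_bundle.projections[name]
        edges = projections[name]
        new_spec = replace(edges.spec, weight=normal_spec.weight,
                           delay=normal_spec.delay)
        projections[name] = replace(edges, spec=new_spec)
        bundle_projections[name] = new_spec
    new_bundle = replace(network.bundle, projections=bundle_projections)
    return replace(network, bundle=new_bundle, projections=projections,
                   restored=network.restored + tuple(names),
                   recalibrate_baseline=True)
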