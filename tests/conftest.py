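"""Shared fixtures: condition bundles, built networks, and micro-networks
(one or two neurons) for single-cell physics checks."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from bgnet.network import Network, Population, ProjectionEdges, build_network
from bgnet.params import (
    NEURON_PARAMS,
    ConditionBundle,
    DopamineState,
    ProjectionSpec,
    build_condition,
)


@pytest.fixture(scope="session")
def normal_bundle():
    return build_condition("normal")


@pytest.fixture(scope="session")
def pd_biphasic_bundle():
    return build_condition("PD-biphasic")


@pytest.fixture(scope="session")
def pd_triphasic_bundle():
    return build_condition("PD-triphasic")


@pytest.fixture(scope="session")
def normal_network(normal_bundle):
    return build_network(normal_bundle, seed=11)


def make_micro_network(pop_specs, projections=(), condition="micro"):
    """A hand-built network of a few neurons for physics tests.

    ``pop_specs``: list of (population_name, size, params_override dict);
    ``projections``: list of (ProjectionSpec, sources_matrix) where the
    matrix has one row of global source ids per target neuron.
    """
    populations = {}
    neuron_params = {}
    first = 0
    for name, size, overrides in pop_specs:
        base = NEURON_PARAMS[name]
        params = dataclasses.replace(base, **overrides) if overrides else base
        kind = "AdEx" if name in ("GPe-TA", "GPe-TI", "SNr") else "LIF"
        populations[name] = Population(name=name, size=size, kind=kind,
                                       first_id=first)
        neuron_params[name] = params
        first += size
    proj_edges = {}
    bundle_projections = {}
    for spec, sources in projections:
        tgt_pop = populations[spec.target]
        proj_edges[spec.name] = ProjectionEdges(
            spec=spec, targets=tgt_pop.ids.astype(np.int32),
            sources=np.asarray(sources, dtype=np.int32))
        bundle_projections[spec.name] = spec
    bundle = ConditionBundle(
        name=condition, dopamine=DopamineState(0.8),
        neuron_params=neuron_params, projections=bundle_projections,
        projections_base=dict(bundle_projections),
    )
    return Network(bundle=bundle, populations=populations,
                   projections=proj_edges, seed=0)


@pytest.fixture
def micro_factory():
    return make_micro_network
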