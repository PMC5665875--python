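"""Shared fixtures: random small networks and the shipped archetype fixtures."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ecowindows.dbn import (
    ConditionalTable,
    ForwardFilter,
    NetworkSchema,
    NodeSpec,
    RegimeSelector,
    StateSpace,
)
from ecowindows.seagrass import build_reference_network
from ecowindows.synth import canonical_bundle, canonical_site


def make_random_network(rng: np.random.Generator, n_nodes: int = 4,
                        n_states: int = 3) -> NetworkSchema:
    """A random DAG-within-slice network with random dense CPTs.

    Every node is guaranteed at least one parent so the network has real
    dynamics; nodes without any would-be parents fall back to a self-loop
    across slices.
    """
    names = [f"n{i}" for i in range(n_nodes)]
    nodes = []
    for i, name in enumerate(names):
        intra = tuple(names[j] for j in range(i) if rng.random() < 0.4)
        inter = tuple(n for n in names if rng.random() < 0.4)
        if not intra and not inter:
            inter = (name,)
        states = StateSpace(tuple(f"s{k}" for k in range(n_states)))
        nodes.append(NodeSpec(name, states, intra, inter))
    tables: dict[str, ConditionalTable] = {}
    selectors: dict[str, RegimeSelector] = {}
    schema = NetworkSchema(nodes, tables, selectors)
    for node in nodes:
        parent_order = tuple(f"{p}[t-1]" for p in node.inter_parents) + node.intra_parents
        label_sets = [
            schema.node(p[:-5] if p.endswith("[t-1]") else p).states.labels
            for p in parent_order
        ]
        rows = {}
        for combo in itertools.product(*label_sets) if label_sets else [()]:
            rows[combo] = rng.dirichlet(np.ones(n_states))
        tables[node.name] = ConditionalTable(node.name, parent_order, rows)
        selectors[node.name] = RegimeSelector(default=node.name)
    return schema


def random_initial(schema: NetworkSchema, rng: np.random.Generator) -> dict:
    return {
        n: rng.dirichlet(np.ones(len(schema.node(n).states)))
        for n in schema.interface
    }


@pytest.fixture(scope="session")
def archetype_setups():
    """(site, schema, filter) per life history for the shipped fixtures."""
    out = {}
    for lh in ("colonising", "opportunistic", "persistent"):
        site = canonical_site(lh)
        schema = build_reference_network(site, canonical_bundle(lh))
        out[lh] = (site, schema, ForwardFilter(schema))
    return out
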