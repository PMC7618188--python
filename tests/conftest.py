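"""Shared fixtures and graph factories for the test suite."""

import numpy as np
import pytest

from lesiongraph.lesion_graph import CohortGraph, LayeredGraph, rescale_weights, to_layered


def random_layered_graph(n, rng, p_edge=0.6):
    """A random small two-layer graph with integer lesion and real task weights."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    keep = [p for p in pairs if rng.random() < p_edge]
    if not keep:
        keep = [pairs[0]]
    edges = np.array(keep)
    e = len(edges)
    graph = CohortGraph(
        nodes=np.arange(n),
        edges=edges,
        lesion_w=rng.integers(1, 6, e),
        task_w=rng.random(e),
        shape=(max(n, 2), 2, 2),
    )
    return to_layered(rescale_weights(graph))


def planted_layered_graph(
    n_blocks=2, block_size=30, p_in=0.3, p_out=0.05,
    mu_in=0.75, mu_out=0.25, sd=0.1, seed=0,
):
    """Planted-partition layered graph: dense, high-weight within blocks."""
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    truth = np.repeat(np.arange(n_blocks), block_size)
    edges, v0, v1 = [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            same = truth[i] == truth[j]
            if rng.random() < (p_in if same else p_out):
                edges.append((i, j))
                mu = mu_in if same else mu_out
                v0.append(np.clip(rng.normal(mu, sd), 0, 1))
                v1.append(np.clip(rng.normal(mu, sd), 0, 1))
    edges = np.array(edges)
    e = len(edges)
    ee = np.arange(e)
    layered = LayeredGraph(
        nodes=np.arange(n),
        edges=edges,
        entry_edge=np.concatenate([ee, ee]),
        entry_layer=np.concatenate([np.zeros(e, np.int8), np.ones(e, np.int8)]),
        entry_value=np.array(v0 + v1),
        entry_count=np.zeros(2 * e, np.int64),
        shape=(n, 1, 1),
    )
    return layered, truth


@pytest.fixture(scope="session")
def template():
    from lesiongraph.synthetic_cohort import default_template

    return default_template()


@pytest.fixture(scope="session")
def small_cohort(template):
    """A small default-conditions cohort shared across read-only tests."""
    from lesiongraph.synthetic_cohort import (
        default_archetypes, default_truth, generate_cohort,
    )

    truth = default_truth(template)
    return generate_cohort(
        template, default_archetypes(template), truth, n_patients=40, seed=7
    )
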