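import numpy as np
import pytest

from epirank import SimulationConfig, run_pipeline_on_dataset, simulate


def pagerank_power_iteration(graph, damping=0.85, tol=1e-14, max_iter=100_000):
    """Dense personalized-PageRank oracle, independent of the implementation.

    Straightforward power iteration on the dense transition matrix with
    restart and dangling mass both following the weight-derived
    personalization vector.
    """
    nodes = list(graph)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    weights = np.array([float(graph.nodes[v].get("weight", 0.0)) for v in nodes])
    p = weights / weights.sum() if weights.sum() > 0 else np.full(n, 1.0 / n)
    adj = np.zeros((n, n))
    for u, v in graph.edges():
        adj[index[u], index[v]] = 1.0
    out_degree = adj.sum(axis=1)
    transition = np.zeros((n, n))
    for i in range(n):
        transition[i] = adj[i] / out_degree[i] if out_degree[i] > 0 else p
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_next = damping * (x @ transition) + (1 - damping) * p
        if np.abs(x_next - x).sum() < tol:
            x = x_next
            break
        x = x_next
    return dict(zip(nodes, x))


@pytest.fixture(scope="session")
def sim_dataset():
    """Default-condition simulated dataset (markers on promoters+enhancers)."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_result(sim_dataset):
    return run_pipeline_on_dataset(sim_dataset)
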