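import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from omicmodules import (
    OmicGraph,
    SampleRegistry,
    SearchParams,
    SimSpec,
    WeightingConfig,
    simulate,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_graph_set(n: int, n_omics: int = 2, seed: int = 0, scale: float = 0.5,
                     loc: float = 0.0) -> list[OmicGraph]:
    """Random symmetric signed weight matrices posing as omic graphs."""
    rng = np.random.default_rng(seed)
    graphs = []
    for i in range(n_omics):
        W = rng.normal(loc, scale, size=(n, n))
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        graphs.append(OmicGraph(f"omic{i + 1}", W, np.ones(n, dtype=bool)))
    return graphs


def ari_pair_counting(a, b) -> float:
    """Independent brute-force Hubert-Arabie ARI over all sample pairs."""
    import itertools

    n11 = n10 = n01 = n00 = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n10 += sa and not sb
        n01 += sb and not sa
        n00 += not sa and not sb
    denom = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    if denom == 0:
        return 1.0
    return 2.0 * (n11 * n00 - n10 * n01) / denom


def set_partitions(items):
    """All set partitions of a list (Bell-number many)."""
    if not items:
        yield []
        return
    head = items[0]
    for part in set_partitions(items[1:]):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1:]
        yield [[head]] + part


def brute_force_heaviest(W: np.ndarray) -> float:
    """Exact maximum subset weight by enumeration (n <= ~14)."""
    n = W.shape[0]
    subsets = np.array([[(s >> i) & 1 for i in range(n)] for s in range(2**n)], dtype=float)
    weights = np.einsum("si,ij,sj->s", subsets, W, subsets) / 2.0
    return float(weights.max())


@pytest.fixture(scope="session")
def blob_dataset():
    """Easy 3-module, 2-omic dataset with full coverage."""
    spec = SimSpec(module_sizes=[40, 40, 40], n_outliers=0, rng_seed=3)
    omics, labels, coverage = simulate(spec)
    registry = SampleRegistry.from_omics(omics)
    return omics, registry, labels, coverage


@pytest.fixture(scope="session")
def blob_graphs(blob_dataset):
    """Consensus graphs for the easy dataset (reduced R for speed)."""
    from omicmodules import build_graphs

    omics, registry, labels, coverage = blob_dataset
    cfg = WeightingConfig(R=30, rng_seed=5)
    graphs, _ = build_graphs(omics, registry, cfg)
    return graphs, labels


@pytest.fixture(scope="session")
def fast_params():
    return SearchParams(restarts=2, rng_seed=7)
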