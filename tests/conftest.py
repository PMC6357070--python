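import numpy as np
import pytest

from synernet.fixtures import (
    VASCULAR_PHENOTYPE,
    vascular_fixture,
    vascular_fixture_network,
)
from synernet.synthetic import OmicsGenConfig, gen_expression, gen_metabolites

STRONG_SHIFT_METABOLITES = (
    "cis-aconitate",
    "malonate",
    "N-acetylglycine",
    "O-acetylcholine",
    "succinate",
    "urea",
    "valproate",
    "2-oxoglutarate",
)


@pytest.fixture(scope="session")
def fixture_subnetwork():
    return vascular_fixture()


@pytest.fixture(scope="session")
def fixture_network():
    return vascular_fixture_network()


@pytest.fixture(scope="session")
def phenotype():
    return VASCULAR_PHENOTYPE


@pytest.fixture(scope="session")
def planted_expression():
    """1000 genes, 50 planted at 2-fold, moderate noise, 10/group."""
    genes = [f"g{i+1:04d}" for i in range(1000)]
    cfg = OmicsGenConfig(
        n_genes=1000,
        n_samples_per_group=10,
        planted_de_genes=set(genes[:50]),
        planted_fold_change=2.0,
        noise_sd=0.4,
        seed=1,
    )
    return gen_expression(cfg), set(genes[:50])


@pytest.fixture(scope="session")
def separated_metabolites():
    """Strongly separated groups: 8 metabolites shifted 3-fold, sd 0.4."""
    cfg = OmicsGenConfig(
        n_samples_per_group=12,
        planted_shift_metabolites={m: 3.0 for m in STRONG_SHIFT_METABOLITES},
        noise_sd=0.4,
        seed=5,
    )
    return gen_metabolites(cfg)


def all_shortest_paths_bruteforce(graph, sources, sinks, max_len):
    """DFS enumeration of every simple path up to max_len; keep per-pair minima."""
    paths = []
    for s in sorted(sources):
        for t in sorted(sinks):
            if s == t:
                continue
            found = []
            stack = [(s, [s])]
            while stack:
                node, path = stack.pop()
                if len(path) - 1 > max_len:
                    continue
                if node == t:
                    found.append(path)
                    continue
                for nxt in graph.successors(node):
                    if nxt not in path:
                        stack.append((nxt, path + [nxt]))
            if found:
                mlen = min(len(p) for p in found)
                paths.extend(p for p in found if len(p) == mlen)
    return paths
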