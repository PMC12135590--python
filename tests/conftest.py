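"""Shared fixtures: tiny hand-written read sets and one mid-sized synthetic
assembly instance reused across traversal tests."""
from __future__ import annotations

import numpy as np
import pytest

from certig import (
    AbundanceHistogram,
    ReadSet,
    abundance_histogram,
    build_threshold_table,
    fit_mixture,
    graph_from_reads,
    make_genome,
    posterior_table,
    simulate_reads,
)

# independent brute-force oracle: per-window canonical counting by string ops
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_canonical_counts(seqs: list[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            rc = naive_revcomp(w)
            canon = w if w <= rc else rc
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def unique_posterior() -> np.ndarray:
    """All mass on alpha=1: the k-mer is certainly unique."""
    return np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])


def repeat2_posterior() -> np.ndarray:
    """All mass on alpha=2."""
    return np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])


@pytest.fixture(scope="session")
def toy_reads() -> ReadSet:
    return ReadSet([("r1", "AAACC")])


@pytest.fixture(scope="session")
def poisson_histogram() -> AbundanceHistogram:
    """Pure single-copy spectrum: Poisson(40) abundances for 10,000 k-mers."""
    rng = np.random.default_rng(40)
    draws = rng.poisson(40, 10_000)
    draws = draws[draws > 0]
    values, counts = np.unique(draws, return_counts=True)
    return AbundanceHistogram(dict(zip(map(int, values), map(int, counts))))


@pytest.fixture(scope="session")
def synthetic_instance():
    """20 kb genome with one 2-copy 1 kb repeat, error-free 40x reads, k=31,
    assembled threshold table at epsilon=0.01 — reused by traversal tests."""
    truth = make_genome(20_000, [(2, 1000)], seed=42)
    reads = simulate_reads(truth, 40, 150, 0.0, seed=43)
    graph = graph_from_reads(reads, 31)
    model = fit_mixture(abundance_histogram(graph))
    posterior = posterior_table(model, graph.max_abundance())
    table = build_threshold_table(posterior, 0.01)
    return {
        "truth": truth,
        "reads": reads,
        "graph": graph,
        "model": model,
        "posterior": posterior,
        "table": table,
    }
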