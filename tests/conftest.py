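"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorised enumeration:
tour lengths are recomputed with plain ``itertools.permutations`` loops so
the two routes check each other.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from amoebatsp import TSPInstance
from amoebatsp.instances import default_labels, generate_experiment_instance


def brute_force_tour_lengths(instance: TSPInstance) -> list[float]:
    """All (n-1)!/2 tour lengths by explicit permutation loop (oracle)."""
    labels = sorted(instance.labels)
    first = labels[0]
    lengths = []
    for perm in itertools.permutations(labels[1:]):
        if perm[0] > perm[-1]:
            continue  # keep one direction per reflection class
        order = (first,) + perm
        total = 0.0
        for a, b in zip(order, order[1:] + (first,)):
            total += instance.dist_between(a, b)
        lengths.append(total)
    return lengths


def make_instance(dist, mode="external") -> TSPInstance:
    dist = np.asarray(dist, dtype=float)
    return TSPInstance(n=len(dist), labels=default_labels(len(dist)), dist=dist, mode=mode)


@pytest.fixture
def ladder4() -> TSPInstance:
    """4 cities, distances AB=10 AC=20 AD=30 BC=40 BD=50 CD=60."""
    return make_instance(
        [
            [0, 10, 20, 30],
            [10, 0, 40, 50],
            [20, 40, 0, 60],
            [30, 50, 60, 0],
        ]
    )


@pytest.fixture
def equi4() -> TSPInstance:
    """4 cities, every distance 100 (degenerate: all tours length 400)."""
    d = np.full((4, 4), 100.0)
    np.fill_diagonal(d, 0.0)
    return make_instance(d)


@pytest.fixture
def equi6() -> TSPInstance:
    d = np.full((6, 6), 100.0)
    np.fill_diagonal(d, 0.0)
    return make_instance(d)


@pytest.fixture(scope="session")
def exp6() -> TSPInstance:
    """A seeded 6-city shaped map, shared across tests."""
    return generate_experiment_instance(6, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
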