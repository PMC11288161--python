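"""Shared fixtures and independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from tauset.io import RankedGeneList, RankedGeneSet


def brute_tau(R, u):
    """Direct O(n^2) pair-counting weighted tau (independent oracle)."""
    R = np.asarray(R, float)
    u = np.asarray(u, float)
    num = den = 0.0
    n = R.size
    for i in range(n):
        for j in range(i + 1, n):
            w = u[i] * u[j]
            num += w * np.sign(R[j] - R[i])
            den += w
    return num / den


def enumeration_variance(u):
    """Variance of the unnormalized statistic over all n! permutations."""
    u = np.asarray(u, float)
    n = u.size
    vals = []
    for perm in itertools.permutations(range(1, n + 1)):
        R = np.asarray(perm, float)
        t = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                t += u[i] * u[j] * np.sign(R[j] - R[i])
        vals.append(t)
    vals = np.asarray(vals)
    return float(vals.mean()), float(vals.var())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_list():
    """g1..g8 with scores 8..1 (g1 ranked first)."""
    genes = [f"g{i}" for i in range(1, 9)]
    return RankedGeneList(genes, np.arange(8, 0, -1, dtype=float))


@pytest.fixture
def toy_set():
    """Top-4 genes of the toy list, set-ranked in the same order."""
    return RankedGeneSet("S1", "top genes", ["g1", "g2", "g3", "g4"],
                         [4.0, 3.0, 2.0, 1.0])
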