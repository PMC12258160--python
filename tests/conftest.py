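"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sgsea.cox_rank import RankedList
from sgsea.io_formats import CountsTable, GeneSetCollection, SurvivalTable


# ---------------------------------------------------------------------------
# independent oracles (deliberately written as plain python loops)
# ---------------------------------------------------------------------------

def oracle_running_sum(stats, is_member, exponent=1.0):
    """Prefix walk of the enrichment score, computed by explicit iteration."""
    n = len(stats)
    hits = [i for i in range(n) if is_member[i]]
    denom = sum(abs(stats[i]) ** exponent for i in hits)
    walk, cur = [], 0.0
    for i in range(n):
        if is_member[i]:
            cur += (abs(stats[i]) ** exponent) / denom if denom > 0 else 1.0 / len(hits)
        else:
            cur -= 1.0 / (n - len(hits))
        walk.append(cur)
    return walk


def oracle_es(stats, is_member, exponent=1.0):
    """Extremum of the walk by absolute value; ties resolve positive."""
    walk = oracle_running_sum(stats, is_member, exponent)
    mx, mn = max(walk), min(walk)
    return mx if mx >= -mn - 1e-12 else mn


def oracle_cox_loglik(beta, x, time):
    """Partial log-likelihood for all-event data with distinct times."""
    order = np.argsort(time)
    xs = np.asarray(x, dtype=float)[order]
    ll = 0.0
    for i in range(len(xs)):
        ll += beta * xs[i] - np.log(np.sum(np.exp(beta * xs[i:])))
    return ll


def oracle_cox_grid(x, time, lo=-10.0, hi=10.0, step=1e-3):
    """Grid-search maximizer of the hand-coded partial likelihood."""
    grid = np.arange(lo, hi + step / 2, step)
    order = np.argsort(time)
    xs = np.asarray(x, dtype=float)[order]
    # vectorized over the grid, still the same plain formula per sample
    lls = np.zeros_like(grid)
    for i in range(len(xs)):
        lls += grid * xs[i] - np.log(np.exp(grid[:, None] * xs[i:]).sum(axis=1))
    return float(grid[np.argmax(lls)])


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def tiny_ranked():
    """Three genes with statistics (3, 2, 1) — the hand-computable universe."""
    return RankedList(genes=["g1", "g2", "g3"], stats=np.array([3.0, 2.0, 1.0]),
                      mode="preranked")


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(42)
    genes = [f"G{i:03d}" for i in range(30)]
    samples = [f"S{i:02d}" for i in range(8)]
    counts = rng.poisson(50, size=(30, 8))
    return CountsTable(pd.DataFrame(counts, index=genes, columns=samples))


@pytest.fixture
def small_survival():
    rng = np.random.default_rng(7)
    samples = [f"S{i:02d}" for i in range(8)]
    time = rng.exponential(100, size=8) + 1
    status = np.array([1, 0, 1, 1, 0, 1, 1, 0])
    return SurvivalTable(pd.DataFrame({"time": time, "status": status}, index=samples))


@pytest.fixture
def random_collection():
    rng = np.random.default_rng(3)
    genes = [f"G{i:03d}" for i in range(30)]
    coll = GeneSetCollection()
    for i in range(5):
        coll.add(f"set{i}", rng.choice(genes, size=6, replace=False), f"random set {i}")
    return coll
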