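"""Shared fixtures: pools are expensive to build, so they are session-scoped."""

import numpy as np
import pytest

from rbpkit import pool as pool_mod
from rbpkit.kmers import KmerUniverse, code_to_kmer


@pytest.fixture(scope="session")
def reduced_pool():
    """Simulation-scale design: order-9 cycle, 15k probes, labeled sets."""
    return pool_mod.build_reduced_pool(seed=1)


@pytest.fixture(scope="session")
def full_pool():
    """The full default design (order-11 cycle, 241,399 probes)."""
    return pool_mod.build_default_pool(seed=1)


def random_probe_pool(rng, n_probes=20, min_len=20, max_len=30, labels=True):
    """Small random pool for toy tests (not de Bruijn derived)."""
    seqs = [
        "".join(rng.choice(list("ACGU"), size=rng.integers(min_len, max_len + 1)))
        for _ in range(n_probes)
    ]
    ids = [f"p{i:03d}" for i in range(n_probes)]
    lab = np.where(np.arange(n_probes) % 2 == 0, "A", "B") if labels else None
    return pool_mod.ProbePool(ids, seqs, lab)


def present_kmer_universe(pool, k):
    """Universe restricted to the k-mers actually present in a toy pool."""
    counts = pool.kmer_counts(k)
    absent = frozenset(
        code_to_kmer(c, k) for c in np.flatnonzero(counts == 0)
    )
    return KmerUniverse(k=k, excluded=absent)
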