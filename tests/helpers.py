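"""Shared builders for tests: compact table construction and random data."""

import numpy as np

from divpart import CommunityMap, CountTable


def make_cmap(habs):
    """CommunityMap from a list of habitat indices, one per community."""
    comms = tuple(f"c{k + 1}" for k in range(len(habs)))
    hab_labels = tuple(f"h{j + 1}" for j in habs)
    return CommunityMap(comms, hab_labels)


def make_table(counts, habs=None, census=0, cmap=None):
    counts = np.atleast_2d(np.asarray(counts))
    if cmap is None:
        if habs is None:
            habs = [0] * counts.shape[1]
        cmap = make_cmap(habs)
    species = tuple(f"s{i + 1}" for i in range(counts.shape[0]))
    return CountTable(counts, species, cmap, census)


def random_habs(rng, max_habitats=3, max_comms=3):
    J = int(rng.integers(1, max_habitats + 1))
    K = int(rng.integers(1, max_comms + 1))
    return [j for j in range(J) for _ in range(K)]


def random_counts(rng, S, C, max_count=20, zero_p=0.35):
    m = rng.integers(1, max_count + 1, size=(S, C))
    m = np.where(rng.random((S, C)) < zero_p, 0, m)
    if m.sum() == 0:
        m[rng.integers(S), rng.integers(C)] = int(rng.integers(1, max_count + 1))
    return m


def random_pair(rng, max_species=6, max_habitats=3, max_comms=3, max_count=20):
    """A random (previous, future) census pair over one shared universe.

    Independent draws with zero inflation, so extinctions and fresh
    immigrant cells both occur naturally.
    """
    S = int(rng.integers(1, max_species + 1))
    habs = random_habs(rng, max_habitats, max_comms)
    C = len(habs)
    prev = random_counts(rng, S, C, max_count)
    fut = random_counts(rng, S, C, max_count)
    cmap = make_cmap(habs)
    species = tuple(f"s{i + 1}" for i in range(S))
    return (
        CountTable(prev, species, cmap, census=0),
        CountTable(fut, species, cmap, census=1),
        habs,
    )
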