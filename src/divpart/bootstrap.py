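"""Parametric bootstrap of the partition terms under a Poisson drift null.

The null holds the present census fixed and resamples each future cell
independently from ``Poisson(mean = present count)``; the present is never
bootstrapped.  Because ``Poisson(0) == 0``, no new (species, community)
cells can appear, so the immigrant classifier (re-applied within every
replicate to keep a single code path) is degenerate under this null: the
immigration term is exactly zero in every replicate.

Replicate ``r`` draws from RNG substream ``r`` (``SeedSequence.spawn``),
so results are independent of execution order and reproducible per seed.
Intervals are empirical type-7 (linear interpolation) quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import COMPONENTS, CountTable, EmptyMetacommunityError
from .partition import TERMS, _partition_terms

__all__ = [
    "TERM_ORDER",
    "BootstrapResult",
    "simulate_null_future",
    "bootstrap_partition",
    "bootstrap_partition_all",
]

#: Column order of :attr:`BootstrapResult.samples`.
TERM_ORDER = TERMS + ("total",)


@dataclass(frozen=True, eq=False)
class BootstrapResult:
    """Empirical bootstrap intervals for the five terms and the total.

    ``samples`` holds the raw replicate values, shape
    ``(n_reps, len(TERM_ORDER))`` with columns in :data:`TERM_ORDER`.
    """

    component: str
    n_reps: int
    level: float
    seed: int | None
    intervals: dict[str, tuple[float, float]]
    samples: np.ndarray


def simulate_null_future(present: CountTable, seed) -> CountTable:
    """One Poisson draw of a future census under the drift null.

    ``seed`` may be anything :func:`numpy.random.default_rng` accepts, or
    an existing :class:`numpy.random.Generator`.  Cells with present count
    zero are zero with certainty.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return present.with_counts(rng.poisson(present.counts), census="null")


def _null_draw(present: CountTable, rng: np.random.Generator) -> CountTable:
    # A fully empty draw cannot be partitioned; retry within the same
    # substream (deterministic, order-independent).  Only plausible for
    # very small present totals.
    for _ in range(1000):
        counts = rng.poisson(present.counts)
        if counts.sum() > 0:
            return present.with_counts(counts, census="null")
    raise RuntimeError(
        "Poisson null repeatedly produced an empty future; present counts "
        "are too small to bootstrap"
    )


def bootstrap_partition_all(
    present: CountTable,
    n_reps: int = 1000,
    level: float = 0.95,
    seed=0,
    z_source: str = "pooled",
) -> dict[str, BootstrapResult]:
    """Bootstrap all three components at once, sharing replicates."""
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if present.total == 0:
        raise EmptyMetacommunityError("cannot bootstrap an empty present census")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_label = seed if isinstance(seed, int) else None
    samples = {c: np.empty((n_reps, len(TERM_ORDER))) for c in COMPONENTS}
    for r, child in enumerate(ss.spawn(n_reps)):
        future = _null_draw(present, np.random.default_rng(child))
        terms, _ = _partition_terms(present, future, z_source=z_source)
        for c in COMPONENTS:
            row = terms[c]
            samples[c][r] = [row[t] for t in TERM_ORDER]

    lo_q = (1.0 - level) / 2.0
    hi_q = 1.0 - lo_q
    results: dict[str, BootstrapResult] = {}
    for c in COMPONENTS:
        qs = np.quantile(samples[c], [lo_q, hi_q], axis=0, method="linear")
        intervals = {
            t: (float(qs[0, i]), float(qs[1, i])) for i, t in enumerate(TERM_ORDER)
        }
        samples[c].setflags(write=False)
        results[c] = BootstrapResult(
            component=c,
            n_reps=n_reps,
            level=level,
            seed=seed_label,
            intervals=intervals,
            samples=samples[c],
        )
    return results


def bootstrap_partition(
    present: CountTable,
    n_reps: int = 1000,
    level: float = 0.95,
    seed=0,
    component: str = "gamma",
    z_source: str = "pooled",
) -> BootstrapResult:
    """Bootstrap one component's partition terms under the Poisson null."""
    if component not in COMPONENTS:
        raise ValueError(f"component must be one of {COMPONENTS}, got {component!r}")
    return bootstrap_partition_all(
        present, n_reps=n_reps, level=level, seed=seed, z_source=z_source
    )[component]
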