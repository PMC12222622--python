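"""Five-term partition of census-to-census change in diversity.

For each component o in {alpha, beta, gamma} the change between two
consecutive censuses splits exactly into

    dH_o = species_selection + habitat_selection + community_selection
           + transmission + immigration

Individuals of species newly observed in a community are classified as
immigrants; everyone else is a resident.  With phi the immigrant fraction
of the future census,

    dH_o = phi * (H'_oI - H_o)  +  (1 - phi) * (H'_od - H_o)

where H'_oI and H'_od average future rarity scores over the immigrant-only
and resident-only weight distributions.  The resident part is then
decomposed with the discrete product rule over the factorisation
``p_ijk = p_i.. * p_j|i. * p_k|ij`` and the rarity scores ``z``:

    term 1 (species):   delta p_i..  with habitat/community/z at present
    term 2 (habitat):   future p_i.., delta p_j|i., rest at present
    term 3 (community): future p_i.., p_j|i., delta p_k|ij, present z
    term 4 (transmission): all future probabilities, delta z

Staggering the deltas this way makes the four terms telescope, so the sum
is exact (not a first-order approximation).  All four are returned already
multiplied by ``1 - phi`` so the published five-term sum equals dH without
rescaling.  Gamma scores are constant within a species, which makes the
habitat and community terms vanish identically for gamma; beta terms equal
gamma minus alpha terms by linearity of ``z_beta``.

Two conventions are offered for the future scores ``z'`` (``z_source``):

``"pooled"`` (default)
    z' computed from the full future metacommunity (immigrants +
    residents).  The immigrant/resident split above is then an algebraic
    identity.
``"resident"``
    z' conditioned on residents only; the immigration term is defined as
    the exact residual ``dH - resident terms`` so additivity still holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    COMPONENTS,
    CountTable,
    DatasetMismatchError,
    EmptyMetacommunityError,
    ProbabilitySet,
    _weighted_mean,
    compute_probabilities,
    rarity_contributions,
)

__all__ = [
    "TERMS",
    "Z_SOURCES",
    "ImmigrantSplit",
    "PartitionResult",
    "classify_immigrants",
    "split_change",
    "decompose_resident_change",
    "partition_change",
    "partition_all",
    "partition_series",
]

#: The five additive terms, in reporting order.
TERMS = (
    "species_selection",
    "habitat_selection",
    "community_selection",
    "transmission",
    "immigration",
)

Z_SOURCES = ("pooled", "resident")


@dataclass(frozen=True)
class ImmigrantSplit:
    """Future census split into immigrant and resident counts.

    ``immigrants.counts + residents.counts`` reproduces the future table
    cellwise; ``phi`` is the immigrant fraction of future individuals.
    """

    immigrants: CountTable
    residents: CountTable
    phi: float


@dataclass(frozen=True)
class PartitionResult:
    """The five-term additive partition of dH for one component.

    All terms are in nats; ``hill_factors`` exposes the multiplicative
    twin ``exp(term)`` of each.  ``resident_defined`` is False when the
    future census contained no residents (phi = 1), in which case the four
    resident terms are zero by convention.
    """

    component: str
    species_selection: float
    habitat_selection: float
    community_selection: float
    transmission: float
    immigration: float
    total: float
    phi: float
    interval: tuple
    resident_defined: bool = True

    @property
    def terms(self) -> dict[str, float]:
        return {t: getattr(self, t) for t in TERMS}

    @property
    def hill_factors(self) -> dict[str, float]:
        out = {t: math.exp(v) for t, v in self.terms.items()}
        out["total"] = math.exp(self.total)
        return out


def classify_immigrants(previous: CountTable, future: CountTable) -> ImmigrantSplit:
    """Default cell-level immigrant classifier.

    Every future individual in a cell (species, community) that held zero
    individuals at the previous census is an immigrant; all other future
    individuals are residents.  Status is assigned per (species, community,
    census) — descendants of earlier immigrants count as residents once
    the species has been observed in the community.
    """
    if not previous.same_universe(future):
        raise DatasetMismatchError(
            "previous and future censuses must share species and communities"
        )
    if future.total == 0:
        raise EmptyMetacommunityError("future census is empty")
    imm = np.where(previous.counts == 0, future.counts, 0)
    res = future.counts - imm
    phi = float(imm.sum() / future.total)
    return ImmigrantSplit(
        immigrants=future.with_counts(imm),
        residents=future.with_counts(res),
        phi=phi,
    )


def _fill(a: np.ndarray) -> np.ndarray:
    """NaN (undefined conditional) -> 0 weight."""
    return np.where(np.isfinite(a), a, 0.0)


def _partition_terms(
    previous: CountTable,
    future: CountTable,
    z_source: str = "pooled",
    split: ImmigrantSplit | None = None,
) -> tuple[dict[str, dict[str, float]], dict]:
    """All components' terms in one pass.

    Returns ``(terms, meta)`` where ``terms[component]`` maps each of the
    five term names plus ``"total"`` to its value in nats, and ``meta``
    carries ``phi``, ``interval`` and ``resident_defined``.
    """
    if z_source not in Z_SOURCES:
        raise ValueError(f"z_source must be one of {Z_SOURCES}, got {z_source!r}")
    if split is None:
        split = classify_immigrants(previous, future)
    else:
        if not np.array_equal(
            split.immigrants.counts + split.residents.counts, future.counts
        ):
            raise ValueError("split is inconsistent with the future census")
    if np.any((split.residents.counts > 0) & (previous.counts == 0)):
        raise ValueError(
            "resident cell with no previous occupancy: the split violates "
            "the classifier contract"
        )

    P = compute_probabilities(previous)  # raises on empty previous
    F = compute_probabilities(future)
    phi = split.phi
    res_total = split.residents.total
    imm_total = split.immigrants.total

    z_prev = {c: rarity_contributions(P, c) for c in ("gamma", "alpha")}
    z_pool = {c: rarity_contributions(F, c) for c in ("gamma", "alpha")}
    Rp: ProbabilitySet | None = None
    if res_total > 0:
        Rp = compute_probabilities(split.residents)
    if z_source == "resident" and Rp is not None:
        z_fut = {c: rarity_contributions(Rp, c) for c in ("gamma", "alpha")}
    else:
        z_fut = z_pool

    H = {c: _weighted_mean(P.joint, z_prev[c], "present entropy") for c in z_prev}
    Hf = {c: _weighted_mean(F.joint, z_pool[c], "future entropy") for c in z_pool}

    if Rp is not None:
        B = _fill(P.habitat_cell)
        C = _fill(P.community_given_sh)
        a2 = Rp.species_marginal
        B2 = _fill(Rp.habitat_cell)
        C2 = _fill(Rp.community_given_sh)
        W1 = a2[:, None] * B * C
        W2 = a2[:, None] * B2 * C
        W3 = Rp.joint
        del C2  # W3 == a2 * B2 * C2 cellwise; the joint is the exact product

    out: dict[str, dict[str, float]] = {}
    for comp in ("gamma", "alpha"):
        d_h = Hf[comp] - H[comp]
        if Rp is not None:
            scale = 1.0 - phi
            s0 = H[comp]
            s1 = _weighted_mean(W1, z_prev[comp], "species term")
            s2 = _weighted_mean(W2, z_prev[comp], "habitat term")
            s3 = _weighted_mean(W3, z_prev[comp], "community term")
            s4 = _weighted_mean(W3, z_fut[comp], "transmission term")
            t_sp = scale * (s1 - s0)
            t_hab = scale * (s2 - s1)
            t_comm = scale * (s3 - s2)
            t_trans = scale * (s4 - s3)
        else:
            t_sp = t_hab = t_comm = t_trans = 0.0
        if imm_total == 0:
            t_imm = 0.0
        elif z_source == "pooled":
            q = split.immigrants.counts / imm_total
            h_i = _weighted_mean(q, z_pool[comp], "immigration term")
            t_imm = phi * (h_i - H[comp])
        else:
            t_imm = d_h - (t_sp + t_hab + t_comm + t_trans)
        out[comp] = {
            "species_selection": t_sp,
            "habitat_selection": t_hab,
            "community_selection": t_comm,
            "transmission": t_trans,
            "immigration": t_imm,
            "total": d_h,
        }
    # z_beta = z_gamma - z_alpha and every term is linear in z, so beta
    # terms are the exact differences.
    out["beta"] = {k: out["gamma"][k] - out["alpha"][k] for k in out["gamma"]}

    meta = {
        "phi": phi,
        "interval": (previous.census, future.census),
        "resident_defined": res_total > 0,
    }
    return out, meta


def split_change(
    previous: CountTable,
    future: CountTable,
    split: ImmigrantSplit | None = None,
    component: str = "gamma",
    z_source: str = "pooled",
) -> tuple[float, float]:
    """Immigrant/resident split of dH for one component.

    Returns ``(immigration_term, resident_term)``; the two sum to the
    total change.  ``resident_term`` is zero (and flagged via
    :class:`PartitionResult` elsewhere) when phi = 1.
    """
    _check_component(component)
    terms, _ = _partition_terms(previous, future, z_source=z_source, split=split)
    t = terms[component]
    resident = (
        t["species_selection"]
        + t["habitat_selection"]
        + t["community_selection"]
        + t["transmission"]
    )
    return t["immigration"], resident


def decompose_resident_change(
    previous: CountTable,
    split: ImmigrantSplit,
    component: str = "gamma",
    z_source: str = "pooled",
) -> tuple[float, float, float, float]:
    """Staggered product-rule decomposition of the resident change.

    Returns ``(species_selection, habitat_selection, community_selection,
    transmission)``, each already multiplied by ``1 - phi`` so they sum
    with the immigration term to the total change.
    """
    _check_component(component)
    future = split.residents.with_counts(
        split.residents.counts + split.immigrants.counts
    )
    terms, _ = _partition_terms(previous, future, z_source=z_source, split=split)
    t = terms[component]
    return (
        t["species_selection"],
        t["habitat_selection"],
        t["community_selection"],
        t["transmission"],
    )


def partition_change(
    previous: CountTable,
    future: CountTable,
    component: str = "gamma",
    z_source: str = "pooled",
) -> PartitionResult:
    """Full five-term partition of dH for one component."""
    _check_component(component)
    return partition_all(previous, future, z_source=z_source)[component]


def partition_all(
    previous: CountTable,
    future: CountTable,
    z_source: str = "pooled",
) -> dict[str, PartitionResult]:
    """Five-term partition for all three components in one pass."""
    terms, meta = _partition_terms(previous, future, z_source=z_source)
    return {
        comp: PartitionResult(
            component=comp,
            species_selection=terms[comp]["species_selection"],
            habitat_selection=terms[comp]["habitat_selection"],
            community_selection=terms[comp]["community_selection"],
            transmission=terms[comp]["transmission"],
            immigration=terms[comp]["immigration"],
            total=terms[comp]["total"],
            phi=meta["phi"],
            interval=meta["interval"],
            resident_defined=meta["resident_defined"],
        )
        for comp in COMPONENTS
    }


def partition_series(
    tables: Sequence[CountTable],
    z_source: str = "pooled",
) -> dict[str, list[PartitionResult]]:
    """Partition every consecutive census pair of an ordered dataset.

    Returns one list of :class:`PartitionResult` per component; interval
    totals telescope, so their sum equals ``H(last) - H(first)``.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 censuses to partition change")
    for t in tables[1:]:
        if not tables[0].same_universe(t):
            raise DatasetMismatchError(
                "all censuses must share species, communities and habitats"
            )
    out: dict[str, list[PartitionResult]] = {c: [] for c in COMPONENTS}
    for prev, fut in zip(tables[:-1], tables[1:]):
        results = partition_all(prev, fut, z_source=z_source)
        for c in COMPONENTS:
            out[c].append(results[c])
    return out


def _check_component(component: str) -> None:
    if component not in COMPONENTS:
        raise ValueError(f"component must be one of {COMPONENTS}, got {component!r}")
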