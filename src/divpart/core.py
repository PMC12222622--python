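"""Hierarchical metacommunity counts and Shannon diversity components.

Counts are stored species x community, with every community nested in
exactly one habitat (the habitat index is derived from the community, so a
community can never sit in two habitats).  Relative abundances factor along
the hierarchy as

    p_ijk = p_i.. * p_j|i. * p_k|ij

and each diversity component is the abundance-weighted mean of
per-individual rarity scores ``z``:

    H_o = sum_ijk p_ijk * z_ijk_o        (natural log; nats)

with ``z_gamma = -log p_i..`` (rarity across the whole region),
``z_alpha = -log p_i|jk`` (rarity within the individual's community) and
``z_beta = z_gamma - z_alpha``.  All individuals are weighted equally, so
alpha is the abundance-weighted average of within-community entropies and
beta is the mutual information between species identity and location
(hence ``H_beta >= 0`` and ``H_gamma = H_alpha + H_beta``).

Exponentiating an entropy (or an entropy change) converts it to the Hill
scale: the equivalent number of uniformly distributed species.

Conventions
-----------
* ``0 * log 0 == 0``; any product containing a zero probability factor is
  zero even when the paired rarity score is undefined.
* Conditional probabilities whose conditioning event has zero mass are
  *undefined*: stored as NaN with the matching ``defined`` mask ``False``.
  They always carry zero weight downstream; an undefined score meeting a
  positive weight raises instead of propagating NaN.
* Identity checks (normalisation, factorisation, additivity) hold to
  :data:`TOL` in double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "TOL",
    "COMPONENTS",
    "CommunityMap",
    "CountTable",
    "ProbabilitySet",
    "ContributionTensor",
    "DiversityValue",
    "compute_probabilities",
    "rarity_contributions",
    "shannon",
    "diversity_components",
    "hill_transform",
    "EmptyMetacommunityError",
    "DatasetMismatchError",
]

#: Tolerance for the internal probability/entropy identities (double precision).
TOL = 1e-12

#: Diversity components, in canonical order.
COMPONENTS = ("alpha", "beta", "gamma")


class EmptyMetacommunityError(ValueError):
    """The operation needs at least one individual in the metacommunity."""


class DatasetMismatchError(ValueError):
    """Tables do not share the same species/community/habitat universe."""


@dataclass(frozen=True)
class CommunityMap:
    """Nesting of communities in habitats.

    Parameters
    ----------
    community_ids :
        Globally unique community labels, one per community.
    habitat_ids :
        Habitat label of each community (parallel to ``community_ids``).
        Each community belongs to exactly one habitat, and the map is
        shared by every census of a dataset.
    """

    community_ids: tuple[str, ...]
    habitat_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "community_ids", tuple(str(c) for c in self.community_ids)
        )
        object.__setattr__(
            self, "habitat_ids", tuple(str(h) for h in self.habitat_ids)
        )
        if len(self.community_ids) != len(self.habitat_ids):
            raise ValueError("community_ids and habitat_ids differ in length")
        if not self.community_ids:
            raise ValueError("need at least one community")
        if len(set(self.community_ids)) != len(self.community_ids):
            dupes = sorted(
                {c for c in self.community_ids if self.community_ids.count(c) > 1}
            )
            raise ValueError(f"community ids must be globally unique: {dupes}")

    @classmethod
    def from_sizes(
        cls,
        n_habitats: int,
        communities_per_habitat: int,
        habitat_prefix: str = "h",
        community_prefix: str = "c",
    ) -> "CommunityMap":
        """Regular grid of ``n_habitats`` habitats x ``communities_per_habitat``."""
        comms: list[str] = []
        habs: list[str] = []
        for j in range(1, n_habitats + 1):
            for k in range(1, communities_per_habitat + 1):
                habs.append(f"{habitat_prefix}{j}")
                comms.append(f"{habitat_prefix}{j}{community_prefix}{k}")
        return cls(tuple(comms), tuple(habs))

    @property
    def n_communities(self) -> int:
        return len(self.community_ids)

    @cached_property
    def habitats(self) -> tuple[str, ...]:
        """Unique habitat labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for h in self.habitat_ids:
            seen.setdefault(h)
        return tuple(seen)

    @property
    def n_habitats(self) -> int:
        return len(self.habitats)

    @cached_property
    def habitat_index(self) -> np.ndarray:
        """Index into :attr:`habitats` for each community, shape ``(C,)``."""
        pos = {h: i for i, h in enumerate(self.habitats)}
        idx = np.array([pos[h] for h in self.habitat_ids], dtype=np.intp)
        idx.setflags(write=False)
        return idx

    @cached_property
    def membership(self) -> np.ndarray:
        """One-hot community-by-habitat matrix, shape ``(C, J)``."""
        m = np.zeros((self.n_communities, self.n_habitats))
        m[np.arange(self.n_communities), self.habitat_index] = 1.0
        m.setflags(write=False)
        return m

    def habitat_of(self, community_id: str) -> str:
        try:
            i = self.community_ids.index(str(community_id))
        except ValueError:
            raise DatasetMismatchError(
                f"community {community_id!r} not in CommunityMap"
            ) from None
        return self.habitat_ids[i]


@dataclass(frozen=True, eq=False)
class CountTable:
    """One census of a metacommunity: integer counts, species x community.

    Parameters
    ----------
    counts :
        Nonnegative integers, shape ``(n_species, n_communities)``.
    species_ids :
        Species labels (rows of ``counts``).
    cmap :
        Community-to-habitat nesting shared by every census of the dataset.
    census :
        Sortable census label (sampling period).
    """

    counts: np.ndarray
    species_ids: tuple[str, ...]
    cmap: CommunityMap
    census: object = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be 2-D (species x community)")
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            flt = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(flt)) or np.any(flt != np.floor(flt)):
                raise ValueError("counts must be integers")
        arr = arr.astype(np.int64, copy=True)
        if np.any(arr < 0):
            raise ValueError("counts must be >= 0")
        species = tuple(str(s) for s in self.species_ids)
        if len(set(species)) != len(species):
            raise ValueError("species ids must be unique")
        if arr.shape != (len(species), self.cmap.n_communities):
            raise DatasetMismatchError(
                f"counts shape {arr.shape} does not match "
                f"{len(species)} species x {self.cmap.n_communities} communities"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "species_ids", species)

    @classmethod
    def from_array(
        cls,
        counts,
        cmap: CommunityMap | None = None,
        census: object = 0,
        species_ids=None,
    ) -> "CountTable":
        """Build a table from an array, defaulting to one habitat and
        auto-generated species labels (convenient in tests and examples)."""
        arr = np.atleast_2d(np.asarray(counts))
        if cmap is None:
            cmap = CommunityMap.from_sizes(1, arr.shape[1])
        if species_ids is None:
            species_ids = tuple(f"s{i + 1}" for i in range(arr.shape[0]))
        return cls(arr, tuple(species_ids), cmap, census)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_communities(self) -> int:
        return self.cmap.n_communities

    @property
    def total(self) -> int:
        """Grand total ``n_...`` of individuals across all cells."""
        return int(self.counts.sum())

    def with_counts(self, counts, census: object = None) -> "CountTable":
        """Same universe, new counts (and optionally a new census label)."""
        return CountTable(
            counts,
            self.species_ids,
            self.cmap,
            self.census if census is None else census,
        )

    def same_universe(self, other: "CountTable") -> bool:
        return self.species_ids == other.species_ids and self.cmap == other.cmap


@dataclass(frozen=True, eq=False)
class ProbabilitySet:
    """Joint, marginal, and conditional relative abundances for one census.

    Undefined conditionals (zero-mass conditioning events) are NaN; they
    always carry zero weight in downstream sums.

    Attributes
    ----------
    joint : ndarray, shape (S, C)
        ``p_ijk = n_ijk / n_...``.
    species_marginal : ndarray, shape (S,)
        ``p_i.. = n_i.. / n_...``, relative abundance across the region.
    within_community : ndarray, shape (S, C)
        ``p_i|jk = n_ijk / n_.jk``; NaN where the community is empty.
    habitat_given_species : ndarray, shape (S, J)
        ``p_j|i. = n_ij. / n_i..``; NaN where the species is absent.
    community_given_sh : ndarray, shape (S, C)
        ``p_k|ij = n_ijk / n_ij.``; NaN where the (species, habitat) pair
        is empty.
    """

    joint: np.ndarray
    species_marginal: np.ndarray
    within_community: np.ndarray
    habitat_given_species: np.ndarray
    community_given_sh: np.ndarray
    n_total: int
    species_ids: tuple[str, ...]
    cmap: CommunityMap

    @cached_property
    def habitat_cell(self) -> np.ndarray:
        """``p_j|i.`` expanded to cells: entry ``(i, k)`` is
        ``p_{j(k)|i.}``, shape ``(S, C)``."""
        return self.habitat_given_species[:, self.cmap.habitat_index]

    @property
    def community_occupied(self) -> np.ndarray:
        """Boolean ``(C,)``: community has at least one individual."""
        return self.joint.sum(axis=0) > 0


@dataclass(frozen=True, eq=False)
class ContributionTensor:
    """Per-cell rarity scores ``z`` for one diversity component, in nats.

    ``values`` is NaN exactly where ``defined`` is ``False`` (zero-support
    cells); such cells must only ever meet zero weight.
    """

    component: str
    values: np.ndarray
    defined: np.ndarray


@dataclass(frozen=True)
class DiversityValue:
    """A diversity component as entropy (nats by default) and Hill number."""

    component: str
    entropy: float
    hill: float


def compute_probabilities(table: CountTable) -> ProbabilitySet:
    """All five probability arrays of a census.

    Raises
    ------
    EmptyMetacommunityError
        If the table holds no individuals.
    """
    n = table.counts.astype(float)
    total = n.sum()
    if total <= 0:
        raise EmptyMetacommunityError("metacommunity is empty (total count 0)")
    joint = n / total
    species_tot = n.sum(axis=1)
    species_marginal = species_tot / total

    comm_tot = n.sum(axis=0)
    within = np.where(
        comm_tot > 0, n / np.where(comm_tot > 0, comm_tot, 1.0), np.nan
    )

    n_ij = n @ table.cmap.membership  # (S, J)
    hab_given_sp = np.where(
        species_tot[:, None] > 0,
        n_ij / np.where(species_tot[:, None] > 0, species_tot[:, None], 1.0),
        np.nan,
    )
    denom_cell = n_ij[:, table.cmap.habitat_index]  # (S, C)
    comm_given = np.where(
        denom_cell > 0, n / np.where(denom_cell > 0, denom_cell, 1.0), np.nan
    )

    return ProbabilitySet(
        joint=joint,
        species_marginal=species_marginal,
        within_community=within,
        habitat_given_species=hab_given_sp,
        community_given_sh=comm_given,
        n_total=int(total),
        species_ids=table.species_ids,
        cmap=table.cmap,
    )


def rarity_contributions(
    probs: ProbabilitySet, component: str
) -> ContributionTensor:
    """Per-individual rarity scores for one component.

    ``gamma`` scores depend only on the species marginal (constant across
    habitat and community within a species); ``alpha`` scores on the
    within-community relative abundance; ``beta`` is their cellwise
    difference.
    """
    if component not in COMPONENTS:
        raise ValueError(f"component must be one of {COMPONENTS}, got {component!r}")
    shape = probs.joint.shape
    pm = probs.species_marginal
    g_def = np.broadcast_to((pm > 0)[:, None], shape)
    with np.errstate(divide="ignore"):
        zg = np.broadcast_to(
            np.where(pm > 0, -np.log(np.where(pm > 0, pm, 1.0)), np.nan)[:, None],
            shape,
        )
    w = probs.within_community
    a_def = np.isfinite(w) & (w > 0)
    za = np.where(a_def, -np.log(np.where(a_def, w, 1.0)), np.nan)

    if component == "gamma":
        values, defined = np.array(zg), np.array(g_def)
    elif component == "alpha":
        values, defined = za, a_def
    else:  # beta
        defined = np.array(g_def & a_def)
        values = np.where(defined, zg - za, np.nan)
    values.setflags(write=False)
    defined.setflags(write=False)
    return ContributionTensor(component, values, defined)


def _weighted_mean(weights, tensor: ContributionTensor, what: str = "entropy") -> float:
    """``sum(weights * z)`` with zero-weight short-circuiting.

    Raises if an undefined score meets positive weight — that indicates a
    bookkeeping violation upstream, never a legitimate state.
    """
    w = np.asarray(weights, dtype=float)
    if np.any((w > 0) & ~tensor.defined):
        raise ValueError(
            f"undefined {tensor.component} rarity score carries positive "
            f"weight in {what}"
        )
    return float(
        np.sum(np.where(w > 0, w, 0.0) * np.where(tensor.defined, tensor.values, 0.0))
    )


def shannon(
    table: CountTable, component: str = "gamma", base: float | None = None
) -> DiversityValue:
    """Shannon diversity component of one census.

    Parameters
    ----------
    table : CountTable
    component : {"alpha", "beta", "gamma"}
    base :
        Optional logarithm base for the reported entropy (e.g. 2 or 10).
        Default is the natural logarithm (nats).  The Hill number is
        base-invariant and always equals ``exp(H_nats)``.
    """
    probs = compute_probabilities(table)
    z = rarity_contributions(probs, component)
    h_nats = _weighted_mean(probs.joint, z, what=f"{component} entropy")
    entropy = h_nats if base is None else h_nats / math.log(base)
    return DiversityValue(component, entropy, math.exp(h_nats))


def diversity_components(
    table: CountTable, base: float | None = None
) -> dict[str, DiversityValue]:
    """All three components of one census, keyed by component name."""
    return {c: shannon(table, c, base=base) for c in COMPONENTS}


def hill_transform(entropy_change: float) -> float:
    """Convert an entropy (change) in nats to the multiplicative Hill scale.

    ``exp`` turns additive entropy terms into multiplicative factors:
    ``hill_transform(a + b) == hill_transform(a) * hill_transform(b)``.
    """
    return math.exp(entropy_change)
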