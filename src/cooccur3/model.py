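"""Core domain types: species panel, phyletic profiles, complexes, networks."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

#: Default species-code convention: 4 uppercase letters prefixing the gene part.
SPECIES_CODE_RE = re.compile(r"^([A-Z]{4})")


class DataError(ValueError):
    """Raised for invalid domain data."""


@dataclass(frozen=True)
class SpeciesPanel:
    """Ordered, fixed set of species identifiers shared by all profiles."""

    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise DataError("duplicate species identifiers in panel")
        if len(self.species) < 4:
            raise DataError("panel must contain at least 4 species")

    @classmethod
    def from_iterable(cls, species: Iterable[str]) -> "SpeciesPanel":
        return cls(tuple(species))

    @property
    def n(self) -> int:
        return len(self.species)

    def index(self, species: str) -> int:
        return self.species.index(species)

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self) -> Iterator[str]:
        return iter(self.species)


class PhyleticProfile:
    """Per-species copy counts for one orthologous group.

    Presence is derived: a species counts as having the gene iff its
    copy count is positive.  In-paralog counts are kept so the same
    object serves both the co-occurrence analysis (presence only) and
    the duplication-retention analysis.
    """

    __slots__ = ("og_id", "counts", "panel")

    def __init__(self, og_id: str, counts: Iterable[int], panel: SpeciesPanel):
        arr = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
        if arr.ndim != 1 or len(arr) != panel.n:
            raise DataError(
                f"profile {og_id!r}: expected {panel.n} counts, got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise DataError(f"profile {og_id!r}: non-integer copy count")
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            raise DataError(f"profile {og_id!r}: negative copy count")
        self.og_id = og_id
        self.counts = arr.astype(np.int64)
        self.panel = panel

    @property
    def presence(self) -> np.ndarray:
        return self.counts > 0

    @property
    def n_present(self) -> int:
        return int((self.counts > 0).sum())

    def present_species(self) -> list[str]:
        return [s for s, c in zip(self.panel, self.counts) if c > 0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyleticProfile):
            return NotImplemented
        return (self.og_id == other.og_id
                and self.panel == other.panel
                and np.array_equal(self.counts, other.counts))

    def __repr__(self) -> str:
        return f"PhyleticProfile({self.og_id!r}, present={self.n_present}/{self.panel.n})"


class ProfileMatrix:
    """Mapping og_id -> PhyleticProfile over one shared panel."""

    def __init__(self, panel: SpeciesPanel,
                 profiles: Mapping[str, PhyleticProfile] | None = None):
        self.panel = panel
        self._profiles: dict[str, PhyleticProfile] = {}
        if profiles:
            for og_id, prof in profiles.items():
                self.add(prof)

    def add(self, profile: PhyleticProfile) -> None:
        if profile.panel != self.panel:
            raise DataError(f"profile {profile.og_id!r} uses a different panel")
        if profile.og_id in self._profiles:
            raise DataError(f"duplicate og_id {profile.og_id!r}")
        self._profiles[profile.og_id] = profile

    def replace(self, profile: PhyleticProfile) -> None:
        if profile.og_id not in self._profiles:
            raise DataError(f"cannot replace unknown og_id {profile.og_id!r}")
        if profile.panel != self.panel:
            raise DataError(f"profile {profile.og_id!r} uses a different panel")
        self._profiles[profile.og_id] = profile

    def __getitem__(self, og_id: str) -> PhyleticProfile:
        return self._profiles[og_id]

    def __contains__(self, og_id: str) -> bool:
        return og_id in self._profiles

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[str]:
        return iter(self._profiles)

    @property
    def og_ids(self) -> list[str]:
        return list(self._profiles)

    def values(self) -> Iterable[PhyleticProfile]:
        return self._profiles.values()

    def items(self):
        return self._profiles.items()

    def counts_array(self, og_ids: Iterable[str] | None = None) -> np.ndarray:
        """Stacked (n_ogs, n_species) copy-count matrix."""
        ids = list(og_ids) if og_ids is not None else self.og_ids
        return np.stack([self._profiles[i].counts for i in ids])

    def presence_array(self, og_ids: Iterable[str] | None = None) -> np.ndarray:
        return self.counts_array(og_ids) > 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProfileMatrix):
            return NotImplemented
        return (self.panel == other.panel
                and self._profiles == other._profiles)


@dataclass
class OrthologMap:
    """protein_id -> og_id bridge between network IDs and profile IDs.

    Proteins that cannot be mapped are recorded in ``unmapped`` rather
    than silently dropped.
    """

    mapping: dict[str, str]
    unmapped: set[str] = field(default_factory=set)

    def __getitem__(self, protein_id: str) -> str:
        return self.mapping[protein_id]

    def get(self, protein_id: str) -> str | None:
        return self.mapping.get(protein_id)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.mapping

    def species_of(self, protein_id: str,
                   pattern: re.Pattern = SPECIES_CODE_RE) -> str:
        m = pattern.match(protein_id)
        if not m:
            raise DataError(f"protein id {protein_id!r} has no species code")
        return m.group(1)


class ComplexSet:
    """complex_id -> set of member protein IDs; every complex has >= 2 members."""

    def __init__(self, complexes: Mapping[str, Iterable[str]] | None = None):
        self._complexes: dict[str, frozenset[str]] = {}
        if complexes:
            for cid, members in complexes.items():
                self.add(cid, members)

    def add(self, complex_id: str, members: Iterable[str]) -> None:
        members = list(members)
        if len(set(members)) != len(members):
            raise DataError(f"complex {complex_id!r} has duplicate members")
        if len(members) < 2:
            raise DataError(f"complex {complex_id!r} has fewer than 2 members")
        if complex_id in self._complexes:
            raise DataError(f"duplicate complex id {complex_id!r}")
        self._complexes[complex_id] = frozenset(members)

    def __getitem__(self, complex_id: str) -> frozenset[str]:
        return self._complexes[complex_id]

    def __contains__(self, complex_id: str) -> bool:
        return complex_id in self._complexes

    def __len__(self) -> int:
        return len(self._complexes)

    def __iter__(self) -> Iterator[str]:
        return iter(self._complexes)

    def items(self):
        return self._complexes.items()

    @property
    def complex_ids(self) -> list[str]:
        return list(self._complexes)

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for members in self._complexes.values():
            out |= members
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComplexSet):
            return NotImplemented
        return self._complexes == other._complexes


class InteractionNetwork:
    """Undirected simple graph of proteins or orthologous groups.

    OG-level networks built by projection carry, per edge, the set of
    protein pairs that realized it (``provenance``), plus a counter of
    in-paralog (intra-OG) interactions that were dropped.
    """

    def __init__(self, level: str = "protein"):
        if level not in ("protein", "og"):
            raise DataError(f"unknown network level {level!r}")
        self.level = level
        self.graph = nx.Graph()
        self.intra_og_edges = 0

    def add_edge(self, u: str, v: str,
                 provenance: tuple[str, str] | None = None) -> None:
        if u == v:
            raise DataError(f"self-interaction {u!r}")
        if not self.graph.has_edge(u, v):
            self.graph.add_edge(u, v, provenance=set())
        if provenance is not None:
            self.graph.edges[u, v]["provenance"].add(tuple(sorted(provenance)))

    def add_node(self, u: str) -> None:
        self.graph.add_node(u)

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def provenance(self, u: str, v: str) -> set[tuple[str, str]]:
        return self.graph.edges[u, v]["provenance"]

    def neighbors(self, u: str) -> list[str]:
        return list(self.graph.neighbors(u))

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return (self.level == other.level
                and set(self.graph.nodes) == set(other.graph.nodes)
                and set(self.edges()) == set(other.edges()))
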