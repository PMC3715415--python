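"""Complementarity scoring of profile triplets and triangle typing.

For a central gene A and partners B, C the score rewards species where A
is present together with exactly one of B and C (the two complexes
complement each other) and penalizes species violating the pattern:
A present with both partners absent, or A absent while a partner is
present.  score = min(nGood_B, nGood_C) - nBad.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .model import DataError, InteractionNetwork, PhyleticProfile

TRIANGLE_TYPES = ("open", "open2A", "closed", "none")


class ScoreComponents(NamedTuple):
    n_good_b: int
    n_good_c: int
    n_bad: int
    score: int


@dataclass
class TripletRecord:
    og_a: str                       # central gene
    og_b: str
    og_c: str
    triangle_type: str
    n_good_b: int
    n_good_c: int
    n_bad: int
    score: int

    def __post_init__(self) -> None:
        if len({self.og_a, self.og_b, self.og_c}) != 3:
            raise DataError("triplet members must be pairwise distinct")
        if self.og_b > self.og_c:   # canonical partner order
            self.og_b, self.og_c = self.og_c, self.og_b
            self.n_good_b, self.n_good_c = self.n_good_c, self.n_good_b

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.og_a, self.og_b, self.og_c)


def complementarity_score(pa: PhyleticProfile, pb: PhyleticProfile,
                          pc: PhyleticProfile) -> ScoreComponents:
    """Score a triplet with A central.

    nGood_B = #species(A & B & ~C); nGood_C = #species(A & ~B & C);
    nBad counts each violating species once: A present with B and C
    both absent, or A absent with B or C present.
    """
    if pa.panel != pb.panel or pa.panel != pc.panel:
        raise DataError("complementarity_score: profiles on different panels")
    a, b, c = pa.presence, pb.presence, pc.presence
    n_good_b = int((a & b & ~c).sum())
    n_good_c = int((a & ~b & c).sum())
    n_bad = int(((a & ~b & ~c) | (~a & (b | c))).sum())
    return ScoreComponents(n_good_b, n_good_c, n_bad,
                           min(n_good_b, n_good_c) - n_bad)


def complementarity_score_arrays(a: np.ndarray, b: np.ndarray,
                                 c: np.ndarray) -> np.ndarray:
    """Vectorized scores for stacked presence arrays (..., n_species)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    c = np.asarray(c, bool)
    n_good_b = (a & b & ~c).sum(axis=-1)
    n_good_c = (a & ~b & c).sum(axis=-1)
    n_bad = ((a & ~b & ~c) | (~a & (b | c))).sum(axis=-1)
    return np.minimum(n_good_b, n_good_c) - n_bad


def central_filter(pa: PhyleticProfile, n: int | None = None) -> bool:
    """Central gene must be present in at least half of all species."""
    n = pa.panel.n if n is None else n
    return pa.n_present >= int(np.ceil(n / 2))


def triangle_type(og_a: str, og_b: str, og_c: str,
                  net: InteractionNetwork) -> str:
    """Type of the triplet with ``og_a`` central, from an OG-level graph.

    closed: all three edges present.  open: A-B and A-C present, B-C
    absent.  open2A: open, and the A-side proteins realizing A-B are
    disjoint from those realizing A-C (two in-paralogs of A take the
    two roles).  none: anything else.
    """
    for og in (og_a, og_b, og_c):
        if og not in net.graph:
            raise DataError(f"OG {og!r} not in network")
    ab = net.has_edge(og_a, og_b)
    ac = net.has_edge(og_a, og_c)
    bc = net.has_edge(og_b, og_c)
    if ab and ac and bc:
        return "closed"
    if ab and ac and not bc:
        a_side_b = _a_side_proteins(net, og_a, og_b)
        a_side_c = _a_side_proteins(net, og_a, og_c)
        if a_side_b and a_side_c and not (a_side_b & a_side_c):
            return "open2A"
        return "open"
    return "none"


def _a_side_proteins(net: InteractionNetwork, og_a: str, og_x: str) -> set[str]:
    """All proteins appearing in the provenance of OG edge A-X.

    Since OGs partition proteins and og_b != og_c, intersecting the
    provenance protein sets of edges A-B and A-C can only ever hit
    members of OG A, so side attribution by name is unnecessary.
    """
    prov = net.provenance(og_a, og_x)
    proteins: set[str] = set()
    for pair in prov:
        proteins.update(pair)
    return proteins


def open_triangles(net: InteractionNetwork,
                   central_ogs: set[str] | None = None) -> list[tuple[str, str, str]]:
    """Enumerate (A, B, C) with A-B, A-C edges and no B-C edge; B < C."""
    if net.level != "og":
        raise DataError("open_triangles expects an OG-level network")
    out = []
    for a in sorted(net.nodes):
        if central_ogs is not None and a not in central_ogs:
            continue
        nbrs = sorted(net.neighbors(a))
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                b, c = nbrs[i], nbrs[j]
                if not net.has_edge(b, c):
                    out.append((a, b, c))
    return out


def closed_triangles(net: InteractionNetwork) -> list[tuple[str, str, str]]:
    """Enumerate closed triangles as sorted node triples."""
    if net.level != "og":
        raise DataError("closed_triangles expects an OG-level network")
    out = []
    nodes = sorted(net.nodes)
    for a in nodes:
        for b in sorted(net.neighbors(a)):
            if b <= a:
                continue
            for c in sorted(net.neighbors(b)):
                if c <= b:
                    continue
                if net.has_edge(a, c):
                    out.append((a, b, c))
    return out
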