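"""Linking triplet scores back to the pairwise classification.

Pairs on the A-side of positive-scoring open triangles are
cross-tabulated against their 4-way category, tested for
over-representation, and laid out on a pair-score x triplet-score
log2-enrichment grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .model import DataError
from .pairwise import CATEGORIES, PairRecord
from .triplets import TripletRecord


@dataclass
class CrossTab:
    """Per category: total classified pairs vs. pairs found in at least
    one positive-scoring open triangle."""

    total: dict[str, int] = field(default_factory=dict)
    in_triplet: dict[str, int] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.total.values())

    @property
    def n_in_triplet(self) -> int:
        return sum(self.in_triplet.values())


def positive_triplet_pairs(triplets: Sequence[TripletRecord],
                           pairs: Sequence[PairRecord],
                           min_score: int = 0) -> CrossTab:
    """Cross-tab of classified pairs by positive-open-triangle membership.

    A pair is 'in' iff it equals an (A,B) or (A,C) side of an open
    triangle (plain or with duplicated A) scoring strictly above
    ``min_score``.
    """
    member_pairs: set[tuple[str, str]] = set()
    for t in triplets:
        if t.triangle_type in ("open", "open2A", "open_taxsubset") \
                and t.score > min_score:
            member_pairs.add(tuple(sorted((t.og_a, t.og_b))))
            member_pairs.add(tuple(sorted((t.og_a, t.og_c))))
    ct = CrossTab(total={c: 0 for c in CATEGORIES},
                  in_triplet={c: 0 for c in CATEGORIES})
    for rec in pairs:
        if not rec.eligible or rec.category is None:
            continue
        ct.total[rec.category] += 1
        if tuple(sorted((rec.og_a, rec.og_b))) in member_pairs:
            ct.in_triplet[rec.category] += 1
    return ct


def overrepresentation(ct: CrossTab, category: str,
                       yates: bool = False) -> tuple[float, float]:
    """Excess of in-triplet pairs in one category vs. random assignment.

    Returns (percent excess, chi-square p) from the 2x2 table
    in-triplet x in-category.  Expected in-triplet fraction is the
    category-blind overall fraction.
    """
    if category not in ct.total or ct.total[category] == 0:
        raise DataError(f"overrepresentation: empty category {category!r}")
    n_cat = ct.total[category]
    k_cat = ct.in_triplet[category]
    n_rest = ct.n_total - n_cat
    k_rest = ct.n_in_triplet - k_cat
    expected_frac = ct.n_in_triplet / ct.n_total
    observed_frac = k_cat / n_cat
    if expected_frac == 0:
        raise DataError("overrepresentation: no in-triplet pairs at all")
    excess = (observed_frac / expected_frac - 1.0) * 100.0
    table = np.array([[k_cat, n_cat - k_cat], [k_rest, n_rest - k_rest]])
    if table.min() < 0 or n_rest == 0:
        raise DataError("overrepresentation: degenerate 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return excess, 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return excess, float(p)


@dataclass
class EnrichmentGrid:
    pair_edges: np.ndarray          # len = n_pair_bins + 1
    triplet_edges: np.ndarray       # len = n_triplet_bins + 1
    log2_enrichment: np.ndarray     # (n_pair_bins, n_triplet_bins); NaN = empty
    n_pairs: np.ndarray             # total pairs per cell
    n_interacting: np.ndarray       # interacting pairs per cell
    overall_fraction: float


def enrichment_grid(pair_score: Sequence[float],
                    triplet_score: Sequence[float],
                    interacting: Sequence[bool],
                    n_pair_bins: int = 10,
                    n_triplet_bins: int = 10,
                    pair_edges: np.ndarray | None = None,
                    triplet_edges: np.ndarray | None = None) -> EnrichmentGrid:
    """log2 enrichment of interacting pairs over a 2-D score grid.

    Each pair contributes its pairwise similarity (partial correlation)
    and its triplet score (max complementarity score over containing
    triplets; pairs in no triplet should be fed the sentinel value that
    sorts below all real scores).  Cells with zero pairs are NaN.
    """
    ps = np.asarray(pair_score, float)
    ts = np.asarray(triplet_score, float)
    inter = np.asarray(interacting, bool)
    if not (len(ps) == len(ts) == len(inter)):
        raise DataError("enrichment_grid: input length mismatch")
    if len(ps) == 0:
        raise DataError("enrichment_grid: no pairs")

    def _edges(vals: np.ndarray, k: int) -> np.ndarray:
        lo, hi = vals.min(), vals.max()
        if lo == hi:
            hi = lo + 1.0
        return np.linspace(lo, hi, k + 1)

    pe = np.asarray(pair_edges, float) if pair_edges is not None \
        else _edges(ps, n_pair_bins)
    te = np.asarray(triplet_edges, float) if triplet_edges is not None \
        else _edges(ts, n_triplet_bins)
    if len(pe) < 3 or len(te) < 3 or np.any(np.diff(pe) <= 0) \
            or np.any(np.diff(te) <= 0):
        raise DataError("enrichment_grid: degenerate binning")

    pi = np.clip(np.searchsorted(pe, ps, side="right") - 1, 0, len(pe) - 2)
    ti = np.clip(np.searchsorted(te, ts, side="right") - 1, 0, len(te) - 2)
    shape = (len(pe) - 1, len(te) - 1)
    n_pairs = np.zeros(shape, dtype=np.int64)
    n_inter = np.zeros(shape, dtype=np.int64)
    np.add.at(n_pairs, (pi, ti), 1)
    np.add.at(n_inter, (pi, ti), inter.astype(np.int64))

    overall = inter.mean()
    if overall == 0:
        raise DataError("enrichment_grid: no interacting pairs")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n_inter / n_pairs
        enr = np.log2(frac / overall)
    enr[n_pairs == 0] = np.nan
    return EnrichmentGrid(pair_edges=pe, triplet_edges=te,
                          log2_enrichment=enr, n_pairs=n_pairs,
                          n_interacting=n_inter, overall_fraction=float(overall))
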