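"""Pair-level profile similarity and the 4-way pair classification.

Similarity is measured on reconstructed evolutionary events rather than
raw presence/absence: each orthologous group gets a single gain (Dollo
parsimony, placed above the last common ancestor of its present species)
and the minimal set of subsequent losses.  Pairs are compared by the
partial correlation of their per-branch event vectors, corrected for a
global per-branch trend, with empirical-percentile cutoffs derived from
a background pair distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import DataError, PhyleticProfile, ProfileMatrix
from .tree import SpeciesTree

CATEGORIES = ("matching", "taxonomic", "subset", "other")


@dataclass(frozen=True)
class PairThresholds:
    """Percentile cutoffs for 'matching' and 'subset' calls.

    A pair qualifies only by *strictly exceeding* the cutoff.
    """

    matching_cutoff: float
    subset_cutoff: float
    percentile: float = 90.0


@dataclass
class PairRecord:
    og_a: str
    og_b: str
    hamming: int
    pcorr: float
    subset_score: int
    eligible: bool
    category: str | None = None


# ---------------------------------------------------------------------------
# elementary measures


def hamming(p: PhyleticProfile, q: PhyleticProfile) -> int:
    """Number of species where presence differs."""
    if p.panel != q.panel:
        raise DataError("hamming: profiles on different panels")
    return int((p.presence != q.presence).sum())


def dollo_gain_loss(p: PhyleticProfile | np.ndarray,
                    tree: SpeciesTree) -> np.ndarray:
    """Single-gain / minimal-loss event vector over tree branches.

    Returns an int8 vector indexed by branch (= node) ID: +1 on the
    branch above the LCA of all present leaves, -1 on every maximal
    branch whose subtree holds no present leaf but descends from the
    gain, 0 elsewhere.
    """
    presence = p.presence if isinstance(p, PhyleticProfile) else np.asarray(p, bool)
    if presence.sum() == 0:
        raise DataError("dollo_gain_loss: all-absent profile")
    masks = tree.subtree_leaf_masks()
    covered = masks @ presence > 0          # subtree holds a present leaf
    gain = tree.lca(presence)
    vec = np.zeros(tree.n_branches, dtype=np.int8)
    vec[gain] = 1
    # losses: uncovered nodes whose parent is covered, within the gain subtree
    for node in range(tree.n_nodes):
        parent = tree.parent[node]
        if parent == -1 or covered[node] or not covered[parent]:
            continue
        if tree.is_ancestor(gain, node):
            vec[node] = -1
    return vec


def gain_loss_matrix(pm: ProfileMatrix, tree: SpeciesTree,
                     og_ids: Sequence[str] | None = None) -> np.ndarray:
    """Stacked (n_ogs, n_branches) Dollo event matrix."""
    ids = list(og_ids) if og_ids is not None else pm.og_ids
    out = np.zeros((len(ids), tree.n_branches), dtype=np.int8)
    for i, og_id in enumerate(ids):
        out[i] = dollo_gain_loss(pm[og_id], tree)
    return out


def global_trend(pm: ProfileMatrix, tree: SpeciesTree) -> np.ndarray:
    """Per-branch sum of gain/loss events over all OGs (float vector)."""
    return gain_loss_matrix(pm, tree).sum(axis=0).astype(float)


def partial_correlation(g_a: np.ndarray, g_b: np.ndarray,
                        trend: np.ndarray) -> tuple[float, bool]:
    """Pearson correlation of two event vectors, partialled on the trend.

    Returns ``(value, degenerate)``; when either vector is perfectly
    correlated with the trend the correction is undefined and the plain
    correlation is returned with ``degenerate=True``.
    """
    g_a = np.asarray(g_a, float)
    g_b = np.asarray(g_b, float)
    trend = np.asarray(trend, float)
    if g_a.shape != g_b.shape or g_a.shape != trend.shape:
        raise DataError("partial_correlation: branch index mismatch")
    if g_a.std() == 0 or g_b.std() == 0:
        raise DataError("partial_correlation: zero-variance event vector")

    def _pearson(x: np.ndarray, y: np.ndarray) -> float:
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_ab = _pearson(g_a, g_b)
    r_ag = _pearson(g_a, trend)
    r_bg = _pearson(g_b, trend)
    denom_sq = (1.0 - r_ag ** 2) * (1.0 - r_bg ** 2)
    if denom_sq <= 0.0:
        return r_ab, True
    return (r_ab - r_ag * r_bg) / np.sqrt(denom_sq), False


def subset_score(p: PhyleticProfile, q: PhyleticProfile) -> int:
    """Support for one profile being contained in the other.

    With A the more widespread profile (ties broken by lexicographic
    og_id), the score is #{A present without B} - #{B present without A}.
    """
    if p.panel != q.panel:
        raise DataError("subset_score: profiles on different panels")
    if p.n_present > q.n_present:
        a, b = p, q
    elif q.n_present > p.n_present:
        a, b = q, p
    else:
        a, b = (p, q) if p.og_id <= q.og_id else (q, p)
    pa, pb = a.presence, b.presence
    return int((pa & ~pb).sum()) - int((pb & ~pa).sum())


def taxonomic_subset(p: PhyleticProfile, q: PhyleticProfile,
                     tree: SpeciesTree) -> bool:
    """True iff one profile spans a strictly narrower clade.

    Operationalized as: the species sets overlap, and the LCA of one
    profile's present species is a strict descendant of the other's.
    """
    pa, pb = p.presence, q.presence
    if not (pa & pb).any():
        return False
    lca_p = tree.lca(pa)
    lca_q = tree.lca(pb)
    if lca_p == lca_q:
        return False
    return tree.is_ancestor(lca_p, lca_q) or tree.is_ancestor(lca_q, lca_p)


# ---------------------------------------------------------------------------
# thresholds and classification


def nearest_rank_percentile(values: Sequence[float], percentile: float) -> float:
    """Classic nearest-rank empirical percentile (1-based rank ceil(p/100*n))."""
    arr = np.sort(np.asarray(values, float))
    n = len(arr)
    if n == 0:
        raise DataError("empty value list")
    rank = int(np.ceil(percentile / 100.0 * n))
    rank = min(max(rank, 1), n)
    return float(arr[rank - 1])


def background_thresholds(bg_pcorr: Sequence[float],
                          bg_subset: Sequence[float],
                          percentile: float = 90.0) -> PairThresholds:
    """Empirical percentile cutoffs from background pair score lists."""
    if len(bg_pcorr) < 20 or len(bg_subset) < 20:
        raise DataError("background_thresholds: need at least 20 background values")
    return PairThresholds(
        matching_cutoff=nearest_rank_percentile(bg_pcorr, percentile),
        subset_cutoff=nearest_rank_percentile(bg_subset, percentile),
        percentile=percentile,
    )


def is_eligible(p: PhyleticProfile, q: PhyleticProfile) -> bool:
    """At least one of the two genes present in at least half of all species."""
    half = int(np.ceil(p.panel.n / 2))
    return p.n_present >= half or q.n_present >= half


def classify_pair(p: PhyleticProfile, q: PhyleticProfile,
                  pcorr: float, sscore: int,
                  thresholds: PairThresholds,
                  tree: SpeciesTree) -> str:
    """Assign one of matching / taxonomic / subset / other.

    Precedence: matching first; then the taxonomic-subset test, which
    preempts a plain subset call; then subset; everything else 'other'.
    Only eligible pairs may be classified.
    """
    if not is_eligible(p, q):
        raise DataError("classify_pair: ineligible pair (half-of-species filter)")
    if pcorr > thresholds.matching_cutoff:
        return "matching"
    if taxonomic_subset(p, q, tree):
        return "taxonomic"
    if sscore > thresholds.subset_cutoff:
        return "subset"
    return "other"


# ---------------------------------------------------------------------------
# cohort-level driver


def classify_pairs(pm: ProfileMatrix, tree: SpeciesTree,
                   pairs: Iterable[tuple[str, str]],
                   background_nodes: Sequence[str] | None = None,
                   percentile: float = 90.0,
                   max_background: int = 20000,
                   seed: int = 0) -> tuple[list[PairRecord], PairThresholds]:
    """Classify a set of OG pairs against an empirical background.

    ``background_nodes`` are the OGs admitted to the background pair
    universe (default: every OG appearing in ``pairs``); background
    pairs are all unordered combinations, subsampled to
    ``max_background`` with the given seed when larger.
    """
    pairs = [tuple(sorted(p)) for p in pairs]
    if background_nodes is None:
        background_nodes = sorted({og for pair in pairs for og in pair})
    background_nodes = [og for og in background_nodes if og in pm]
    if len(background_nodes) < 3:
        raise DataError("classify_pairs: too few background OGs")

    events = gain_loss_matrix(pm, tree)
    ev_index = {og: i for i, og in enumerate(pm.og_ids)}
    trend = events.sum(axis=0).astype(float)

    rng = np.random.default_rng(seed)
    n_bg = len(background_nodes)
    all_bg = n_bg * (n_bg - 1) // 2
    if all_bg <= max_background:
        bg_pairs = [(background_nodes[i], background_nodes[j])
                    for i in range(n_bg) for j in range(i + 1, n_bg)]
    else:
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < max_background:
            i, j = rng.integers(0, n_bg, size=2)
            if i != j:
                chosen.add((min(i, j), max(i, j)))
        bg_pairs = [(background_nodes[i], background_nodes[j])
                    for i, j in sorted(chosen)]

    bg_pcorr = []
    bg_subset = []
    for a, b in bg_pairs:
        r, _ = partial_correlation(events[ev_index[a]], events[ev_index[b]], trend)
        bg_pcorr.append(r)
        bg_subset.append(subset_score(pm[a], pm[b]))
    thresholds = background_thresholds(bg_pcorr, bg_subset, percentile)

    records: list[PairRecord] = []
    for a, b in pairs:
        p, q = pm[a], pm[b]
        r, _ = partial_correlation(events[ev_index[a]], events[ev_index[b]], trend)
        ss = subset_score(p, q)
        rec = PairRecord(og_a=a, og_b=b, hamming=hamming(p, q),
                         pcorr=r, subset_score=ss,
                         eligible=is_eligible(p, q))
        if rec.eligible:
            rec.category = classify_pair(p, q, r, ss, thresholds, tree)
        records.append(rec)
    return records, thresholds
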