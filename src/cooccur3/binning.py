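"""Equal-count binning of scored triplets and triangle-type trends."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .model import DataError, InteractionNetwork
from .triplets import TripletRecord

BIN_TYPES = ("open", "open2A", "open_taxsubset", "closed", "none")


@dataclass
class BinSummary:
    bin_index: int                      # 1 = lowest scores
    score_min: int
    score_max: int
    n: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def fractions(self) -> dict[str, float]:
        if self.n == 0:
            return {t: float("nan") for t in self.counts}
        return {t: c / self.n for t, c in self.counts.items()}


def sample_noninteracting(net: InteractionNetwork, n: int,
                          seed: int) -> list[tuple[str, str, str]]:
    """Uniform sample of ``n`` distinct node triples with no internal edge.

    Small graphs are enumerated exhaustively; if fewer than ``n``
    edge-free triples exist, all of them are returned with a warning.
    Larger graphs use seeded rejection sampling.
    """
    nodes = sorted(net.nodes)
    if len(nodes) < 3:
        raise DataError("sample_noninteracting: need at least 3 nodes")
    rng = np.random.default_rng(seed)
    n_total = len(nodes) * (len(nodes) - 1) * (len(nodes) - 2) // 6
    if n_total <= max(10 * n, 50000):
        all_free = [t for t in combinations(nodes, 3)
                    if not (net.has_edge(t[0], t[1]) or net.has_edge(t[0], t[2])
                            or net.has_edge(t[1], t[2]))]
        if len(all_free) <= n:
            if len(all_free) < n:
                warnings.warn(
                    f"only {len(all_free)} non-interacting triples available "
                    f"(requested {n})", stacklevel=2)
            return all_free
        idx = rng.choice(len(all_free), size=n, replace=False)
        return [all_free[i] for i in sorted(idx)]
    # rejection sampling for large graphs
    chosen: set[tuple[str, str, str]] = set()
    attempts = 0
    max_attempts = 200 * n
    while len(chosen) < n and attempts < max_attempts:
        attempts += 1
        i, j, k = rng.choice(len(nodes), size=3, replace=False)
        t = tuple(sorted((nodes[i], nodes[j], nodes[k])))
        if (net.has_edge(t[0], t[1]) or net.has_edge(t[0], t[2])
                or net.has_edge(t[1], t[2])):
            continue
        chosen.add(t)
    if len(chosen) < n:
        warnings.warn(f"sampled only {len(chosen)} of {n} requested "
                      "non-interacting triples", stacklevel=2)
    return sorted(chosen)


def bin_triplets(records: Sequence[TripletRecord],
                 n_bins: int = 20) -> list[BinSummary]:
    """Sort by score (canonical-ID tiebreak) and split into equal bins.

    Bin 1 holds the lowest scores; bin sizes differ by at most one.
    Type labels are taken from ``record.triangle_type`` and tallied over
    the label set actually present plus the standard types.
    """
    if len(records) < n_bins:
        raise DataError(f"bin_triplets: {len(records)} records < {n_bins} bins")
    ordered = sorted(records, key=lambda r: (r.score, r.key))
    n = len(ordered)
    base, extra = divmod(n, n_bins)
    types = sorted(set(BIN_TYPES) | {r.triangle_type for r in records})
    bins: list[BinSummary] = []
    start = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        chunk = ordered[start:start + size]
        start += size
        counts = {t: 0 for t in types}
        for rec in chunk:
            counts[rec.triangle_type] += 1
        bins.append(BinSummary(
            bin_index=b + 1,
            score_min=chunk[0].score,
            score_max=chunk[-1].score,
            n=len(chunk),
            counts=counts,
        ))
    return bins


def fraction_trend(bins: Sequence[BinSummary],
                   triangle_type: str = "open") -> tuple[float, float]:
    """Spearman correlation of bin index vs. type fraction.

    Open-triangle sub-types: requesting 'open' counts plain open,
    open2A and open_taxsubset variants together only if asked via
    type 'open_all'.  Constant fractions give (nan, nan).
    """
    if len(bins) < 5:
        raise DataError("fraction_trend: need at least 5 bins")
    if triangle_type == "open_all":
        fracs = [sum(b.fractions.get(t, 0.0)
                     for t in ("open", "open2A", "open_taxsubset"))
                 for b in bins]
    else:
        fracs = [b.fractions.get(triangle_type, 0.0) for b in bins]
    if len(set(fracs)) == 1:
        return float("nan"), float("nan")
    idx = np.arange(1, len(bins) + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(idx, fracs)
    return float(rho), float(p)
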