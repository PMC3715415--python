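"""Duplication retention of shared subunits vs. partner proteins.

A gene counts as duplicated when it has in-paralogs (copy count >= 2)
in at least 5 species; only genes that are single-copy in at least 5
species enter the analysis, which suppresses clusters contaminated by
out-paralogs or annotation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import DataError, PhyleticProfile, ProfileMatrix
from .triplets import TripletRecord

MIN_SPECIES = 5


@dataclass(frozen=True)
class DupStatus:
    og_id: str
    n_species_multi: int
    n_species_single: int
    eligible: bool
    duplicated: bool


@dataclass
class DupCategoryStats:
    category: str               # open / open2A / closed / other
    n_triplets: int
    n_a_eligible: int
    n_a_dup: int
    n_bc_eligible: int
    n_bc_dup: int

    @property
    def pct_dup_a(self) -> float:
        return 100.0 * self.n_a_dup / self.n_a_eligible if self.n_a_eligible else float("nan")

    @property
    def pct_dup_bc(self) -> float:
        return 100.0 * self.n_bc_dup / self.n_bc_eligible if self.n_bc_eligible else float("nan")


def dup_status(p: PhyleticProfile) -> DupStatus:
    n_multi = int((p.counts >= 2).sum())
    n_single = int((p.counts == 1).sum())
    eligible = n_single >= MIN_SPECIES
    return DupStatus(
        og_id=p.og_id,
        n_species_multi=n_multi,
        n_species_single=n_single,
        eligible=eligible,
        duplicated=bool(eligible and n_multi >= MIN_SPECIES),
    )


def dup_rates_by_category(triplets: Sequence[TripletRecord],
                          pm: ProfileMatrix,
                          per_occurrence: bool = True,
                          yates: bool = False,
                          ) -> tuple[list[DupCategoryStats], float]:
    """Duplication percentages per triangle category, plus the A-vs-B/C
    chi-square p for open triangles.

    Open triangles (plain and duplicated-A) keep the central gene A
    separate from the partners; closed triangles and non-interacting
    triplets have no central gene, so all three members are pooled into
    the B/C column.  By default every triangle occurrence counts
    (an OG appearing in many triangles is counted each time); set
    ``per_occurrence=False`` to count unique OGs per role instead.
    """
    status = {og: dup_status(pm[og]) for og in pm.og_ids}

    def _cat(t: TripletRecord) -> str:
        if t.triangle_type in ("open", "open_taxsubset"):
            return "open"
        if t.triangle_type == "open2A":
            return "open2A"
        if t.triangle_type == "closed":
            return "closed"
        return "other"

    buckets: dict[str, dict[str, object]] = {}
    for t in triplets:
        for og in (t.og_a, t.og_b, t.og_c):
            if og not in status:
                raise DataError(f"dup_rates_by_category: no profile for {og!r}")
        cat = _cat(t)
        bk = buckets.setdefault(cat, {"n": 0, "a": [], "bc": []})
        bk["n"] += 1
        if cat in ("open", "open2A"):
            bk["a"].append(t.og_a)
            bk["bc"].extend((t.og_b, t.og_c))
        else:
            bk["bc"].extend((t.og_a, t.og_b, t.og_c))

    results: list[DupCategoryStats] = []
    for cat in ("open", "open2A", "closed", "other"):
        if cat not in buckets:
            continue
        bk = buckets[cat]
        a_occ = bk["a"] if per_occurrence else sorted(set(bk["a"]))
        bc_occ = bk["bc"] if per_occurrence else sorted(set(bk["bc"]))
        a_el = [og for og in a_occ if status[og].eligible]
        bc_el = [og for og in bc_occ if status[og].eligible]
        results.append(DupCategoryStats(
            category=cat,
            n_triplets=bk["n"],
            n_a_eligible=len(a_el),
            n_a_dup=sum(status[og].duplicated for og in a_el),
            n_bc_eligible=len(bc_el),
            n_bc_dup=sum(status[og].duplicated for og in bc_el),
        ))

    p_value = float("nan")
    open_stats = [r for r in results if r.category == "open"]
    if open_stats:
        r = open_stats[0]
        if r.n_a_eligible and r.n_bc_eligible:
            table = np.array([
                [r.n_a_dup, r.n_a_eligible - r.n_a_dup],
                [r.n_bc_dup, r.n_bc_eligible - r.n_bc_dup],
            ])
            if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
                _, p_value, _, _ = stats.chi2_contingency(table, correction=yates)
                p_value = float(p_value)
            else:
                p_value = 1.0
    return results, p_value
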