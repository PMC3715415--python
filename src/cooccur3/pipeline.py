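"""End-to-end orchestration: networks -> pairs -> triplets -> reports.

Every stage is a pure function elsewhere; this module wires them
together, applies the central-gene filter at the cohort level, and
produces one JSON-serializable report containing the category pie,
bin summaries, the pair/triplet cross-tab, the enrichment grid, and
the duplication table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import binning, duplication, integration, network, pairwise, triplets
from .model import (ComplexSet, DataError, InteractionNetwork, OrthologMap,
                    ProfileMatrix)
from .tree import SpeciesTree

logger = logging.getLogger("cooccur3")

#: sentinel triplet score for pairs that sit in no scored triplet
NO_TRIPLET_SCORE = -(10 ** 6)


@dataclass
class RunConfig:
    tree: str = ""
    profiles: str = ""
    clusters: str = ""
    complexes: str = ""
    pairs: str = ""
    og_map: str = ""
    percentile: float = 90.0
    n_bins: int = 20
    noninteracting_sample: int = 100000
    max_background: int = 20000
    seed: int = 0
    out_dir: str = "cooccur3_out"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def build_triplet_records(pm: ProfileMatrix, tree: SpeciesTree,
                          net: InteractionNetwork,
                          n_noninteracting: int = 0,
                          seed: int = 0) -> list[triplets.TripletRecord]:
    """Assemble and score the triplet universe from an OG-level network.

    Open triangles require the central gene to pass the half-of-species
    filter; open triangles whose B or C is a taxonomic subset of A are
    labelled 'open_taxsubset'.  Closed triangles and sampled
    non-interacting triples have no distinguished center, so they are
    scored with the best-scoring eligible center (and skipped when no
    member passes the filter).
    """
    central = {og for og in net.nodes
               if og in pm and triplets.central_filter(pm[og])}
    records: list[triplets.TripletRecord] = []
    seen: set[frozenset[str]] = set()

    for a, b, c in triplets.open_triangles(net, central_ogs=central):
        if b not in pm or c not in pm:
            continue
        comp = triplets.complementarity_score(pm[a], pm[b], pm[c])
        ttype = triplets.triangle_type(a, b, c, net)
        if ttype == "open" and (
                pairwise.taxonomic_subset(pm[b], pm[a], tree)
                or pairwise.taxonomic_subset(pm[c], pm[a], tree)):
            ttype = "open_taxsubset"
        records.append(triplets.TripletRecord(
            og_a=a, og_b=b, og_c=c, triangle_type=ttype,
            n_good_b=comp.n_good_b, n_good_c=comp.n_good_c,
            n_bad=comp.n_bad, score=comp.score))
        seen.add(frozenset((a, b, c)))

    def _best_center(trio: tuple[str, str, str],
                     ttype: str) -> triplets.TripletRecord | None:
        best = None
        for a in trio:
            if a not in central:
                continue
            b, c = [x for x in trio if x != a]
            comp = triplets.complementarity_score(pm[a], pm[b], pm[c])
            if best is None or comp.score > best.score:
                best = triplets.TripletRecord(
                    og_a=a, og_b=b, og_c=c, triangle_type=ttype,
                    n_good_b=comp.n_good_b, n_good_c=comp.n_good_c,
                    n_bad=comp.n_bad, score=comp.score)
        return best

    for trio in triplets.closed_triangles(net):
        if any(og not in pm for og in trio):
            continue
        rec = _best_center(trio, "closed")
        if rec is not None:
            records.append(rec)
            seen.add(frozenset(trio))

    if n_noninteracting > 0:
        for trio in binning.sample_noninteracting(net, n_noninteracting, seed):
            if any(og not in pm for og in trio) or frozenset(trio) in seen:
                continue
            rec = _best_center(trio, "none")
            if rec is not None:
                records.append(rec)
    return records


def pair_triplet_scores(records: Sequence[triplets.TripletRecord],
                        ) -> dict[tuple[str, str], int]:
    """Max complementarity score over triplets containing each A-side pair."""
    out: dict[tuple[str, str], int] = {}
    for t in records:
        for pair in ((t.og_a, t.og_b), (t.og_a, t.og_c)):
            key = tuple(sorted(pair))
            if key not in out or t.score > out[key]:
                out[key] = t.score
    return out


def run_all(pm: ProfileMatrix, tree: SpeciesTree,
            protein_net: InteractionNetwork, om: OrthologMap,
            cs: ComplexSet | None = None,
            config: RunConfig | None = None) -> dict[str, Any]:
    """Execute the full analysis and return the JSON-ready report."""
    cfg = config or RunConfig()
    report: dict[str, Any] = {"config": {
        "percentile": cfg.percentile, "n_bins": cfg.n_bins,
        "noninteracting_sample": cfg.noninteracting_sample,
        "seed": cfg.seed,
    }}

    def _stage(name: str):
        logger.info("stage: %s", name)

    try:
        _stage("network")
        removed: list[str] = []
        if cs is not None:
            cs, removed = network.remove_covered_complexes(cs)
            protein_net = network.complexes_to_pairs(cs)
        og_net = network.project_to_ogs(protein_net, om)
        report["network"] = {
            "removed_complexes": removed,
            "protein_level": network.network_stats(protein_net, cs).to_dict(),
            "og_level": network.network_stats(og_net, cs).to_dict(),
            "intra_og_edges": og_net.intra_og_edges,
        }
    except Exception as exc:
        raise DataError(f"[network] {exc}") from exc

    try:
        _stage("pairwise")
        og_pairs = [e for e in og_net.edges() if e[0] in pm and e[1] in pm]
        bg_nodes = [n for n in og_net.nodes if n in pm]
        if len(bg_nodes) * (len(bg_nodes) - 1) // 2 < 20:
            # tiny networks cannot provide a percentile background on
            # their own; fall back to the whole profile matrix
            logger.info("background widened to all %d profiled OGs", len(pm))
            bg_nodes = pm.og_ids
        pair_records, thresholds = pairwise.classify_pairs(
            pm, tree, og_pairs,
            background_nodes=bg_nodes,
            percentile=cfg.percentile, max_background=cfg.max_background,
            seed=cfg.seed)
        n_eligible = sum(r.eligible for r in pair_records)
        pie = {c: sum(r.category == c for r in pair_records)
               for c in pairwise.CATEGORIES}
        report["pairs"] = {
            "n_pairs": len(pair_records),
            "n_eligible": n_eligible,
            "thresholds": {"matching": thresholds.matching_cutoff,
                           "subset": thresholds.subset_cutoff,
                           "percentile": thresholds.percentile},
            "category_counts": pie,
            "category_fractions": {
                c: (v / n_eligible if n_eligible else float("nan"))
                for c, v in pie.items()},
        }
        logger.info("thresholds: matching>%.4f subset>%s (percentile %s)",
                    thresholds.matching_cutoff, thresholds.subset_cutoff,
                    cfg.percentile)
    except Exception as exc:
        raise DataError(f"[pairwise] {exc}") from exc

    try:
        _stage("triplets")
        trip_records = build_triplet_records(
            pm, tree, og_net, n_noninteracting=cfg.noninteracting_sample,
            seed=cfg.seed)
        type_counts: dict[str, int] = {}
        for t in trip_records:
            type_counts[t.triangle_type] = type_counts.get(t.triangle_type, 0) + 1
        report["triplets"] = {
            "n_records": len(trip_records),
            "type_counts": type_counts,
            "worked_examples": [
                {"og_a": t.og_a, "og_b": t.og_b, "og_c": t.og_c,
                 "type": t.triangle_type, "n_good_b": t.n_good_b,
                 "n_good_c": t.n_good_c, "n_bad": t.n_bad, "score": t.score}
                for t in sorted(trip_records, key=lambda r: -r.score)[:20]],
        }
    except Exception as exc:
        raise DataError(f"[triplets] {exc}") from exc

    try:
        _stage("bins")
        if len(trip_records) >= cfg.n_bins:
            bins = binning.bin_triplets(trip_records, cfg.n_bins)
            if cfg.n_bins >= 5:
                rho, p = binning.fraction_trend(bins, "open_all")
            else:
                rho = p = float("nan")
            report["bins"] = {
                "n_bins": cfg.n_bins,
                "open_fraction_trend": {"rho": rho, "p": p},
                "summaries": [
                    {"bin": b.bin_index, "score_min": b.score_min,
                     "score_max": b.score_max, "n": b.n, "counts": b.counts}
                    for b in bins],
            }
        else:
            report["bins"] = {"n_bins": cfg.n_bins, "skipped":
                              "fewer triplets than bins"}
    except Exception as exc:
        raise DataError(f"[bins] {exc}") from exc

    try:
        _stage("integration")
        ct = integration.positive_triplet_pairs(trip_records, pair_records)
        over = {}
        for cat in pairwise.CATEGORIES:
            if ct.total.get(cat, 0) > 0 and ct.n_in_triplet > 0:
                excess, p = integration.overrepresentation(ct, cat)
                over[cat] = {"excess_percent": excess, "p": p}
        tscores = pair_triplet_scores(trip_records)
        interacting_keys = {tuple(sorted((r.og_a, r.og_b)))
                            for r in pair_records}
        ps, ts, inter = [], [], []
        for rec in pair_records:
            if not rec.eligible:
                continue
            ps.append(rec.pcorr)
            ts.append(tscores.get(tuple(sorted((rec.og_a, rec.og_b))),
                                  NO_TRIPLET_SCORE))
            inter.append(True)
        # non-interacting background pairs complete the grid universe
        bg_ogs = [n for n in og_net.nodes if n in pm]
        rng = np.random.default_rng(cfg.seed)
        events = pairwise.gain_loss_matrix(pm, tree)
        ev_index = {og: i for i, og in enumerate(pm.og_ids)}
        trend = events.sum(axis=0).astype(float)
        n_bg_grid = min(cfg.max_background, 5000)
        for _ in range(n_bg_grid):
            i, j = rng.integers(0, len(bg_ogs), size=2)
            if i == j:
                continue
            a, b = sorted((bg_ogs[i], bg_ogs[j]))
            if (a, b) in interacting_keys:
                continue
            r, _deg = pairwise.partial_correlation(
                events[ev_index[a]], events[ev_index[b]], trend)
            ps.append(r)
            ts.append(tscores.get((a, b), NO_TRIPLET_SCORE))
            inter.append(False)
        grid_block: dict[str, Any]
        if len(ps) >= 50 and any(inter) and not all(inter):
            real_ts = [t for t in ts if t > NO_TRIPLET_SCORE]
            t_lo = (min(real_ts) - 1) if real_ts else -1
            t_hi = (max(real_ts) + 1) if real_ts else 1
            t_edges = np.concatenate(
                [[NO_TRIPLET_SCORE - 1], np.linspace(t_lo, t_hi, 8)])
            grid = integration.enrichment_grid(
                ps, ts, inter, n_pair_bins=8, triplet_edges=t_edges)
            grid_block = {
                "pair_edges": grid.pair_edges.tolist(),
                "triplet_edges": grid.triplet_edges.tolist(),
                "log2_enrichment": [
                    [None if not np.isfinite(v) else float(v) for v in row]
                    for row in grid.log2_enrichment],
                "overall_fraction": grid.overall_fraction,
            }
        else:
            grid_block = {"skipped": "too few pairs for a grid"}
        report["crosstab"] = {
            "total": ct.total, "in_positive_triplet": ct.in_triplet,
            "overrepresentation": over,
        }
        report["grid"] = grid_block
    except Exception as exc:
        raise DataError(f"[integration] {exc}") from exc

    try:
        _stage("duplication")
        dup_stats, dup_p = duplication.dup_rates_by_category(trip_records, pm)
        dup_unique, _ = duplication.dup_rates_by_category(
            trip_records, pm, per_occurrence=False)
        report["duplication"] = {
            "chi2_p_open_A_vs_BC": dup_p,
            "per_occurrence": [_dup_row(r) for r in dup_stats],
            "per_unique_og": [_dup_row(r) for r in dup_unique],
        }
    except Exception as exc:
        raise DataError(f"[duplication] {exc}") from exc

    return report


def _dup_row(r: duplication.DupCategoryStats) -> dict:
    return {"category": r.category, "n_triplets": r.n_triplets,
            "pct_dup_A": r.pct_dup_a, "pct_dup_BC": r.pct_dup_bc,
            "n_A_eligible": r.n_a_eligible, "n_BC_eligible": r.n_bc_eligible}


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default),
                          encoding="utf-8")


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
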