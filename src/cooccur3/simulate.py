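"""Synthetic species trees, gene-content evolution, and planted complexes.

Gene families evolve by a single origin (root-biased, with a tail of
late inventions), per-branch Bernoulli losses, and per-branch Bernoulli
duplications that raise copy counts in all descendant species.  Planted
complex architectures reproduce the shared-subunit scenario: a broadly
retained central gene A belongs to two complexes whose private members
B and C are lost in complementary species sets.

Truth labels are returned as separate structures (and written to a
separate file by the CLI) so that analysis code cannot accidentally
consume them.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np

from .model import (ComplexSet, DataError, InteractionNetwork, OrthologMap,
                    PhyleticProfile, ProfileMatrix, SpeciesPanel)
from .tree import SpeciesTree


@dataclass
class SimulationConfig:
    n_species: int = 51
    n_ogs: int = 2000
    root_origin_prob: float = 0.7
    loss_prob: float = 0.04
    dup_prob: float = 0.012
    n_architectures: int = 50          # planted shared-subunit triangles
    shared_subunit_fraction: float = 1.0
    complementary_strength: float = 1.0
    open2a_fraction: float = 0.0       # planted architectures with duplicated A
    a_dup_multiplier: float = 1.0      # duplication boost for A-role genes
    n_noise_closed: int = 0            # random fully connected triples
    n_noise_open: int = 0              # random hub-and-spokes (open, unplanted)
    background_noise: float = 0.0      # per-species presence flip rate
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("root_origin_prob", "loss_prob", "dup_prob",
                     "shared_subunit_fraction", "complementary_strength",
                     "open2a_fraction", "background_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0,1], got {v}")
        if self.n_species < 4:
            raise DataError("n_species must be >= 4")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticTruth:
    og_origin: dict[str, int] = field(default_factory=dict)
    og_losses: dict[str, list[int]] = field(default_factory=dict)
    pair_category: dict[tuple[str, str], str] = field(default_factory=dict)
    architectures: list[dict] = field(default_factory=list)
    dup_class: dict[str, str] = field(default_factory=dict)
    n_regenerated: int = 0


def _species_codes(n: int) -> list[str]:
    """Deterministic 4-letter uppercase codes: SAAA, SAAB, ..."""
    letters = string.ascii_uppercase
    codes = []
    for combo in itertools.product(letters, repeat=3):
        codes.append("S" + "".join(combo))
        if len(codes) == n:
            return codes
    raise DataError("too many species requested")


def simulate_tree(n: int, seed: int | np.random.Generator) -> SpeciesTree:
    """Random rooted bifurcating tree grown by a Yule (pure-birth) process."""
    if n < 4:
        raise DataError("simulate_tree: n must be >= 4")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    parent = [-1, 0, 0]
    children: list[list[int]] = [[1, 2], [], []]
    leaves = [1, 2]
    while len(leaves) < n:
        pick = int(rng.integers(len(leaves)))
        node = leaves.pop(pick)
        left, right = len(parent), len(parent) + 1
        parent.extend([node, node])
        children[node] = [left, right]
        children.extend([[], []])
        leaves.extend([left, right])
    codes = _species_codes(n)
    leaf_name = {node: codes[i] for i, node in enumerate(sorted(leaves))}
    tree = SpeciesTree(parent=parent, children=children, leaf_name=leaf_name)
    tree.set_leaf_order(codes)
    return tree


def _descendants_preorder(tree: SpeciesTree, node: int) -> list[int]:
    out = []
    stack = [node]
    while stack:
        v = stack.pop()
        out.append(v)
        stack.extend(tree.children[v])
    return out


def _evolve_presence(tree: SpeciesTree, origin: int, loss_prob: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, list[int]]:
    """Propagate presence tip-ward from the origin with per-branch loss."""
    leaf_col = {node: i for i, node in enumerate(tree.leaf_nodes)}
    present_nodes: dict[int, bool] = {origin: True}
    losses: list[int] = []
    for v in _descendants_preorder(tree, origin):
        if v == origin:
            continue
        if not present_nodes[tree.parent[v]]:
            present_nodes[v] = False
            continue
        lost = rng.random() < loss_prob
        present_nodes[v] = not lost
        if lost:
            losses.append(v)
    presence = np.zeros(len(leaf_col), dtype=bool)
    for node, ok in present_nodes.items():
        if ok and tree.is_leaf(node):
            presence[leaf_col[node]] = True
    return presence, losses


def _counts_from_presence(tree: SpeciesTree, presence: np.ndarray,
                          dup_prob: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Copy counts: 1 + duplication events on the root-to-leaf path.

    Duplications are per-branch Bernoulli events inherited by all
    descendant species, so in-paralog counts are clade-correlated.
    """
    leaf_col = {node: i for i, node in enumerate(tree.leaf_nodes)}
    extra: dict[int, int] = {tree.root: 0}
    order = [v for v in _descendants_preorder(tree, tree.root)]
    for v in order:
        if v == tree.root:
            continue
        extra[v] = extra[tree.parent[v]] + (1 if rng.random() < dup_prob else 0)
    counts = np.zeros(len(leaf_col), dtype=np.int64)
    for node, col in leaf_col.items():
        if presence[col]:
            counts[col] = 1 + extra[node]
    return counts


def simulate_gene_content(cfg: SimulationConfig,
                          tree: SpeciesTree | None = None,
                          rng: np.random.Generator | None = None,
                          og_prefix: str = "OG",
                          ) -> tuple[SpeciesTree, ProfileMatrix, SyntheticTruth]:
    """Simulate a copy-number profile matrix on a (given or fresh) tree."""
    rng = rng if rng is not None else cfg.rng()
    if tree is None:
        tree = simulate_tree(cfg.n_species, rng)
    panel = SpeciesPanel.from_iterable(tree.leaves)
    internal = [v for v in range(tree.n_nodes) if not tree.is_leaf(v)]
    pm = ProfileMatrix(panel)
    truth = SyntheticTruth()
    width = len(str(max(cfg.n_ogs, 1)))
    i = 0
    consecutive_rejects = 0
    while len(pm) < cfg.n_ogs:
        if consecutive_rejects > 1000:
            raise DataError(
                "simulate_gene_content: degenerate config, every simulated "
                "OG is lost everywhere (loss_prob too close to 1?)")
        og_id = f"{og_prefix}{i:0{width}d}"
        if rng.random() < cfg.root_origin_prob:
            origin = tree.root
        else:
            origin = internal[int(rng.integers(len(internal)))]
        presence, losses = _evolve_presence(tree, origin, cfg.loss_prob, rng)
        if cfg.background_noise > 0:
            flips = rng.random(panel.n) < cfg.background_noise
            presence = presence ^ flips
        if not presence.any():
            truth.n_regenerated += 1
            consecutive_rejects += 1
            continue
        consecutive_rejects = 0
        counts = _counts_from_presence(tree, presence, cfg.dup_prob, rng)
        pm.add(PhyleticProfile(og_id, counts, panel))
        truth.og_origin[og_id] = origin
        truth.og_losses[og_id] = losses
        truth.dup_class[og_id] = "base"
        i += 1
    return tree, pm, truth


# ---------------------------------------------------------------------------
# planted complex architectures


def plant_complexes(cfg: SimulationConfig, tree: SpeciesTree,
                    pm: ProfileMatrix, truth: SyntheticTruth,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[ComplexSet, InteractionNetwork, OrthologMap]:
    """Add shared-subunit architectures on top of a simulated matrix.

    Each architecture picks a broadly present OG as the shared subunit
    A and creates two partner OGs B and C whose presence is A's minus
    complementary loss sets, then emits the two complexes {A,B} and
    {A,C}.  Architecture strength (the complementary-loss intensity)
    is drawn per architecture so scores span a range, as in real data.
    Noise triangles and the protein-level network are also produced.
    """
    rng = rng if rng is not None else cfg.rng()
    panel = pm.panel
    half = int(np.ceil(panel.n / 2))
    broad = [og for og in pm.og_ids
             if pm[og].n_present >= max(half + 2, int(0.75 * panel.n))]
    rng.shuffle(broad)
    n_arch = cfg.n_architectures
    if len(broad) < n_arch + 3 * (cfg.n_noise_closed + cfg.n_noise_open):
        raise DataError("plant_complexes: not enough broadly present OGs")

    cs = ComplexSet()
    om_mapping: dict[str, str] = {}
    used = iter(broad)
    width = len(str(max(n_arch, 1)))

    def _protein(og: str, k: int = 1) -> str:
        pid = f"{og}.p{k}"
        om_mapping[pid] = og
        return pid

    a_dup = cfg.dup_prob * cfg.a_dup_multiplier
    for k in range(n_arch):
        og_a = next(used)
        shared = rng.random() < cfg.shared_subunit_fraction
        strength = float(rng.uniform(0.05, 1.0)) * cfg.complementary_strength
        a_pres = pm[og_a].presence.copy()
        idx_a = np.flatnonzero(a_pres)
        # partition A-present species: lose-B / lose-C / keep-both / lose-both
        p_lose = 0.42 * strength if shared else 0.0
        p_bad = 0.02 + 0.10 * (1.0 - strength)
        u = rng.random(len(idx_a))
        lose_b = idx_a[u < p_lose]
        lose_c = idx_a[(u >= p_lose) & (u < 2 * p_lose)]
        bad = idx_a[(u >= 2 * p_lose) & (u < 2 * p_lose + p_bad)]
        b_pres = a_pres.copy()
        b_pres[lose_b] = False
        b_pres[bad] = False
        c_pres = a_pres.copy()
        c_pres[lose_c] = False
        c_pres[bad] = False
        og_b, og_c = f"ARCH{k:0{width}d}B", f"ARCH{k:0{width}d}C"
        for og, pres in ((og_b, b_pres), (og_c, c_pres)):
            if not pres.any():
                pres[idx_a[0]] = True
            counts = _counts_from_presence(tree, pres, cfg.dup_prob, rng)
            pm.add(PhyleticProfile(og, counts, panel))
            truth.dup_class[og] = "partner"
        # refresh A's copy counts with its duplication propensity
        a_counts = _counts_from_presence(tree, a_pres, a_dup, rng)
        pm.replace(PhyleticProfile(og_a, a_counts, panel))
        truth.dup_class[og_a] = "shared_subunit"

        two_a = rng.random() < cfg.open2a_fraction
        if two_a:
            # force in-paralogs so the duplicated-A call is observable
            a2 = np.where(a_pres, np.maximum(pm[og_a].counts, 2), 0)
            pm.replace(PhyleticProfile(og_a, a2, panel))
        pa1 = _protein(og_a, 1)
        pa2 = _protein(og_a, 2) if two_a else pa1
        cs.add(f"CPX{k:0{width}d}B", [pa1, _protein(og_b)])
        cs.add(f"CPX{k:0{width}d}C", [pa2, _protein(og_c)])
        truth.architectures.append({
            "label": "shared-subunit" if shared else "independent",
            "og_a": og_a, "og_b": min(og_b, og_c), "og_c": max(og_b, og_c),
            "strength": strength, "open2a": two_a,
        })

    for k in range(cfg.n_noise_closed):
        ogs = [next(used), next(used), next(used)]
        cs.add(f"NOISEK{k}", [_protein(og) for og in ogs])
        truth.architectures.append({
            "label": "closed-complex", "og_a": ogs[0],
            "og_b": min(ogs[1:]), "og_c": max(ogs[1:]),
            "strength": 0.0, "open2a": False,
        })
    for k in range(cfg.n_noise_open):
        hub, s1, s2 = next(used), next(used), next(used)
        cs.add(f"NOISEO{k}A", [_protein(hub), _protein(s1)])
        cs.add(f"NOISEO{k}B", [_protein(hub), _protein(s2)])
        truth.architectures.append({
            "label": "independent", "og_a": hub,
            "og_b": min(s1, s2), "og_c": max(s1, s2),
            "strength": 0.0, "open2a": False,
        })

    net = InteractionNetwork(level="protein")
    from itertools import combinations
    for cid in cs:
        for x, y in combinations(sorted(cs[cid]), 2):
            net.add_edge(x, y)
    return cs, net, OrthologMap(om_mapping)


# ---------------------------------------------------------------------------
# planted pair cohorts (for classification recovery tests)


def plant_pair_cohort(tree: SpeciesTree, n_per_category: int,
                      seed: int | np.random.Generator,
                      n_background: int = 200,
                      loss_prob: float = 0.05,
                      ) -> tuple[ProfileMatrix, list[tuple[str, str]], dict]:
    """Profile pairs with known matching/taxonomic/subset/other labels.

    matching: shared origin and shared loss events (one optional extra
    private loss).  taxonomic: broad gene plus a late invention nested
    in a strict subclade.  subset: scattered losses carving a proper
    subset whose span still reaches the root.  other: two independent
    broad genes.  Background OGs provide the threshold distribution.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    panel = SpeciesPanel.from_iterable(tree.leaves)
    pm = ProfileMatrix(panel)
    masks = tree.subtree_leaf_masks()
    n = panel.n
    half = int(np.ceil(n / 2))
    truth: dict[tuple[str, str], str] = {}
    pairs: list[tuple[str, str]] = []

    def _add(og: str, presence: np.ndarray) -> None:
        pm.add(PhyleticProfile(og, presence.astype(np.int64), panel))

    def _spans_root(pres: np.ndarray) -> bool:
        kids = tree.children[tree.root]
        return all((masks[c] & pres).any() for c in kids)

    def _broad(min_present: int = half + 3) -> tuple[np.ndarray, set[int]]:
        while True:
            pres, losses = _evolve_presence(tree, tree.root, loss_prob, rng)
            if pres.sum() >= min_present and _spans_root(pres):
                return pres, set(losses)

    clades = [v for v in range(tree.n_nodes)
              if v != tree.root and 3 <= masks[v].sum() <= int(0.5 * n)]

    for i in range(n_per_category):
        # matching: shared origin and shared loss events, tiny divergence
        pa, _ = _broad()
        pb = pa.copy()
        if rng.random() < 0.3 and pb.sum() > half + 1:
            drop = rng.choice(np.flatnonzero(pb))
            pb[drop] = False
        _add(f"MATCH{i}A", pa)
        _add(f"MATCH{i}B", pb)
        pairs.append((f"MATCH{i}A", f"MATCH{i}B"))
        truth[(f"MATCH{i}A", f"MATCH{i}B")] = "matching"

        # taxonomic: late invention in a strict subclade, history
        # independent of A's (no shared loss events)
        pa, a_losses = _broad()
        while True:
            clade = clades[int(rng.integers(len(clades)))]
            pb_arr, b_losses = _evolve_presence(tree, clade, loss_prob, rng)
            if pb_arr.any() and (pa & pb_arr).any() \
                    and not (set(b_losses) & a_losses):
                break
        _add(f"TAX{i}A", pa)
        _add(f"TAX{i}B", pb_arr)
        pairs.append((f"TAX{i}A", f"TAX{i}B"))
        truth[(f"TAX{i}A", f"TAX{i}B")] = "taxonomic"

        # subset: sparse proper subset of a ubiquitous gene, spanning
        # the root so the span test does not fire first
        pa = np.ones(n, dtype=bool)
        while True:
            pb = rng.random(n) < 0.08
            if pb.any() and _spans_root(pb):
                break
        _add(f"SUB{i}A", pa)
        _add(f"SUB{i}B", pb)
        pairs.append((f"SUB{i}A", f"SUB{i}B"))
        truth[(f"SUB{i}A", f"SUB{i}B")] = "subset"

        # other: independent histories (disjoint loss branches), both
        # spanning the root, similar breadth
        pa, a_losses = _broad()
        while True:
            pb_arr, b_losses = _evolve_presence(tree, tree.root,
                                                2 * loss_prob, rng)
            if pb_arr.any() and _spans_root(pb_arr) \
                    and not (set(b_losses) & a_losses):
                break
        _add(f"OTH{i}A", pa)
        _add(f"OTH{i}B", pb_arr)
        pairs.append((f"OTH{i}A", f"OTH{i}B"))
        truth[(f"OTH{i}A", f"OTH{i}B")] = "other"

    for j in range(n_background):
        while True:
            origin = tree.root if rng.random() < 0.6 \
                else clades[int(rng.integers(len(clades)))]
            pres, _ = _evolve_presence(tree, origin, loss_prob, rng)
            if pres.any():
                break
        _add(f"BG{j}", pres)
    return pm, pairs, truth
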