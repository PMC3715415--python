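"""Readers and writers for trees, profiles, clusters, complexes, and pairs.

All tabular formats are UTF-8, tab-separated; lines starting with '#'
are ignored.  Profile tables have a header row of species codes and one
row per orthologous group with integer copy counts.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np

from .model import (SPECIES_CODE_RE, ComplexSet, DataError, InteractionNetwork,
                    OrthologMap, PhyleticProfile, ProfileMatrix, SpeciesPanel)
from .tree import SpeciesTree, TreeError


def _read_text(path: str | Path) -> str:
    return Path(path).read_text(encoding="utf-8")


def read_newick(path: str | Path, panel: SpeciesPanel | None = None) -> SpeciesTree:
    """Read a rooted Newick tree; if a panel is given, its leaf set must
    match the panel exactly and leaves are re-ordered to panel order."""
    tree = SpeciesTree.from_newick(_read_text(path))
    if panel is not None:
        if set(tree.leaves) != set(panel.species):
            missing = set(panel.species) - set(tree.leaves)
            extra = set(tree.leaves) - set(panel.species)
            raise TreeError(
                f"tree/panel leaf mismatch (missing={sorted(missing)}, "
                f"extra={sorted(extra)})")
        tree.set_leaf_order(panel.species)
    return tree


def _data_lines(path: str | Path) -> list[list[str]]:
    rows = []
    for raw in _read_text(path).splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def read_profile_matrix(path: str | Path,
                        panel: SpeciesPanel | None = None) -> ProfileMatrix:
    """Read an OG x species copy-count table.

    The header row lists the species codes (first cell is the OG-ID
    column name and is ignored).  When a panel is supplied the header
    must contain exactly the panel species; columns are aligned to
    panel order.
    """
    rows = _data_lines(path)
    if not rows:
        raise DataError(f"empty profile table {path}")
    header = rows[0][1:]
    if panel is None:
        panel = SpeciesPanel.from_iterable(header)
    if set(header) != set(panel.species):
        raise DataError("profile table columns do not match the species panel")
    order = [header.index(s) for s in panel.species]
    matrix = ProfileMatrix(panel)
    for row in rows[1:]:
        og_id, cells = row[0], row[1:]
        if len(cells) != len(header):
            raise DataError(f"row {og_id!r}: expected {len(header)} cells")
        try:
            counts = np.array([int(c) for c in cells], dtype=np.int64)
        except ValueError as exc:
            raise DataError(f"row {og_id!r}: non-integer count") from exc
        matrix.add(PhyleticProfile(og_id, counts[order], panel))
    return matrix


def write_profile_matrix(matrix: ProfileMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("og_id\t" + "\t".join(matrix.panel.species) + "\n")
        for og_id in matrix.og_ids:
            counts = matrix[og_id].counts
            fh.write(og_id + "\t" + "\t".join(str(int(c)) for c in counts) + "\n")


def profiles_from_clusters(cluster_rows: Iterable[tuple[str, str]] | str | Path,
                           panel: SpeciesPanel,
                           species_pattern: re.Pattern = SPECIES_CODE_RE,
                           ) -> tuple[ProfileMatrix, OrthologMap]:
    """Build copy-number profiles from a cluster membership table.

    Rows are (cluster_id, protein_id) pairs; the species is recovered
    from the protein ID prefix.  ``counts[s]`` is the number of member
    proteins from species ``s``.  Returns the matrix together with the
    protein -> OG map implied by the table.
    """
    if isinstance(cluster_rows, (str, Path)):
        rows = [(r[0], r[1]) for r in _data_lines(cluster_rows)]
    else:
        rows = list(cluster_rows)
    if not rows:
        raise DataError("empty cluster table")
    idx = {s: i for i, s in enumerate(panel.species)}
    counts: dict[str, np.ndarray] = {}
    mapping: dict[str, str] = {}
    for cluster_id, protein_id in rows:
        m = species_pattern.match(protein_id)
        if not m:
            raise DataError(
                f"protein id {protein_id!r} has no recognizable species code")
        species = m.group(1)
        if species not in idx:
            raise DataError(
                f"protein id {protein_id!r}: species {species!r} not in panel")
        if cluster_id not in counts:
            counts[cluster_id] = np.zeros(panel.n, dtype=np.int64)
        counts[cluster_id][idx[species]] += 1
        mapping[protein_id] = cluster_id
    matrix = ProfileMatrix(panel)
    for cluster_id, vec in counts.items():
        matrix.add(PhyleticProfile(cluster_id, vec, panel))
    return matrix, OrthologMap(mapping)


def read_complexes(path: str | Path) -> ComplexSet:
    """Read a complex table: complex_id TAB member TAB member ..."""
    rows = _data_lines(path)
    cs = ComplexSet()
    for row in rows:
        if len(row) < 3:
            raise DataError(f"complex row too short: {row!r}")
        cs.add(row[0], row[1:])
    return cs


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid in cs.complex_ids:
            fh.write(cid + "\t" + "\t".join(sorted(cs[cid])) + "\n")


def read_pairs(path: str | Path, level: str = "protein") -> InteractionNetwork:
    """Read a two-column undirected pair list into a simple graph."""
    net = InteractionNetwork(level=level)
    for row in _data_lines(path):
        if len(row) < 2:
            raise DataError(f"pair row too short: {row!r}")
        net.add_edge(row[0], row[1])
    return net


def write_pairs(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(net.edges()):
            fh.write(f"{u}\t{v}\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column protein_id -> og_id table."""
    mapping: dict[str, str] = {}
    for row in _data_lines(path):
        if len(row) < 2:
            raise DataError(f"map row too short: {row!r}")
        mapping[row[0]] = row[1]
    if not mapping:
        raise DataError("empty ortholog map")
    return OrthologMap(mapping)
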