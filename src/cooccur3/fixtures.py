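"""Packaged worked-example data: the TOR and emerin-related triplets.

Two triplets of presence/absence profiles over the 51-species panel,
shipped as plain TSV inside the package.  The TOR triplet (MTOR central,
RPTOR/RICTOR partners) scores -1; the emerin-related triplet (HNRNPK
central, PDCD4/CDC37 partners) scores 8.
"""

from __future__ import annotations

from importlib import resources

from .io import read_profile_matrix
from .model import ProfileMatrix, SpeciesPanel

#: (central og, partner og, partner og)
TRIPLET_SPECS: tuple[tuple[str, str, str], ...] = (
    ("MTOR", "RPTOR", "RICTOR"),
    ("HNRNPK", "PDCD4", "CDC37"),
)


def _data_path(name: str):
    return resources.files("cooccur3.data").joinpath(name)


def table2_fixture() -> tuple[ProfileMatrix, tuple[tuple[str, str, str], ...]]:
    """Load the packaged 6-OG x 51-species worked-example profiles."""
    with resources.as_file(_data_path("tor_emerin_profiles.tsv")) as path:
        matrix = read_profile_matrix(path)
    return matrix, TRIPLET_SPECS


def species_panel_51() -> SpeciesPanel:
    """The 51-species eukaryote panel (4-letter codes, fixed order)."""
    text = _data_path("species_panel_51.tsv").read_text(encoding="utf-8")
    codes = [line.split("\t")[0] for line in text.splitlines()
             if line.strip() and not line.startswith("#")]
    return SpeciesPanel.from_iterable(codes)
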