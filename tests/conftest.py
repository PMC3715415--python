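"""Shared fixtures: small panels, hand-built trees, and generated data."""

from __future__ import annotations

import numpy as np
import pytest

from cooccur3 import (PhyleticProfile, ProfileMatrix, SpeciesPanel,
                      SpeciesTree, table2_fixture)


@pytest.fixture(scope="session")
def panel4() -> SpeciesPanel:
    return SpeciesPanel.from_iterable(["s1", "s2", "s3", "s4"])


@pytest.fixture(scope="session")
def tree4(panel4) -> SpeciesTree:
    """((s1,s2),(s3,s4)) with leaf order fixed to the panel."""
    tree = SpeciesTree.from_newick("((s1,s2),(s3,s4));")
    tree.set_leaf_order(panel4.species)
    return tree


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


def make_profile(og_id: str, presence, panel: SpeciesPanel,
                 counts=None) -> PhyleticProfile:
    if counts is None:
        counts = np.asarray(presence, dtype=np.int64)
    return PhyleticProfile(og_id, np.asarray(counts, dtype=np.int64), panel)


@pytest.fixture
def profile_factory():
    return make_profile
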