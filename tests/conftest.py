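"""Shared fixtures: generated sequence sets and pocket structures."""

from __future__ import annotations

import pytest

from diatomlox import make_group_sequences, make_pocket_fixture
from diatomlox.pocket import Orientation


@pytest.fixture(scope="session")
def seq_fixture():
    """Two members per terminal pattern, seed 1."""
    return make_group_sequences(seed=1, per_group=2)


@pytest.fixture(scope="session")
def family_fixture():
    """Four members per terminal pattern (tree-stage tests)."""
    return make_group_sequences(seed=1, per_group=4)


@pytest.fixture(scope="session")
def pocket_open(tmp_path_factory):
    """20-carbon chain, C10 nearest, head external, glycine gate."""
    fx = make_pocket_fixture(20, 10, Orientation.HEAD_EXTERNAL, "GLY", seed=7)
    path = tmp_path_factory.mktemp("pocket") / "open.pdb"
    fx.write(path)
    return fx, path


@pytest.fixture(scope="session")
def pocket_closed_internal(tmp_path_factory):
    """16-carbon chain, C11 nearest, head internal, alanine gate."""
    fx = make_pocket_fixture(16, 11, Orientation.HEAD_INTERNAL, "ALA", seed=7)
    path = tmp_path_factory.mktemp("pocket") / "closed.pdb"
    fx.write(path)
    return fx, path
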