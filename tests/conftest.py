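"""Shared fixtures: a tiny deterministic panel and helpers to put it on disk."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

from ampcall import (
    PanelConfig,
    build_tile_index,
    make_panel,
)
from ampcall.reads import OrientedInsert
from ampcall.simulate import write_panel


@pytest.fixture(scope="session")
def small_panel():
    return make_panel(PanelConfig(n_tiles=5, insert_len=60, primer_len=15, seed=7))


@pytest.fixture(scope="session")
def small_index(small_panel):
    return build_tile_index(
        small_panel.specs, small_panel.primers, small_panel.reference, 15
    )


@pytest.fixture()
def panel_files(tmp_path, small_panel):
    ref = tmp_path / "ref.fa"
    coords = tmp_path / "coords.tsv"
    seqs = tmp_path / "seqs.tsv"
    write_panel(small_panel, str(ref), str(coords), str(seqs))
    return {"reference": str(ref), "coords": str(coords), "seqs": str(seqs)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)


def make_insert(bases: str, side: str = "left", qual: int = 40) -> OrientedInsert:
    return OrientedInsert(bases=bases, quals=tuple([qual] * len(bases)), side=side)
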