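"""Shared fixtures: tiny deterministic window sets and file helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from psadpr import AMINO_ACIDS, PeptideWindow, WINDOW_LENGTH

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_window(flanks: str = "A" * 40, label: str = "UM", **kw) -> PeptideWindow:
    """Build a 41-mer with 'S' at the center from 40 flank characters."""
    assert len(flanks) == WINDOW_LENGTH - 1
    pep = flanks[:20] + "S" + flanks[20:]
    return PeptideWindow(pep, label=label, **kw)


def random_window(rng: np.random.Generator, label: str = "UM") -> PeptideWindow:
    chars = rng.choice(list(AMINO_ACIDS), size=WINDOW_LENGTH - 1)
    return make_window("".join(chars), label=label)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(
        ">P1 first protein\n"
        "MKT" + "A" * 46 + "S" + "A" * 50 + "\n"
        ">P2\n"
        "SAAAAKRKR" + "C" * 30 + "\n"
    )
    return path
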