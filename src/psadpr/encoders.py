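"""Numeric encodings of 41-mer peptide windows.

Five schemes are supported, each with an exact dimensional contract for the
default window length 41 and sliding-window size 5:

======  ==================================  =========  ========  ===========
name    description                         positions  channels  flat length
======  ==================================  =========  ========  ===========
OH      one-hot over 21 symbols             41         21        861
ZSCALE  five physicochemical descriptors    41         5         205
WE      integer tokens (embedded in-model)  41         1         41 tokens
EAAC    sliding-window residue frequency    37         20        740
EGAAC   sliding-window group frequency      37         5         185
======  ==================================  =========  ========  ===========

The alphabet ordering is fixed: ``ACDEFGHIKLMNPQRSTVWY`` with the padding
symbol ``_`` last (index 20). The padding symbol contributes zero rows to
ZSCALE and is counted toward no residue or group in EAAC/EGAAC.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .windows import ALPHABET, AMINO_ACIDS, PAD, WINDOW_LENGTH, PeptideWindow

#: Default sliding-window size for EAAC/EGAAC.
SLIDING_WINDOW = 5

#: Five physicochemical residue groups: aliphatic, aromatic, positive charge,
#: negative charge, uncharged polar / small.
AA_GROUPS: Mapping[str, str] = {
    "G1": "GAVLMI",
    "G2": "FYW",
    "G3": "KRH",
    "G4": "DE",
    "G5": "STCPNQ",
}

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_GROUP_OF = np.full(len(ALPHABET), -1, dtype=int)
for _g, (_name, _members) in enumerate(AA_GROUPS.items()):
    for _aa in _members:
        _GROUP_OF[_AA_INDEX[_aa]] = _g


@dataclass(frozen=True)
class EncodingScheme:
    """Dimensional contract of one encoding."""

    name: str
    positions: int
    channels: int

    @property
    def flat_length(self) -> int:
        return self.positions * self.channels


def scheme(name: str, length: int = WINDOW_LENGTH, w: int = SLIDING_WINDOW) -> EncodingScheme:
    """Return the :class:`EncodingScheme` for ``name`` at window length ``length``."""
    name = name.upper()
    slid = length - w + 1
    table = {
        "OH": (length, 21),
        "ZSCALE": (length, 5),
        "WE": (length, 1),
        "EAAC": (slid, 20),
        "EGAAC": (slid, 5),
    }
    if name not in table:
        raise ValueError(f"unknown encoding {name!r}; choose from {sorted(table)}")
    pos, ch = table[name]
    return EncodingScheme(name=name, positions=pos, channels=ch)


ENCODING_NAMES = ("OH", "ZSCALE", "WE", "EAAC", "EGAAC")


def load_zscale_table() -> dict[str, np.ndarray]:
    """Load the packaged five-descriptor z-scale table (Sandberg et al., 1998).

    z1 relates to hydrophilicity, z2 to side-chain bulk, z3 to polarity, and
    z4/z5 to electronic properties. The padding symbol maps to the zero vector.
    """
    with resources.files("psadpr.data").joinpath("zscales.csv").open() as fh:
        df = pd.read_csv(fh)
    table = {
        str(r.residue): np.array([r.z1, r.z2, r.z3, r.z4, r.z5], dtype=np.float64)
        for r in df.itertuples(index=False)
    }
    table[PAD] = np.zeros(5)
    return table


_ZSCALES: dict[str, np.ndarray] | None = None


def _zscale_matrix(table: Mapping[str, np.ndarray] | None = None) -> np.ndarray:
    global _ZSCALES
    if table is None:
        if _ZSCALES is None:
            _ZSCALES = load_zscale_table()
        table = _ZSCALES
    missing = [aa for aa in ALPHABET if aa not in table]
    if missing:
        raise ValueError(f"z-scale table missing residues {missing}")
    return np.stack([np.asarray(table[aa], dtype=np.float64) for aa in ALPHABET])


def _as_codes(windows: Sequence[PeptideWindow] | Sequence[str]) -> np.ndarray:
    """Integer-code peptides: (n, L) array of alphabet indices."""
    peps = [w.peptide if isinstance(w, PeptideWindow) else w for w in windows]
    if not peps:
        raise ValueError("no windows to encode")
    lengths = {len(p) for p in peps}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths {sorted(lengths)}")
    joined = "".join(peps)
    bad = set(joined) - set(ALPHABET)
    if bad:
        raise ValueError(f"characters outside the 21-symbol alphabet: {sorted(bad)}")
    lut = np.full(128, -1, dtype=np.int64)
    for ch, i in _AA_INDEX.items():
        lut[ord(ch)] = i
    return lut[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)].reshape(
        len(peps), -1
    )


def encode_onehot(windows: Sequence[PeptideWindow] | Sequence[str]) -> np.ndarray:
    """One-hot encode: (n, L, 21) binary array; each row sums to 1."""
    codes = _as_codes(windows)
    out = np.zeros((*codes.shape, len(ALPHABET)), dtype=np.float32)
    n, L = codes.shape
    out[np.arange(n)[:, None], np.arange(L)[None, :], codes] = 1.0
    return out


def encode_zscale(
    windows: Sequence[PeptideWindow] | Sequence[str],
    table: Mapping[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Z-scale encode: (n, L, 5) array of physicochemical descriptors."""
    codes = _as_codes(windows)
    return _zscale_matrix(table)[codes].astype(np.float32)


def encode_indices(windows: Sequence[PeptideWindow] | Sequence[str]) -> np.ndarray:
    """Integer tokens in {0..20}: (n, L) array; the word-embedding model input."""
    return _as_codes(windows)


def decode_indices(tokens: np.ndarray) -> list[str]:
    """Inverse of :func:`encode_indices`."""
    tokens = np.asarray(tokens)
    if tokens.min() < 0 or tokens.max() >= len(ALPHABET):
        raise ValueError("tokens outside {0..20}")
    return ["".join(ALPHABET[t] for t in row) for row in np.atleast_2d(tokens)]


def _sliding_counts(onehot21: np.ndarray, w: int) -> np.ndarray:
    """Sum one-hot channels over each length-``w`` sliding window via cumsum."""
    n, L, C = onehot21.shape
    if w > L:
        raise ValueError(f"sliding window {w} exceeds peptide length {L}")
    cs = np.concatenate(
        [np.zeros((n, 1, C), dtype=np.float64), np.cumsum(onehot21, axis=1)], axis=1
    )
    return cs[:, w:, :] - cs[:, :-w, :]  # (n, L-w+1, C)


def encode_eaac(
    windows: Sequence[PeptideWindow] | Sequence[str], w: int = SLIDING_WINDOW
) -> np.ndarray:
    """Enhanced amino-acid composition: (n, L-w+1, 20) sliding frequencies.

    For each sliding window of length ``w`` the count of each of the 20
    residues is divided by ``w``; padding characters count toward no residue,
    so padded windows have channel sums below 1.
    """
    counts = _sliding_counts(encode_onehot(windows).astype(np.float64), w)
    return (counts[:, :, :20] / w).astype(np.float32)


def encode_egaac(
    windows: Sequence[PeptideWindow] | Sequence[str], w: int = SLIDING_WINDOW
) -> np.ndarray:
    """Enhanced grouped amino-acid content: (n, L-w+1, 5) sliding group frequencies."""
    counts = _sliding_counts(encode_onehot(windows).astype(np.float64), w)
    n, P, _ = counts.shape
    out = np.zeros((n, P, len(AA_GROUPS)), dtype=np.float64)
    for aa_idx in range(20):
        out[:, :, _GROUP_OF[aa_idx]] += counts[:, :, aa_idx]
    return (out / w).astype(np.float32)


_ENCODERS = {
    "OH": encode_onehot,
    "ZSCALE": encode_zscale,
    "WE": encode_indices,
    "EAAC": encode_eaac,
    "EGAAC": encode_egaac,
}


def encode(
    windows: Sequence[PeptideWindow] | Sequence[str], name: str
) -> np.ndarray:
    """Encode windows under the named scheme; shape per the scheme contract."""
    name = name.upper()
    if name not in _ENCODERS:
        raise ValueError(f"unknown encoding {name!r}")
    return _ENCODERS[name](windows)
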