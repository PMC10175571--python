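"""Synthetic serine-centered peptide datasets with planted compositional signals.

The generator emulates the qualitative sequence character of crosstalk
(phospho + ADP-ribosyl) serines relative to background serines: lysine broadly
enriched across the flanks (except position +1), arginine enriched at -2/-3,
glycine enriched at +1/+2, and aspartate/glutamate depleted around the site
with leucine depleted throughout. Each flank residue is drawn independently
from a per-position residue distribution, so generated sets have exactly the
positional composition the motif profile encodes and no longer-range structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import SplitPlan, split_dataset
from .windows import AMINO_ACIDS, PAD, WINDOW_LENGTH, PeptideWindow

_AA = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

FLANK = WINDOW_LENGTH // 2  # 20 residues on each side
#: Flank positions relative to the central serine.
POSITIONS = tuple(p for p in range(-FLANK, FLANK + 1) if p != 0)

#: Approximate human-proteome amino-acid frequencies (UniProt composition),
#: packaged as the alternative to the uniform background.
HUMAN_AA_FREQUENCIES: Mapping[str, float] = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.012, "Y": 0.027,
}


def uniform_background() -> np.ndarray:
    """Uniform residue distribution over the 20 amino acids (default null)."""
    return np.full(20, 1.0 / 20.0)


def empirical_background() -> np.ndarray:
    """Human-proteome residue frequencies, normalized."""
    v = np.array([HUMAN_AA_FREQUENCIES[aa] for aa in AMINO_ACIDS])
    return v / v.sum()


@dataclass(frozen=True)
class MotifSpec:
    """Per-position residue distributions for one peptide class.

    ``profiles`` maps each flank position (-20..-1, +1..+20) to a length-20
    probability vector over the alphabetically ordered amino acids;
    ``background`` is the reference distribution the profiles deviate from.
    ``planted`` records the deliberately perturbed cells (+1 enriched,
    -1 depleted); the remaining residues at a perturbed position absorb the
    probability shift through renormalization and are not considered planted.
    """

    profiles: Mapping[int, np.ndarray]
    background: np.ndarray
    planted: Mapping[tuple[int, str], int] | None = None

    def __post_init__(self) -> None:
        if set(self.profiles) != set(POSITIONS):
            raise ValueError("profiles must cover every flank position")
        for pos, p in self.profiles.items():
            p = np.asarray(p)
            if p.shape != (20,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"profile at position {pos} is not a distribution")

    def planted_cells(self, tol: float = 1e-9) -> dict[tuple[int, str], int]:
        """Planted cells with their sign: +1 enriched, -1 depleted.

        Falls back to diffing profiles against the background when the motif
        was built by hand without an explicit ``planted`` record.
        """
        if self.planted is not None:
            return dict(self.planted)
        cells = {}
        for pos in POSITIONS:
            diff = np.asarray(self.profiles[pos]) - self.background
            for i, aa in enumerate(AMINO_ACIDS):
                if diff[i] > tol:
                    cells[(pos, aa)] = 1
                elif diff[i] < -tol:
                    cells[(pos, aa)] = -1
        return cells

    def to_frame(self) -> pd.DataFrame:
        rows = {pos: np.asarray(self.profiles[pos]) for pos in POSITIONS}
        df = pd.DataFrame(rows, index=list(AMINO_ACIDS)).T
        df.index.name = "position"
        return df

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.8f")

    @classmethod
    def load(cls, path: str | Path, background: np.ndarray | None = None) -> "MotifSpec":
        df = pd.read_csv(path, sep="\t", index_col="position")
        profiles = {}
        for pos in df.index:
            p = df.loc[pos].to_numpy(dtype=float)
            profiles[int(pos)] = p / p.sum()  # undo serialization rounding
        return cls(profiles=profiles,
                   background=uniform_background() if background is None else background)


def build_spec(
    enrich: Mapping[tuple[int, str], float] | None = None,
    deplete: Mapping[tuple[int, str], float] | None = None,
    background: np.ndarray | None = None,
    effect_size: float = 1.0,
) -> MotifSpec:
    """Construct a :class:`MotifSpec` by perturbing a background distribution.

    ``enrich[(pos, aa)] = delta`` raises that residue's probability by
    ``effect_size * delta``; ``deplete[(pos, aa)] = frac`` removes
    ``effect_size * frac`` of its background probability. At each position the
    unperturbed residues are rescaled so the profile remains a distribution.
    """
    if not 0.0 <= effect_size <= 1.0:
        raise ValueError("effect_size must be in [0, 1]")
    bg = uniform_background() if background is None else np.asarray(background, float)
    enrich = enrich or {}
    deplete = deplete or {}
    profiles: dict[int, np.ndarray] = {}
    for pos in POSITIONS:
        p = bg.copy()
        touched = np.zeros(20, dtype=bool)
        for (ppos, aa), delta in enrich.items():
            if ppos == pos:
                p[_AA[aa]] = bg[_AA[aa]] + effect_size * delta
                touched[_AA[aa]] = True
        for (ppos, aa), frac in deplete.items():
            if ppos == pos:
                if touched[_AA[aa]]:
                    raise ValueError(f"residue {aa} both enriched and depleted at {pos}")
                p[_AA[aa]] = bg[_AA[aa]] * (1.0 - effect_size * frac)
                touched[_AA[aa]] = True
        free = ~touched
        spare = 1.0 - p[touched].sum()
        if spare < -1e-12 or (spare > 1e-12 and not free.any()):
            raise ValueError(f"profile at {pos} cannot be renormalized")
        if free.any():
            p[free] = bg[free] * (max(spare, 0.0) / bg[free].sum())
        profiles[pos] = p
    planted: dict[tuple[int, str], int] = {}
    if effect_size > 0:
        planted = {cell: 1 for cell in enrich} | {cell: -1 for cell in deplete}
    return MotifSpec(profiles=profiles, background=bg, planted=planted)


#: Planted signal of the positive (crosstalk) class: probability increments for
#: enriched cells and removed background fractions for depleted cells. The
#: strengths sit in the low-to-mid tens of percentage points, the magnitude
#: range positional-composition differences reach on real crosstalk data.
POSITIVE_ENRICH: dict[tuple[int, str], float] = (
    {(p, "K"): 0.12 for p in POSITIONS if p != 1}
    | {(-2, "R"): 0.15, (-3, "R"): 0.15}
    | {(1, "G"): 0.12, (2, "G"): 0.12}
)
POSITIVE_DEPLETE: dict[tuple[int, str], float] = (
    {(p, aa): 0.9 for aa in "DE" for p in range(-3, 6) if p != 0}
    | {(p, "L"): 0.9 for p in POSITIONS}
)


def default_positive_spec(effect_size: float = 1.0,
                          background: np.ndarray | None = None) -> MotifSpec:
    """The positive-class motif at a given effect size (0 = background)."""
    return build_spec(POSITIVE_ENRICH, POSITIVE_DEPLETE, background, effect_size)


def background_spec(background: np.ndarray | None = None) -> MotifSpec:
    """A motif-free class: every position draws from the background."""
    return build_spec({}, {}, background, effect_size=0.0)


def generate_windows(
    n: int,
    spec: MotifSpec,
    label: str,
    seed: int,
    pad_fraction: float = 0.0,
) -> list[PeptideWindow]:
    """Draw ``n`` serine-centered windows from ``spec``'s positional profiles.

    With ``pad_fraction`` > 0, that fraction of windows (in expectation) gets a
    terminal ``_`` run of random length 1..20, exercising the padding paths.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chars = np.empty((n, WINDOW_LENGTH), dtype="U1")
    chars[:, FLANK] = "S"
    aa_arr = np.array(list(AMINO_ACIDS))
    for pos in POSITIONS:
        draws = rng.choice(20, size=n, p=np.asarray(spec.profiles[pos]))
        chars[:, FLANK + pos] = aa_arr[draws]
    if pad_fraction > 0:
        padded = rng.random(n) < pad_fraction
        for i in np.nonzero(padded)[0]:
            run = int(rng.integers(1, FLANK + 1))
            if rng.random() < 0.5:
                chars[i, :run] = PAD
            else:
                chars[i, WINDOW_LENGTH - run:] = PAD
    return [
        PeptideWindow("".join(row), label=label, source_id=f"syn{seed}_{i}",
                      source_position=FLANK + 1)
        for i, row in enumerate(chars)
    ]


def generate_crosstalk_benchmark(
    n_pos: int,
    n_neg: int,
    effect_size: float = 1.0,
    seed: int = 0,
    n_groups: int = 11,
    negative_label: str = "UM",
    background: np.ndarray | None = None,
    pad_fraction: float = 0.0,
) -> tuple[list[PeptideWindow], np.ndarray, SplitPlan]:
    """A labeled benchmark: planted-motif positives vs background negatives.

    Returns the windows (positives first), a 0/1 label vector, and an
    ``n_groups``-way stratified :class:`SplitPlan` (last group = independent
    test). At ``effect_size=0`` the classes are exchangeable, so any
    classifier's expected AUC is 0.5.
    """
    if min(n_pos, n_neg) < n_groups:
        raise ValueError(f"need at least {n_groups} windows per class")
    pos_spec = default_positive_spec(effect_size, background)
    neg_spec = background_spec(background)
    windows = generate_windows(n_pos, pos_spec, "pSADPr", seed=seed,
                               pad_fraction=pad_fraction)
    windows += generate_windows(n_neg, neg_spec, negative_label, seed=seed + 1,
                                pad_fraction=pad_fraction)
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    plan = split_dataset(windows, n_groups=n_groups, seed=seed + 2)
    return windows, labels, plan
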