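"""Serine-centered peptide windows: FASTA input, window extraction, prediction output.

A site is represented by a fixed-length (default 41) peptide window with the
serine at the center. Sites close to a protein terminus are padded with the
filler symbol ``_`` so the window length is always maintained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: 20 canonical residues, alphabetical, plus the terminal-padding symbol.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
ALPHABET = AMINO_ACIDS + PAD

#: Residue codes that are legal in FASTA but outside the canonical 20.
NONSTANDARD = set("BJOUXZ")

#: Site labels: crosstalk, ADP-ribosylation only, phosphorylation only, unmodified.
SITE_LABELS = ("pSADPr", "SADPr", "pS", "UM")

WINDOW_LENGTH = 41


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its FASTA header token as identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A 1-based serine position on a protein with its modification label."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in SITE_LABELS:
            raise ValueError(f"unknown site label {self.label!r}")


@dataclass(frozen=True)
class PeptideWindow:
    """A serine-centered peptide of fixed odd length over the 21-symbol alphabet.

    ``peptide`` has the central residue ``S``; ``_`` occurs only as contiguous
    terminal runs (N- and/or C-terminal padding). ``source_position`` is the
    1-based coordinate of the central serine on ``source_id``.
    """

    peptide: str
    label: str
    source_id: str = ""
    source_position: int = 0

    def __post_init__(self) -> None:
        n = len(self.peptide)
        if n % 2 == 0:
            raise ValueError(f"window length must be odd, got {n}")
        center = n // 2
        if self.peptide[center] != "S":
            raise ValueError(
                f"window center must be 'S', got {self.peptide[center]!r}"
            )
        bad = set(self.peptide) - set(ALPHABET)
        if bad:
            raise ValueError(f"illegal window characters {sorted(bad)}")
        core = self.peptide.strip(PAD)
        if PAD in core:
            raise ValueError("'_' permitted only as contiguous terminal runs")

    def __len__(self) -> int:
        return len(self.peptide)


def _clean_sequence(seq: str, record_id: str, on_nonstandard: str) -> str:
    """Uppercase and handle non-canonical residues (map to '_' or reject)."""
    seq = seq.upper()
    present = set(seq) & NONSTANDARD
    if present:
        if on_nonstandard == "reject":
            raise ValueError(
                f"protein {record_id!r}: non-standard residues {sorted(present)}"
            )
        logger.warning(
            "protein %r: mapping non-standard residues %s to '%s'",
            record_id, sorted(present), PAD,
        )
        for ch in present:
            seq = seq.replace(ch, PAD)
    return seq


def read_fasta(path: str | Path, on_nonstandard: str = "map") -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file into :class:`ProteinRecord` objects.

    Parameters
    ----------
    path
        FASTA file; wrapped or unwrapped lines.
    on_nonstandard
        ``"map"`` replaces B/J/O/U/X/Z with ``_`` (with a logged warning);
        ``"reject"`` raises on any such residue.
    """
    if on_nonstandard not in ("map", "reject"):
        raise ValueError("on_nonstandard must be 'map' or 'reject'")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(rec.seq), rec.id, on_nonstandard)
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def extract_window(
    protein: ProteinRecord, position: int, length: int = WINDOW_LENGTH,
    label: str = "UM",
) -> PeptideWindow:
    """Extract the ``length``-residue window centered on a serine.

    ``position`` is 1-based. Positions falling before the N-terminus or after
    the C-terminus are filled with ``_`` so the result always has exactly
    ``length`` characters.
    """
    if length % 2 == 0:
        raise ValueError(f"window length must be odd, got {length}")
    if not 1 <= position <= len(protein):
        raise ValueError(
            f"position {position} out of range 1..{len(protein)} for {protein.id!r}"
        )
    if protein.sequence[position - 1] != "S":
        raise ValueError(
            f"{protein.id!r} position {position}: residue "
            f"{protein.sequence[position - 1]!r} is not serine"
        )
    flank = length // 2
    start = position - 1 - flank  # 0-based, may be negative
    chunks = []
    for i in range(start, start + length):
        chunks.append(protein.sequence[i] if 0 <= i < len(protein) else PAD)
    return PeptideWindow(
        peptide="".join(chunks),
        label=label,
        source_id=protein.id,
        source_position=position,
    )


def extract_annotated_windows(
    proteins: Iterable[ProteinRecord],
    sites: Iterable[SiteAnnotation],
    length: int = WINDOW_LENGTH,
) -> list[PeptideWindow]:
    """Extract windows for every annotated site; errors on unknown proteins."""
    by_id = {p.id: p for p in proteins}
    out = []
    for s in sites:
        if s.protein_id not in by_id:
            raise KeyError(f"site references unknown protein {s.protein_id!r}")
        out.append(
            extract_window(by_id[s.protein_id], s.position, length, label=s.label)
        )
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["protein_id", "position", "label"]
WINDOW_COLUMNS = ["peptide", "label", "source_id", "position"]
PREDICTION_COLUMNS = ["header", "position", "sequence", "score", "category"]


def read_sites_tsv(path: str | Path) -> list[SiteAnnotation]:
    """Read a 3-column TSV of site annotations (protein_id, position, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns {sorted(missing)}")
    return [
        SiteAnnotation(str(r.protein_id), int(r.position), str(r.label))
        for r in df.itertuples(index=False)
    ]


def write_windows_tsv(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    df = pd.DataFrame(
        [(w.peptide, w.label, w.source_id, w.source_position) for w in windows],
        columns=WINDOW_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_windows_tsv(path: str | Path) -> list[PeptideWindow]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "source_id": str})
    missing = set(WINDOW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"window table missing columns {sorted(missing)}")
    return [
        PeptideWindow(str(r.peptide), str(r.label), str(r.source_id), int(r.position))
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class PredictionRecord:
    """One scored serine site, ready for the 5-column output table."""

    header: str
    position: int
    sequence: str
    score: float
    category: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def write_predictions(
    records: Sequence[PredictionRecord], path: str | Path
) -> None:
    """Write the 5-column prediction table.

    Columns, in order: sequence header, position, sequence, prediction score,
    and prediction category. Tab-separated with a header row.
    """
    df = pd.DataFrame(
        [(r.header, r.position, r.sequence, r.score, r.category) for r in records],
        columns=PREDICTION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def pad_count(position: int, protein_length: int, length: int = WINDOW_LENGTH) -> int:
    """Number of '_' characters in the window for a site at ``position``."""
    flank = length // 2
    return max(0, flank + 1 - position) + max(0, position + flank - protein_length)
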