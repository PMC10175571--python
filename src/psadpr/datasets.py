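"""Dataset construction: label derivation, redundancy reduction, splitting.

Three binary classification datasets are derived from site catalogs:
crosstalk-vs-ADPr-only, crosstalk-vs-phospho-only, and crosstalk-vs-unmodified.
Each combined peptide pool is reduced with greedy 60%-identity clustering and a
crosstalk-preferring representative rule, then split into 11 label-stratified
groups (10 cross-validation folds + 1 independent test group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .windows import PAD, PeptideWindow

Site = tuple[str, int]

POSITIVE_LABEL = "pSADPr"

#: Default clustering threshold: fraction of identical positions in the
#: ungapped 41-mer alignment.
IDENTITY_THRESHOLD = 0.6

N_GROUPS = 11


def derive_labels(
    pS_sites: set[Site], SADPr_sites: set[Site], UM_sites: set[Site]
) -> dict[str, set[Site]]:
    """Partition site catalogs into pSADPr / pS-only / SADPr-only / UM sets.

    A crosstalk (pSADPr) site is a serine reported as both phosphorylated and
    ADP-ribosylated; the single-modification sets keep only their exclusive
    members. Unmodified sites must be disjoint from every modified catalog.
    """
    modified = pS_sites | SADPr_sites
    overlap = UM_sites & modified
    if overlap:
        raise ValueError(
            f"unmodified sites overlap modified catalogs: {sorted(overlap)[:5]}"
        )
    return {
        "pSADPr": pS_sites & SADPr_sites,
        "pS": pS_sites - SADPr_sites,
        "SADPr": SADPr_sites - pS_sites,
        "UM": set(UM_sites),
    }


def peptide_identity(a: PeptideWindow | str, b: PeptideWindow | str,
                     count_pad: bool = True) -> float:
    """Fraction of positions with identical characters in two equal-length peptides.

    With ``count_pad`` (default) a ``_``/``_`` pair counts as a match — padding
    runs at the same terminus indicate comparable sequence context. With
    ``count_pad=False`` positions where both characters are ``_`` are excluded
    from numerator and denominator.
    """
    sa = a.peptide if isinstance(a, PeptideWindow) else a
    sb = b.peptide if isinstance(b, PeptideWindow) else b
    if len(sa) != len(sb):
        raise ValueError(f"length mismatch: {len(sa)} vs {len(sb)}")
    if count_pad:
        return sum(x == y for x, y in zip(sa, sb)) / len(sa)
    pairs = [(x, y) for x, y in zip(sa, sb) if not (x == PAD and y == PAD)]
    if not pairs:
        return 1.0
    return sum(x == y for x, y in pairs) / len(pairs)


@dataclass
class PeptideCluster:
    """A cluster of homologous windows with one selected representative."""

    members: list[PeptideWindow]
    representative: PeptideWindow

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be non-empty")
        if self.representative not in self.members:
            raise ValueError("representative must be a cluster member")


def cluster_peptides(
    windows: Sequence[PeptideWindow],
    threshold: float = IDENTITY_THRESHOLD,
    count_pad: bool = True,
) -> list[PeptideCluster]:
    """Greedy incremental identity clustering of equal-length peptides.

    Windows are processed in a deterministic order (sorted by peptide string,
    ties by label then source). A window joins the first existing cluster whose
    founder has identity >= ``threshold`` with it; otherwise it founds a new
    cluster. The founder serves as the provisional representative; use
    :func:`select_representatives` for the crosstalk-preferring final choice.
    """
    if not windows:
        raise ValueError("no windows to cluster")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths {sorted(lengths)}")
    order = sorted(
        windows, key=lambda w: (w.peptide, w.label, w.source_id, w.source_position)
    )
    # Integer-code peptides once so founder comparisons are vectorized.
    codes = np.frombuffer(
        "".join(w.peptide for w in order).encode("ascii"), dtype=np.uint8
    ).reshape(len(order), -1)
    L = codes.shape[1]
    # founders kept in a capacity-doubling buffer so each comparison is one
    # vectorized pass without per-iteration reallocation
    buf = np.empty((16, L), dtype=np.uint8)
    n_founders = 0
    clusters: list[PeptideCluster] = []
    pad_byte = ord(PAD)
    for w, row in zip(order, codes):
        placed = False
        if n_founders:
            founders = buf[:n_founders]
            eq = founders == row
            if count_pad:
                ident = eq.mean(axis=1)
            else:
                both_pad = (founders == pad_byte) & (row == pad_byte)
                denom = L - both_pad.sum(axis=1)
                ident = np.where(
                    denom > 0, (eq & ~both_pad).sum(axis=1) / np.maximum(denom, 1), 1.0
                )
            hits = np.nonzero(ident >= threshold)[0]
            if hits.size:
                clusters[hits[0]].members.append(w)
                placed = True
        if not placed:
            clusters.append(PeptideCluster(members=[w], representative=w))
            if n_founders == buf.shape[0]:
                buf = np.concatenate([buf, np.empty_like(buf)])
            buf[n_founders] = row
            n_founders += 1
    return clusters


def select_representatives(
    clusters: Sequence[PeptideCluster], seed: int
) -> list[PeptideWindow]:
    """Pick one representative per cluster, preferring crosstalk members.

    If a cluster contains any pSADPr window, the representative is drawn
    uniformly among its pSADPr members; otherwise uniformly among all members.
    The draw is seeded and the clusters are updated in place.
    """
    rng = np.random.default_rng(seed)
    reps = []
    for c in clusters:
        pool = [w for w in c.members if w.label == POSITIVE_LABEL] or c.members
        rep = pool[int(rng.integers(len(pool)))]
        c.representative = rep
        reps.append(rep)
    return reps


@dataclass
class SplitPlan:
    """Partition of dataset indices into 11 disjoint groups.

    Groups 0..9 form the ten-fold cross-validation pool; the final group is
    the independent test dataset.
    """

    groups: list[np.ndarray]
    cv_group_ids: list[int] = field(default_factory=lambda: list(range(10)))
    test_group_id: int = 10

    def __post_init__(self) -> None:
        all_idx = np.concatenate([np.asarray(g) for g in self.groups])
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split groups are not disjoint")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def cv_indices(self) -> np.ndarray:
        return np.sort(np.concatenate([self.groups[g] for g in self.cv_group_ids]))

    @property
    def test_indices(self) -> np.ndarray:
        return np.sort(self.groups[self.test_group_id])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, idx in enumerate(self.groups):
            role = "test" if gid == self.test_group_id else "cv"
            rows.extend((int(i), gid, role) for i in idx)
        return (
            pd.DataFrame(rows, columns=["index", "group", "role"])
            .sort_values("index")
            .reset_index(drop=True)
        )


def split_dataset(
    windows: Sequence[PeptideWindow], n_groups: int = N_GROUPS, seed: int = 0
) -> SplitPlan:
    """Label-stratified random partition into ``n_groups`` near-equal groups.

    Within each label stratum the group sizes differ by at most one. The last
    group is designated the independent test dataset.
    """
    labels = np.array([w.label for w in windows])
    rng = np.random.default_rng(seed)
    groups: list[list[int]] = [[] for _ in range(n_groups)]
    for lab in sorted(set(labels)):
        idx = np.nonzero(labels == lab)[0]
        if len(idx) < n_groups:
            raise ValueError(
                f"stratum {lab!r} has {len(idx)} windows; need >= {n_groups}"
            )
        rng.shuffle(idx)
        for g, chunk in enumerate(np.array_split(idx, n_groups)):
            groups[g].extend(int(i) for i in chunk)
    return SplitPlan(
        groups=[np.sort(np.array(g, dtype=int)) for g in groups],
        cv_group_ids=list(range(n_groups - 1)),
        test_group_id=n_groups - 1,
    )


def balance_dataset(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    seed: int = 0,
) -> list[PeptideWindow]:
    """All positives plus a seeded uniform sample of equally many negatives."""
    if len(negatives) < len(positives):
        raise ValueError(
            f"need at least {len(positives)} negatives, got {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(negatives), size=len(positives), replace=False)
    return list(positives) + [negatives[i] for i in sorted(keep)]


def write_clusters_tsv(clusters: Sequence[PeptideCluster], path: str | Path) -> None:
    rows = []
    for cid, c in enumerate(clusters):
        for w in c.members:
            rows.append(
                (cid, w.peptide, w.label, w.source_id, w.source_position,
                 int(w is c.representative))
            )
    pd.DataFrame(
        rows,
        columns=["cluster", "peptide", "label", "source_id", "position",
                 "is_representative"],
    ).to_csv(path, sep="\t", index=False)
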