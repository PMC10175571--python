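"""Positional residue enrichment and hypergeometric subset enrichment.

Two analyses of what distinguishes crosstalk serines:

* :func:`positional_enrichment` — a two-sample-logo style comparison: for each
  flank position and residue, a pooled two-sample t-test on the per-peptide
  0/1 presence indicator between a foreground and a background peptide set,
  Bonferroni corrected over all 800 (40 positions x 20 residues) cells. The
  pooled (equal-variance) form keeps the statistic bounded when one set is
  small and degenerate (e.g. a handful of peptides none of which carry a
  residue), where an unpooled statistic would diverge.
* :func:`hypergeom_enrichment` / :func:`kinase_subfamily_enrichment` — exact
  hypergeometric tail tests for over/under-representation of a property (e.g.
  "predicted substrate of kinase subfamily X") in a site subset against a
  background, computed with log-space binomial coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import ttest_ind

from .windows import AMINO_ACIDS, PAD, PeptideWindow

#: Bonferroni universe: 40 flank positions x 20 residues.
N_CELLS = 800


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-(position, residue) comparison of foreground vs background."""

    table: pd.DataFrame  # columns: position, residue, fg_freq, bg_freq,
    #                      diff, p_value, significant
    alpha: float
    n_tests: int

    def significant_cells(self) -> dict[tuple[int, str], int]:
        """Significant cells mapped to their sign (+1 enriched, -1 depleted)."""
        sig = self.table[self.table.significant]
        return {
            (int(r.position), str(r.residue)): (1 if r.diff > 0 else -1)
            for r in sig.itertuples(index=False)
        }


def _presence(windows: Sequence[PeptideWindow] | Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-peptide residue indicators: (n, L) codes and (n, L) pad mask."""
    peps = [w.peptide if isinstance(w, PeptideWindow) else w for w in windows]
    if not peps:
        raise ValueError("empty peptide set")
    if len({len(p) for p in peps}) != 1:
        raise ValueError("mixed window lengths")
    arr = np.frombuffer("".join(peps).encode("ascii"), dtype=np.uint8).reshape(
        len(peps), -1
    )
    return arr, arr != ord(PAD)


def positional_enrichment(
    foreground: Sequence[PeptideWindow] | Sequence[str],
    background: Sequence[PeptideWindow] | Sequence[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Per-position, per-residue two-sample comparison with Bonferroni control.

    For every flank position (the central serine is excluded) and residue, the
    per-peptide presence indicator (1 if that peptide has that residue at that
    position) is compared between the two sets with a two-sided pooled
    two-sample t-test. Padded positions are excluded from both numerator and
    denominator.
    A cell is significant when its raw p-value is at most ``alpha / 800``.
    """
    fg, fg_real = _presence(foreground)
    bg, bg_real = _presence(background)
    if fg.shape[1] != bg.shape[1]:
        raise ValueError("foreground and background window lengths differ")
    L = fg.shape[1]
    center = L // 2
    flank = [i for i in range(L) if i != center]
    rows = []
    for col in flank:
        pos = col - center
        f_keep = fg_real[:, col]
        b_keep = bg_real[:, col]
        fcol = fg[f_keep, col]
        bcol = bg[b_keep, col]
        for aa in AMINO_ACIDS:
            x = (fcol == ord(aa)).astype(float)
            y = (bcol == ord(aa)).astype(float)
            fg_freq = float(x.mean()) if x.size else np.nan
            bg_freq = float(y.mean()) if y.size else np.nan
            if x.size < 2 or y.size < 2:
                p = np.nan
            elif x.std() == 0 and y.std() == 0:
                p = 1.0 if fg_freq == bg_freq else 0.0
            else:
                p = float(ttest_ind(x, y, equal_var=True).pvalue)
            rows.append((pos, aa, fg_freq, bg_freq, fg_freq - bg_freq, p))
    table = pd.DataFrame(
        rows, columns=["position", "residue", "fg_freq", "bg_freq", "diff", "p_value"]
    )
    table["significant"] = table.p_value <= alpha / N_CELLS
    return EnrichmentResult(table=table, alpha=alpha, n_tests=N_CELLS)


def render_text_logo(result: EnrichmentResult) -> str:
    """Plain-text rendering of the significant cells, one line per position."""
    sig = result.significant_cells()
    lines = []
    for pos in sorted({p for p, _ in sig}):
        up = "".join(aa for (p, aa), s in sorted(sig.items()) if p == pos and s > 0)
        dn = "".join(aa for (p, aa), s in sorted(sig.items()) if p == pos and s < 0)
        lines.append(f"{pos:+3d}  enriched: {up or '-':<8} depleted: {dn or '-'}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Hypergeometric subset enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubsetEnrichment:
    """Counts and tail p-values for one subset-vs-background property."""

    N: int  # background size
    K: int  # background members with the property
    n: int  # subset size
    k: int  # subset members with the property
    p_enriched: float  # upper tail  P(X >= k)
    p_depleted: float  # lower tail  P(X <= k)

    @property
    def p_value(self) -> float:
        """The enrichment (upper-tail) p-value."""
        return self.p_enriched


def _log_binom(n, k) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_enrichment(N: int, K: int, n: int, k: int) -> SubsetEnrichment:
    """Exact hypergeometric tail probabilities via log-space binomials.

    ``X ~ Hypergeometric(N, K, n)`` is the number of property-carrying members
    in a size-``n`` subset drawn without replacement from a background of
    ``N`` with ``K`` carriers. The enrichment p-value is ``P(X >= k)``, the
    depletion p-value ``P(X <= k)``.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)) or k < max(0, n - (N - K)):
        raise ValueError(f"impossible k={k} for N={N}, K={K}, n={n}")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    support = np.arange(lo, hi + 1)
    logpmf = (
        _log_binom(K, support)
        + _log_binom(N - K, n - support)
        - _log_binom(N, n)
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    p_up = float(pmf[support >= k].sum())
    p_dn = float(pmf[support <= k].sum())
    return SubsetEnrichment(N=N, K=K, n=n, k=k,
                            p_enriched=min(p_up, 1.0), p_depleted=min(p_dn, 1.0))


def kinase_subfamily_enrichment(
    site_predictions: pd.DataFrame | np.ndarray,
    subset_mask: Sequence[bool],
    subfamilies: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a site subset per kinase subfamily.

    ``site_predictions`` is a binary matrix (sites x subfamilies) of external
    kinase-substrate predictions covering the background; ``subset_mask``
    selects the subset (e.g. crosstalk sites) within it. Returns one row per
    subfamily with counts, coverage fractions and both tail p-values.
    """
    if isinstance(site_predictions, pd.DataFrame):
        names = list(site_predictions.columns)
        M = site_predictions.to_numpy()
    else:
        M = np.asarray(site_predictions)
        names = list(subfamilies) if subfamilies is not None else [
            f"subfamily_{i}" for i in range(M.shape[1])
        ]
    mask = np.asarray(subset_mask, dtype=bool)
    if mask.shape[0] != M.shape[0]:
        raise ValueError("subset mask length does not match prediction matrix")
    if not np.isin(M, (0, 1)).all():
        raise ValueError("prediction matrix must be binary")
    N, n = M.shape[0], int(mask.sum())
    rows = []
    for j, name in enumerate(names):
        K = int(M[:, j].sum())
        k = int(M[mask, j].sum())
        e = hypergeom_enrichment(N, K, n, k)
        rows.append({
            "subfamily": name, "N": N, "K": K, "n": n, "k": k,
            "background_fraction": K / N if N else np.nan,
            "subset_fraction": k / n if n else np.nan,
            "p_enriched": e.p_enriched, "p_depleted": e.p_depleted,
        })
    return pd.DataFrame(rows)
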