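"""Signed log2 co-occurrence statistics among cardinal motifs within
promoter windows.

Off-diagonal cells test presence/absence co-occurrence of two motifs over
the promoter universe with an exact hypergeometric null; the diagonal tests
a motif's tendency to appear in multiple copies within the same window
(self co-occurrence) against a truncated-Poisson null.  Scores are signed
log2 p-values: positive for co-occurrence beyond chance, negative for
avoidance, masked (0) when neither tail clears ``alpha``.

The self statistic's null is this package's construction: occurrences are
assumed to fall independently across windows with a pooled per-window rate,
and the number of multi-copy windows among occupied windows is referred to
a binomial tail.  Output metadata flags this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motif_engine import hypergeom_tails

__all__ = [
    "CooccurrenceMatrix",
    "pairwise_cooccurrence",
    "self_cooccurrence",
    "cooccurrence_on_subset",
]


@dataclass
class CooccurrenceMatrix:
    """Symmetric motif x motif signed log2 co-occurrence scores.

    ``scores`` holds the signed log2 p-values with masked cells set to 0;
    ``mask`` is True where no tail reached significance; ``details`` is a
    long-format table of (A, B, N, a, b, x, p_pos, p_neg, masked).
    """

    motifs: list[str]
    scores: pd.DataFrame
    mask: pd.DataFrame
    details: pd.DataFrame
    alpha: float
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, scores_path, details_path=None) -> None:
        self.scores.to_csv(scores_path, sep="\t")
        if details_path is not None:
            self.details.to_csv(details_path, sep="\t", index=False)


def _signed_score(p_pos: float, p_neg: float, observed_ge_expected: bool,
                  alpha: float) -> tuple[float, bool]:
    """Signed log2 score and mask bit from the two tails."""
    if min(p_pos, p_neg) > alpha:
        return 0.0, True
    if observed_ge_expected:
        return -float(np.log2(max(p_pos, 1e-300))), False
    return float(np.log2(max(p_neg, 1e-300))), False


def self_cooccurrence(counts: np.ndarray, alpha: float = 0.05
                      ) -> tuple[float, float, float, bool]:
    """Multi-copy tendency of one motif over N promoter windows.

    Null: occurrences land independently with per-window rate
    lambda = total/N (Poisson), so among the m occupied windows the chance
    of >= 2 copies is q = P(Pois >= 2)/P(Pois >= 1).  The observed number
    of multi-copy windows m2 is referred to Binomial(m, q) tails.

    Returns (score, p_pos, p_neg, masked).
    """
    counts = np.asarray(counts)
    N = counts.size
    if N < 2:
        raise ValueError("need at least 2 promoters")
    m = int((counts >= 1).sum())
    if m == 0:
        return 0.0, 1.0, 1.0, True
    lam = counts.sum() / N
    p_ge1 = -np.expm1(-lam)                    # P(Pois >= 1)
    p_ge2 = p_ge1 - lam * np.exp(-lam)         # P(Pois >= 2)
    q = float(p_ge2 / p_ge1)
    m2 = int((counts >= 2).sum())
    p_pos = float(stats.binom.sf(m2 - 1, m, q))
    p_neg = float(stats.binom.cdf(m2, m, q))
    score, masked = _signed_score(p_pos, p_neg, m2 >= m * q, alpha)
    return score, p_pos, p_neg, masked


def pairwise_cooccurrence(
    occurrence: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> CooccurrenceMatrix:
    """Signed log2 co-occurrence matrix over all motif pairs.

    For motifs A != B over N promoters with a = |A-positive|,
    b = |B-positive|, x = |both|: the upper/lower hypergeometric tails of x
    give p_pos/p_neg; score = -log2(p_pos) when x >= a*b/N, else
    +log2(p_neg).  Cells with min(p) > alpha are masked white.  The
    diagonal holds the self (multi-copy) statistic from the count matrix.

    ``bh_correct`` applies Benjamini–Hochberg across the upper-triangle
    directional p-values before masking.
    """
    import warnings

    if occurrence.shape[1] < 2 or occurrence.shape[0] < 2:
        raise ValueError("need >= 2 motifs and >= 2 promoters")
    motifs = list(occurrence.columns)
    presence = (occurrence.values >= 1)
    N = presence.shape[0]
    k = len(motifs)
    scores = np.zeros((k, k))
    mask = np.zeros((k, k), dtype=bool)
    rows = []

    col_sums = presence.sum(axis=0)
    cross = presence.T.astype(np.int64) @ presence.astype(np.int64)

    pair_stats = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b, x = int(col_sums[i]), int(col_sums[j]), int(cross[i, j])
            if a == 0 or b == 0:
                warnings.warn(
                    f"motif {motifs[i] if a == 0 else motifs[j]!r} absent "
                    "from all promoters; cell masked"
                )
                pair_stats[(i, j)] = (a, b, x, 1.0, 1.0, True)
                continue
            p_pos, p_neg = hypergeom_tails(N, a, b, x)
            pair_stats[(i, j)] = (a, b, x, p_pos, p_neg, False)

    if bh_correct:
        keys = [ij for ij, s in pair_stats.items() if not s[5]]
        pvals = np.array([min(pair_stats[ij][3], pair_stats[ij][4]) for ij in keys])
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, pvals[idx] * m / (rank_pos + 1))
            adj[idx] = running
        reject = {keys[t]: adj[t] <= alpha for t in range(m)}
    else:
        reject = None

    for (i, j), (a, b, x, p_pos, p_neg, degenerate) in pair_stats.items():
        if degenerate:
            s, msk = 0.0, True
        else:
            s, msk = _signed_score(p_pos, p_neg, x >= a * b / N, alpha)
            if reject is not None and not msk:
                msk = not reject.get((i, j), False)
                if msk:
                    s = 0.0
        scores[i, j] = scores[j, i] = s
        mask[i, j] = mask[j, i] = msk
        rows.append(dict(A=motifs[i], B=motifs[j], N=N, a=a, b=b, x=x,
                         p_pos=p_pos, p_neg=p_neg, masked=msk))

    for i in range(k):
        s, p_pos, p_neg, msk = self_cooccurrence(occurrence.values[:, i], alpha)
        scores[i, i] = s
        mask[i, i] = msk
        rows.append(dict(A=motifs[i], B=motifs[i], N=N,
                         a=int(col_sums[i]), b=int(col_sums[i]),
                         x=int((occurrence.values[:, i] >= 2).sum()),
                         p_pos=p_pos, p_neg=p_neg, masked=msk))

    return CooccurrenceMatrix(
        motifs=motifs,
        scores=pd.DataFrame(scores, index=motifs, columns=motifs),
        mask=pd.DataFrame(mask, index=motifs, columns=motifs),
        details=pd.DataFrame(rows),
        alpha=alpha,
        metadata={
            "diagonal_null": "truncated-Poisson/binomial multi-copy test "
                             "(package construction, not an upstream-defined test)",
            "bh_corrected": bh_correct,
        },
    )


def cooccurrence_on_subset(
    occurrence: pd.DataFrame,
    promoter_subset,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> CooccurrenceMatrix:
    """The identical statistic computed over a promoter subset (N = |subset|).

    Used for restricted universes such as DHS-overlapping promoters or
    focused/dispersed promoter classes.
    """
    subset = list(promoter_subset)
    if len(subset) < 2:
        raise ValueError("subset must contain at least 2 promoters")
    missing = set(subset) - set(occurrence.index)
    if missing:
        raise KeyError(f"subset promoters not in occurrence matrix: {sorted(missing)[:5]}")
    return pairwise_cooccurrence(occurrence.loc[subset], alpha=alpha,
                                 bh_correct=bh_correct)
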