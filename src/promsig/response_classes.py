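"""Two-knockdown differential-response calls, the Class I–VIII taxonomy,
fold-over-background binding enrichment, overlap significance, and
dual-reporter selectivity calls.

The taxonomy crosses the per-gene response to two siRNA treatments
(e.g. NRF1 and LSD1 knockdown):

    (down, down) -> I      (none, down) -> V
    (up,   up)   -> II     (none, up)   -> VI
    (down, up)   -> III    (down, none) -> VII
    (up,   down) -> IV     (up,   none) -> VIII
    (none, none) -> Unaffected

"Background" for fold-over-background is the Unaffected class: a class's
factor-occupancy rate divided by the occupancy rate among unaffected genes;
ratios above 1 read as enrichment for direct effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .motif_engine import hypergeom_tails

__all__ = [
    "DECall",
    "FoldOverBackground",
    "CLASS_TABLE",
    "call_de",
    "call_de_table",
    "assign_class",
    "assign_classes",
    "class_counts",
    "same_direction_percent",
    "fold_over_background",
    "overlap_stats",
    "call_reporter_selectivity",
]

CLASS_TABLE: dict[tuple[str, str], str] = {
    ("down", "down"): "I",
    ("up", "up"): "II",
    ("down", "up"): "III",
    ("up", "down"): "IV",
    ("none", "down"): "V",
    ("none", "up"): "VI",
    ("down", "none"): "VII",
    ("up", "none"): "VIII",
    ("none", "none"): "Unaffected",
}


@dataclass(frozen=True)
class DECall:
    gene_id: str
    treatment: str
    direction: str       # up | down | none
    log2fc: float
    p_value: float


@dataclass(frozen=True)
class FoldOverBackground:
    gene_class: str
    factor: str
    class_rate: float
    background_rate: float
    ratio: float         # inf flagged when background rate is 0
    flagged: bool


def call_de(
    gene_id: str,
    treatment: str,
    control: np.ndarray,
    treated: np.ndarray,
    min_abs_log2fc: float = 0.585,
    alpha: float = 0.05,
) -> DECall:
    """Two-sided two-sample t-test plus a fold-change filter.

    Replicate arrays are on the log2 expression scale; direction is the
    sign of the mean difference when both the p-value and |log2fc| clear
    their thresholds, else "none".
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size < 2 or treated.size < 2:
        raise ValueError("need >= 2 replicates per arm")
    log2fc = float(treated.mean() - control.mean())
    if control.std(ddof=1) == 0 and treated.std(ddof=1) == 0:
        p = 1.0 if log2fc == 0 else 0.0
    else:
        p = float(stats.ttest_ind(treated, control, equal_var=False).pvalue)
    direction = "none"
    if p < alpha and abs(log2fc) >= min_abs_log2fc:
        direction = "up" if log2fc > 0 else "down"
    return DECall(gene_id, treatment, direction, log2fc, p)


def call_de_table(
    expression: pd.DataFrame,
    arms: dict[str, list[str]],
    treatment: str,
    control_arm: str = "control",
    min_abs_log2fc: float = 0.585,
    alpha: float = 0.05,
) -> dict[str, DECall]:
    """Vectorized per-gene calls from a gene x replicate table.

    ``arms`` maps arm name -> replicate column names; the comparison is
    ``treatment`` vs ``control_arm``.
    """
    C = expression[arms[control_arm]].to_numpy(dtype=float)
    T = expression[arms[treatment]].to_numpy(dtype=float)
    log2fc = T.mean(axis=1) - C.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(T, C, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (C.std(axis=1, ddof=1) == 0) & (T.std(axis=1, ddof=1) == 0)
    p = np.where(degenerate, np.where(log2fc == 0, 1.0, 0.0), p)
    sig = (p < alpha) & (np.abs(log2fc) >= min_abs_log2fc)
    calls = {}
    for i, gene in enumerate(expression.index):
        direction = "none"
        if sig[i]:
            direction = "up" if log2fc[i] > 0 else "down"
        calls[str(gene)] = DECall(str(gene), treatment, direction,
                                  float(log2fc[i]), float(p[i]))
    return calls


def assign_class(call_a: DECall, call_b: DECall) -> str:
    """Class I–VIII (or Unaffected) from the two treatments' calls for one
    gene (A = first knockdown, B = second)."""
    if call_a.gene_id != call_b.gene_id:
        raise ValueError("calls refer to different genes")
    return CLASS_TABLE[(call_a.direction, call_b.direction)]


def assign_classes(
    calls_a: dict[str, DECall], calls_b: dict[str, DECall]
) -> dict[str, str]:
    if set(calls_a) != set(calls_b):
        raise ValueError("the two call sets must cover the same genes")
    return {g: assign_class(calls_a[g], calls_b[g]) for g in calls_a}


def class_counts(assignment: dict[str, str]) -> dict[str, int]:
    counts = {c: 0 for c in ["I", "II", "III", "IV", "V", "VI", "VII", "VIII",
                             "Unaffected"]}
    for c in assignment.values():
        counts[c] += 1
    return counts


def same_direction_percent(counts: dict[str, int]) -> int:
    """Percent of both-treatment responders affected in the same direction:
    (|I| + |II|) / (|I|+|II|+|III|+|IV|), nearest integer percent."""
    both = counts["I"] + counts["II"] + counts["III"] + counts["IV"]
    if both == 0:
        raise ValueError("no genes responded to both treatments")
    return round(100 * (counts["I"] + counts["II"]) / both)


def fold_over_background(
    assignment: dict[str, str],
    occupancy: dict[str, dict[str, bool]],
    background_class: str = "Unaffected",
) -> list[FoldOverBackground]:
    """Per (class, factor) occupancy rate relative to the unaffected-gene
    background rate."""
    classes = [c for c in class_counts(assignment) if c != background_class]
    bg_genes = [g for g, c in assignment.items() if c == background_class]
    if not bg_genes:
        raise ValueError("background (unaffected) class is empty")
    factors = sorted({f for occ in occupancy.values() for f in occ})
    results = []
    for factor in factors:
        bg_rate = np.mean([bool(occupancy.get(g, {}).get(factor)) for g in bg_genes])
        for cls in classes:
            genes = [g for g, c in assignment.items() if c == cls]
            if not genes:
                continue
            rate = float(np.mean([bool(occupancy.get(g, {}).get(factor))
                                  for g in genes]))
            if bg_rate == 0:
                warnings.warn(f"factor {factor!r}: background rate 0; "
                              "ratio flagged infinite")
                results.append(FoldOverBackground(cls, factor, rate, 0.0,
                                                  float("inf"), True))
            else:
                results.append(FoldOverBackground(cls, factor, rate,
                                                  float(bg_rate),
                                                  rate / float(bg_rate), False))
    return results


def overlap_stats(
    n_a: int, n_b: int, n_ab: int, universe_size: int | None = None
) -> tuple[int, int, float | None]:
    """Overlap of two gene sets: (percent of A, percent of B, upper
    hypergeometric tail p).

    Percentages are rounded to the nearest integer and do not depend on the
    universe; the p-value needs ``universe_size`` (None -> p is None).
    """
    if n_ab > min(n_a, n_b) or min(n_a, n_b, n_ab) < 0:
        raise ValueError("inconsistent overlap counts")
    if universe_size is not None and max(n_a, n_b) > universe_size:
        raise ValueError("set larger than the universe")
    frac_a = round(100 * n_ab / n_a) if n_a else 0
    frac_b = round(100 * n_ab / n_b) if n_b else 0
    p = None
    if universe_size is not None:
        p, _ = hypergeom_tails(universe_size, n_a, n_b, n_ab)
    return frac_a, frac_b, p


def call_reporter_selectivity(
    reporter1: dict[str, np.ndarray],
    reporter2: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> str:
    """Selectivity of one siRNA treatment between two reporters.

    Each reporter dict carries ``treatment`` and ``control`` replicate
    arrays (measurements normalized within the reporter).  Per reporter, a
    paired two-sided t-test against control; between reporters, a t-test on
    the control-normalized effects.  Labels:

    - ``reporter1-selective`` / ``reporter2-selective``: significant on that
      reporter only AND the between-reporter difference significant;
    - ``both-opposite``: significant on both with opposite signs;
    - ``shared-but-stronger-1`` / ``-2``: significant on both, same sign,
      between-reporter difference significant (stronger side named);
    - ``none`` otherwise.
    """
    effects = {}
    signif = {}
    sign = {}
    for name, rep in (("r1", reporter1), ("r2", reporter2)):
        if "control" not in rep or "treatment" not in rep:
            raise ValueError(f"reporter {name}: need control and treatment replicates")
        t = np.asarray(rep["treatment"], dtype=float)
        c = np.asarray(rep["control"], dtype=float)
        if t.size < 3 or c.size < 3:
            raise ValueError("need >= 3 replicates per condition")
        if t.size == c.size:
            p = float(stats.ttest_rel(t, c).pvalue)
        else:
            p = float(stats.ttest_ind(t, c, equal_var=False).pvalue)
        eff = t - c.mean()
        effects[name] = eff
        signif[name] = p < alpha
        sign[name] = np.sign(t.mean() - c.mean())
    p_between = float(stats.ttest_ind(effects["r1"], effects["r2"],
                                      equal_var=False).pvalue)
    between = p_between < alpha
    s1, s2 = signif["r1"], signif["r2"]
    if s1 and s2:
        if sign["r1"] != sign["r2"]:
            return "both-opposite"
        if between:
            stronger = "1" if abs(effects["r1"].mean()) > abs(effects["r2"].mean()) else "2"
            return f"shared-but-stronger-{stronger}"
        return "none"
    if s1 and not s2 and between:
        return "reporter1-selective"
    if s2 and not s1 and between:
        return "reporter2-selective"
    return "none"
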