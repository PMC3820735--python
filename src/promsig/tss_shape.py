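"""Focused vs dispersed promoter classification from 5' read-count profiles.

A promoter is *focused* when at least 90% of its 5' reads fall within
+/-5 bp of the primary TSS (the read-maximal position), relative to the
surrounding 100 bp context centered on that position; otherwise it is
*dispersed*.  Profiles below a minimum read depth are left unclassified —
the ratio is unstable at low depth, so the filter is explicit and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .motif_engine import motif_enrichment

__all__ = [
    "TssReadProfile",
    "ShapeCall",
    "primary_tss",
    "classify_shape",
    "classify_profiles",
    "shape_motif_preference",
    "read_profiles_tsv",
    "write_labels_tsv",
]


@dataclass(frozen=True)
class TssReadProfile:
    """5' read counts at TSS-relative positions for one promoter."""

    promoter_id: str
    positions: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.counts):
            raise ValueError("positions and counts must align")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError(f"profile {self.promoter_id!r}: duplicate positions")
        if any(c < 0 for c in self.counts):
            raise ValueError(f"profile {self.promoter_id!r}: negative counts")

    @property
    def total(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class ShapeCall:
    promoter_id: str
    label: str        # focused | dispersed | unclassified
    ratio: float | None
    total_reads: int


def primary_tss(profile: TssReadProfile) -> int:
    """The read-maximal position; ties go to the most 5' (smallest) one."""
    if profile.total < 1:
        raise ValueError(f"profile {profile.promoter_id!r} has no reads")
    best_pos, best_count = None, -1
    for pos, count in sorted(zip(profile.positions, profile.counts)):
        if count > best_count:
            best_pos, best_count = pos, count
    return best_pos


def classify_shape(
    profile: TssReadProfile,
    focus_halfwidth: int = 5,
    context_width: int = 100,
    threshold: float = 0.90,
    min_reads: int = 10,
) -> ShapeCall:
    """Focused/dispersed call for one profile.

    With t = primary TSS, ratio = reads in [t-5, t+5] (11 positions) over
    reads in the 100-position context [t-50, t+49]; focused iff
    ratio >= threshold (the 90% boundary is inclusive).  Profiles with
    fewer than ``min_reads`` reads in the context window are unclassified.
    """
    if profile.total < 1:
        return ShapeCall(profile.promoter_id, "unclassified", None, 0)
    t = primary_tss(profile)
    lo, hi = t - context_width // 2, t + context_width - context_width // 2 - 1
    context = focus = 0
    for pos, count in zip(profile.positions, profile.counts):
        if lo <= pos <= hi:
            context += count
            if t - focus_halfwidth <= pos <= t + focus_halfwidth:
                focus += count
    if context < min_reads:
        return ShapeCall(profile.promoter_id, "unclassified", None, context)
    ratio = focus / context
    label = "focused" if ratio >= threshold else "dispersed"
    return ShapeCall(profile.promoter_id, label, ratio, context)


def classify_profiles(profiles, **kwargs) -> dict[str, ShapeCall]:
    return {p.promoter_id: classify_shape(p, **kwargs) for p in profiles}


def shape_motif_preference(
    labels: dict[str, str], occurrence: pd.DataFrame, alpha: float | None = None
) -> pd.DataFrame:
    """Per-class motif enrichment, focused vs dispersed.

    For each class, each motif's directional hypergeometric enrichment uses
    the other class as background (signed -log10 p); unclassified promoters
    are excluded.  Both classes must be non-empty.
    """
    focused = [p for p, lab in labels.items() if lab == "focused"]
    dispersed = [p for p, lab in labels.items() if lab == "dispersed"]
    if not focused or not dispersed:
        raise ValueError("both focused and dispersed classes must be non-empty")
    presence = occurrence.loc[focused + dispersed] >= 1
    out = {}
    for class_name, fg_ids, bg_ids in (
        ("focused", focused, dispersed),
        ("dispersed", dispersed, focused),
    ):
        fg = presence.loc[fg_ids]
        bg = presence.loc[bg_ids]
        vals = {}
        for motif in occurrence.columns:
            res = motif_enrichment(motif, len(fg), int(fg[motif].sum()),
                                   len(bg), int(bg[motif].sum()))
            v = res.signed_neg_log_p
            if alpha is not None and min(res.p_enrich, res.p_deplete) > alpha:
                v = 0.0
            vals[motif] = v
        out[class_name] = vals
    return pd.DataFrame(out).T


def read_profiles_tsv(path) -> list[TssReadProfile]:
    """Read profiles from TSV (promoter_id, relative_position, count)."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for pid, grp in df.groupby("promoter_id", sort=False):
        profiles.append(TssReadProfile(
            str(pid),
            tuple(int(p) for p in grp["relative_position"]),
            tuple(int(c) for c in grp["count"]),
        ))
    return profiles


def write_labels_tsv(calls: dict[str, ShapeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("promoter_id\tlabel\tratio\ttotal_reads\n")
        for pid, call in calls.items():
            ratio = "" if call.ratio is None else f"{call.ratio:.6f}"
            fh.write(f"{pid}\t{call.label}\t{ratio}\t{call.total_reads}\n")
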