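"""ChIP peak positioning relative to TSSs, genomic-category annotation,
promoter-window overlap (Venn) counting, and signal meta-profiles.

A peak's location is its summit when one is provided, else the interval
midpoint (integer floor).  Peaks are assigned to the nearest TSS on their
contig; equidistant ties go to the lower-coordinate TSS.
"""

from __future__ import annotations

import collections
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import GenomicInterval, PromoterCatalog, PromoterWindow

__all__ = [
    "PeakSet",
    "PeakAssignment",
    "PositionalHistogram",
    "VennCounts",
    "assign_peaks_to_promoters",
    "positional_histogram",
    "annotate_peaks",
    "overlap_sets",
    "windows_hit",
    "meta_profile",
]


@dataclass
class PeakSet:
    """A named ChIP peak list; ``summits`` maps peak index -> genomic summit."""

    name: str
    peaks: list[GenomicInterval]
    summits: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def location(self, i: int) -> int:
        """Peak center: summit if present, else interval midpoint (floor)."""
        return self.summits.get(i, self.peaks[i].center)


@dataclass(frozen=True)
class PeakAssignment:
    peak_index: int
    promoter_id: str | None
    tss_relative_offset: int | None  # signed in gene orientation
    in_window: bool


@dataclass
class PositionalHistogram:
    """Peak percentages over TSS-distance bins (sums to 100)."""

    labels: list[str]
    percentages: np.ndarray
    counts: np.ndarray
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.labels, "count": self.counts, "percent": self.percentages}
        )


@dataclass
class VennCounts:
    """Exclusive/intersection window counts for 2–3 peak sets.

    ``regions`` maps a frozenset of set names to the number of promoter
    windows positive for exactly those sets.
    """

    set_names: list[str]
    regions: dict[frozenset, int]
    universe_note: str

    def count(self, *names: str) -> int:
        """Windows positive for at least all of ``names`` (inclusive count)."""
        want = frozenset(names)
        return sum(c for k, c in self.regions.items() if want <= k)

    def exclusive(self, *names: str) -> int:
        return self.regions.get(frozenset(names), 0)

    def to_dict(self) -> dict:
        return {
            "sets": self.set_names,
            "regions": {"+".join(sorted(k)): v for k, v in self.regions.items()},
            "universe": self.universe_note,
        }


def _tss_arrays(catalog: PromoterCatalog):
    by_contig: dict[str, list[tuple[int, str, str]]] = collections.defaultdict(list)
    for pid, _gid, contig, tss, strand in catalog:
        by_contig[contig].append((tss, pid, strand))
    return {
        c: sorted(v, key=lambda t: (t[0], t[1])) for c, v in by_contig.items()
    }


def assign_peaks_to_promoters(
    peaks: PeakSet,
    catalog: PromoterCatalog,
    windows: dict[str, PromoterWindow],
) -> list[PeakAssignment]:
    """Assign each peak (by its center) to the nearest TSS on its contig.

    The TSS-relative offset is signed in gene orientation (positive =
    downstream of the TSS).  ``in_window`` is True iff the center lies in
    that promoter's window.  Peaks on contigs absent from the catalog are
    returned unassigned with a warning.
    """
    if len(catalog) == 0:
        raise ValueError("empty promoter catalog")
    tss_by_contig = _tss_arrays(catalog)
    sorted_pos = {c: np.array([t[0] for t in v]) for c, v in tss_by_contig.items()}
    out: list[PeakAssignment] = []
    missing_contigs = set()
    for i, peak in enumerate(peaks.peaks):
        center = peaks.location(i)
        entries = tss_by_contig.get(peak.contig)
        if not entries:
            missing_contigs.add(peak.contig)
            out.append(PeakAssignment(i, None, None, False))
            continue
        pos = sorted_pos[peak.contig]
        j = int(np.searchsorted(pos, center))
        # candidates around the insertion point; tie -> lower coordinate
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(entries):
                d = abs(center - entries[cand][0])
                if best is None or d < best[0]:
                    best = (d, cand)
        tss, pid, strand = entries[best[1]]
        offset = center - tss if strand == "+" else tss - center
        win = windows.get(pid)
        in_window = (
            win is not None
            and win.interval.contig == peak.contig
            and win.interval.start <= center < win.interval.end
        )
        out.append(PeakAssignment(i, pid, offset, in_window))
    if missing_contigs:
        warnings.warn(
            f"peaks on contigs absent from catalog left unassigned: "
            f"{sorted(missing_contigs)}"
        )
    return out


def positional_histogram(
    peaks: PeakSet,
    catalog: PromoterCatalog,
    windows: dict[str, PromoterWindow],
    window_label: str = "-150/+50",
    combine_distal: bool = False,
) -> PositionalHistogram:
    """Percentage of peaks per TSS-distance range.

    Bins: the promoter window itself; 200 bp bins out to +/-2 kb; 1 kb bins
    out to +/-10 kb; one aggregate bin beyond +/-10 kb per side (or a single
    combined distal bin when ``combine_distal``).  Offsets are signed in
    gene orientation, with the window bin taking priority.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks to bin")
    assignments = assign_peaks_to_promoters(peaks, catalog, windows)

    edges: list[tuple[float, float, str]] = []
    for lo in range(-2000, 2000, 200):
        edges.append((lo, lo + 200, f"{lo}:{lo + 200}"))
    for lo in range(-10000, -2000, 1000):
        edges.append((lo, lo + 1000, f"{lo}:{lo + 1000}"))
    for lo in range(2000, 10000, 1000):
        edges.append((lo, lo + 1000, f"{lo}:{lo + 1000}"))
    if combine_distal:
        distal = [(-np.inf, -10000, "beyond +/-10kb"), (10000, np.inf, "beyond +/-10kb")]
    else:
        distal = [(-np.inf, -10000, "< -10kb"), (10000, np.inf, "> +10kb")]
    edges += distal

    labels = [window_label] + sorted({lab for _, _, lab in edges},
                                     key=lambda s: next(lo for lo, _, l2 in edges if l2 == s))
    counts = collections.Counter()
    total = 0
    for asg in assignments:
        if asg.promoter_id is None:
            continue
        total += 1
        if asg.in_window:
            counts[window_label] += 1
            continue
        off = asg.tss_relative_offset
        for lo, hi, lab in edges:
            if lo <= off < hi:
                counts[lab] += 1
                break
    if total == 0:
        raise ValueError("no assignable peaks")
    cnt = np.array([counts.get(lab, 0) for lab in labels])
    return PositionalHistogram(labels, 100.0 * cnt / total, cnt, total)


def annotate_peaks(
    peaks: PeakSet,
    gene_models: list[dict],
    promoter_flank: tuple[int, int] = (1000, 100),
    tts_flank: tuple[int, int] = (100, 1000),
) -> dict[str, float]:
    """Fraction of peaks per genomic category.

    ``gene_models`` entries carry contig, strand, tss, tts, and exon
    (start, end) pairs.  Category by peak center with priority
    promoter > TTS > exon > intron > intergenic; the promoter flank is
    [TSS-1000, TSS+100] and the TTS flank [TTS-100, TTS+1000], both in gene
    orientation and configurable.
    """
    categories = ["promoter", "TTS", "exon", "intron", "intergenic"]
    if not gene_models:
        warnings.warn("empty gene annotation: all peaks intergenic")
        return {c: (1.0 if c == "intergenic" else 0.0) for c in categories}
    counts = dict.fromkeys(categories, 0)
    for i, peak in enumerate(peaks.peaks):
        center = peaks.location(i)
        best = "intergenic"
        rank = {c: r for r, c in enumerate(categories)}
        for gm in gene_models:
            if gm["contig"] != peak.contig:
                continue
            strand = gm.get("strand", "+")
            sign = 1 if strand == "+" else -1
            rel_tss = sign * (center - gm["tss"])
            rel_tts = sign * (center - gm["tts"])
            cat = None
            if -promoter_flank[0] <= rel_tss <= promoter_flank[1]:
                cat = "promoter"
            elif -tts_flank[0] <= rel_tts <= tts_flank[1]:
                cat = "TTS"
            else:
                lo, hi = sorted((gm["tss"], gm["tts"]))
                if lo <= center <= hi:
                    cat = "exon" if any(
                        s <= center < e for s, e in gm.get("exons", [])
                    ) else "intron"
            if cat is not None and rank[cat] < rank[best]:
                best = cat
        counts[best] += 1
    total = max(len(peaks), 1)
    return {c: counts[c] / total for c in categories}


def windows_hit(
    peaks: PeakSet,
    windows: dict[str, PromoterWindow],
    catalog: PromoterCatalog | None = None,
    polii_mode: bool = False,
    max_tss_distance: int = 1000,
) -> set[str]:
    """Promoter windows positive for a peak set.

    Default: a window is positive iff >= 1 peak center falls inside it.
    ``polii_mode`` instead counts a promoter positive when a peak center
    lies within ``max_tss_distance`` of its TSS (the wider overlap rule used
    for RNA PolII).
    """
    centers_by_contig: dict[str, list[int]] = collections.defaultdict(list)
    for i in range(len(peaks)):
        centers_by_contig[peaks.peaks[i].contig].append(peaks.location(i))
    for c in centers_by_contig:
        centers_by_contig[c].sort()
    hit: set[str] = set()
    if polii_mode:
        if catalog is None:
            raise ValueError("polii_mode requires the catalog (TSS positions)")
        for pid, _gid, contig, tss, _strand in catalog:
            centers = centers_by_contig.get(contig, [])
            j = int(np.searchsorted(centers, tss))
            for cand in (j - 1, j):
                if 0 <= cand < len(centers) and abs(centers[cand] - tss) <= max_tss_distance:
                    hit.add(pid)
                    break
        return hit
    for pid, win in windows.items():
        iv = win.interval
        centers = centers_by_contig.get(iv.contig, [])
        j = int(np.searchsorted(centers, iv.start))
        if j < len(centers) and centers[j] < iv.end:
            hit.add(pid)
    return hit


def overlap_sets(
    peak_sets: list[PeakSet],
    windows: dict[str, PromoterWindow],
    catalog: PromoterCatalog | None = None,
    polii_sets: tuple[str, ...] = (),
    max_tss_distance: int = 1000,
) -> VennCounts:
    """Venn counts of 2–3 peak sets, counted in promoter-window units.

    A window is positive for a set iff >= 1 peak center falls inside it;
    intersections are by window identity.  Sets named in ``polii_sets`` use
    the within-``max_tss_distance``-of-TSS rule instead.
    """
    if not 2 <= len(peak_sets) <= 3:
        raise ValueError("overlap_sets handles 2 or 3 peak sets; use tables beyond that")
    names = [ps.name for ps in peak_sets]
    if len(set(names)) != len(names):
        raise ValueError("peak set names must be unique")
    membership = {
        ps.name: windows_hit(
            ps, windows, catalog=catalog,
            polii_mode=ps.name in polii_sets,
            max_tss_distance=max_tss_distance,
        )
        for ps in peak_sets
    }
    regions: dict[frozenset, int] = {}
    all_windows = set().union(*membership.values())
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set(all_windows)
            for n in combo:
                inside &= membership[n]
            for n in names:
                if n not in combo:
                    inside -= membership[n]
            regions[frozenset(combo)] = len(inside)
    return VennCounts(
        names, regions,
        universe_note=f"promoter windows (n={len(windows)}); unit = window identity",
    )


def meta_profile(
    coverage: dict[str, np.ndarray],
    anchors: list[tuple[str, int, str]],
    half_width: int = 3000,
    bin_size: int = 25,
) -> pd.DataFrame:
    """Anchor-centered mean signal profile.

    ``coverage`` maps contig -> per-base signal array; ``anchors`` are
    (contig, position, strand) peak centers; minus-strand anchors are
    flipped so the profile reads in gene orientation.  Bins that fall off a
    contig edge are excluded from that bin's mean (count-weighted).
    """
    if not anchors:
        raise ValueError("no anchors")
    n_bins = (2 * half_width) // bin_size
    sums = np.zeros(n_bins)
    weights = np.zeros(n_bins)
    for contig, pos, strand in anchors:
        sig = coverage.get(contig)
        if sig is None:
            continue
        window = np.full(2 * half_width, np.nan)
        lo, hi = pos - half_width, pos + half_width
        src_lo, src_hi = max(lo, 0), min(hi, len(sig))
        if src_lo < src_hi:
            window[src_lo - lo : src_hi - lo] = sig[src_lo:src_hi]
        if strand == "-":
            window = window[::-1]
        binned = window.reshape(n_bins, bin_size)
        valid = ~np.isnan(binned)
        sums += np.where(valid, binned, 0.0).sum(axis=1)
        weights += valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(weights > 0, sums / weights, np.nan)
    centers = np.arange(n_bins) * bin_size - half_width + bin_size // 2
    return pd.DataFrame({"position": centers, "mean_signal": mean})
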