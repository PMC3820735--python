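"""Cardinal motif representation, window scanning, GC-matched background
sampling, and hypergeometric motif enrichment.

The default library holds the nine cardinal promoter elements (TATA,
Sp1/GC-rich, NFY/CCAAT, ETS/GABP, NRF1, CREB/E-box, YY1, Clus1, GFY) as
IUPAC consensus strings with exact matching.  The NRF1 and NFY entries are
anchored by sequence fragments with known match behavior (the 3x NRF1
wild-type/mutant reporter inserts and the 3x NFY/CCAAT insert); the other
seven are documented literature consensi and deliberately overridable —
version the library file if you change them.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import PromoterWindow, reverse_complement

__all__ = [
    "Motif",
    "MotifHit",
    "EnrichmentResult",
    "DEFAULT_MOTIF_LIBRARY",
    "default_motif_library",
    "read_motif_library",
    "write_motif_library",
    "scan_sequence",
    "build_occurrence_matrix",
    "presence_matrix",
    "gc_fraction",
    "sample_gc_matched_background",
    "hypergeom_tails",
    "motif_enrichment",
]

# IUPAC code -> set of concrete bases it stands for
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Motif:
    """A consensus motif matched exactly (up to ``max_mismatches``).

    A sequence base matches a consensus position iff it is one of the
    concrete bases the IUPAC code stands for; a sequence ``N`` matches only
    a consensus ``N``.
    """

    name: str
    consensus: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        object.__setattr__(self, "consensus", cons)
        if len(cons) < 4:
            raise ValueError(f"motif {self.name!r}: consensus shorter than 4")
        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name!r}: non-IUPAC codes {sorted(bad)}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    promoter_id: str
    motif: str
    offset: int          # 0-based, forward orientation of the scanned string
    strand: str          # strand of the match relative to the scanned string
    mismatches: int


@dataclass(frozen=True)
class EnrichmentResult:
    """Directional hypergeometric enrichment of one motif, foreground vs
    background promoter sets."""

    motif: str
    fg_n: int
    fg_k: int
    bg_n: int
    bg_k: int
    p_enrich: float
    p_deplete: float
    direction: str       # "+" iff observed >= expected under the null
    neg_log_p: float     # -log10 of the directional p

    @property
    def signed_neg_log_p(self) -> float:
        return self.neg_log_p if self.direction == "+" else -self.neg_log_p


# Literature consensus strings for the nine cardinal promoter elements.
# NRF1 (RCGCRTGCGY) matches the FMR1-derived site TGCGCATGCGCAG and rejects
# its binding-disrupting mutant TGTTTATTTTCAG; NFY (RRCCAAT) matches the
# ATTGG/CCAAT context on the reverse strand of the canonical 3x insert.
_DEFAULT_MOTIFS = [
    ("TATA", "TATAWAWR"),
    ("Sp1", "GGGGCGGGG"),
    ("NFY", "RRCCAAT"),
    ("ETS", "RCCGGAAGY"),
    ("NRF1", "RCGCRTGCGY"),
    ("CREB", "TGACGTCA"),
    ("YY1", "GCCATNTT"),
    ("Clus1", "TCTCGCGAGA"),
    ("GFY", "ACTACAATTCCC"),
]

DEFAULT_MOTIF_LIBRARY: list[Motif] = [Motif(n, c) for n, c in _DEFAULT_MOTIFS]


def default_motif_library() -> list[Motif]:
    """A fresh copy of the shipped nine-motif cardinal library."""
    return [Motif(n, c) for n, c in _DEFAULT_MOTIFS]


def read_motif_library(path) -> list[Motif]:
    """Read a tab-delimited library (name, consensus[, max_mismatches])."""
    motifs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            mm = int(fields[2]) if len(fields) > 2 else 0
            motifs.append(Motif(fields[0], fields[1], mm))
    if not motifs:
        raise ValueError(f"no motifs in {path}")
    return motifs


def write_motif_library(motifs: list[Motif], path) -> None:
    with open(path, "w") as fh:
        fh.write("# promsig motif library v1\n")
        for m in motifs:
            fh.write(f"{m.name}\t{m.consensus}\t{m.max_mismatches}\n")


def _matches_at(seq: str, cons: str, pos: int, max_mm: int) -> int | None:
    """Mismatch count if cons matches seq at pos within max_mm, else None."""
    mm = 0
    for i, code in enumerate(cons):
        base = seq[pos + i]
        if base == "N":
            if code != "N":
                return None
        elif base not in IUPAC[code]:
            mm += 1
            if mm > max_mm:
                return None
    return mm


def scan_sequence(
    sequence: str,
    motif: Motif,
    both_strands: bool = True,
    promoter_id: str = "",
) -> list[MotifHit]:
    """All match offsets of ``motif`` in ``sequence`` (deterministic
    left-to-right order; overlapping matches all reported).

    Reverse-strand matches are reported at the forward-orientation offset of
    the match's leftmost base.  A motif longer than the sequence yields an
    empty result.
    """
    seq = sequence.upper()
    L = len(motif)
    hits: list[MotifHit] = []
    cons_fwd = motif.consensus
    cons_rev = reverse_complement(motif.consensus) if both_strands else None
    for pos in range(len(seq) - L + 1):
        mm = _matches_at(seq, cons_fwd, pos, motif.max_mismatches)
        if mm is not None:
            hits.append(MotifHit(promoter_id, motif.name, pos, "+", mm))
        elif cons_rev is not None:
            mm = _matches_at(seq, cons_rev, pos, motif.max_mismatches)
            if mm is not None:
                hits.append(MotifHit(promoter_id, motif.name, pos, "-", mm))
    return hits


def build_occurrence_matrix(
    window_sequences: dict[str, str],
    motif_library: list[Motif],
    both_strands: bool = True,
) -> pd.DataFrame:
    """Promoter x motif occurrence-count matrix (``counts >= 1`` is presence).

    Rows follow the input promoter order, columns the library order.
    """
    names = [m.name for m in motif_library]
    dupes = [n for n, c in collections.Counter(names).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate motif names {dupes}")
    data = np.zeros((len(window_sequences), len(names)), dtype=int)
    for i, (pid, seq) in enumerate(window_sequences.items()):
        for j, motif in enumerate(motif_library):
            data[i, j] = len(scan_sequence(seq, motif, both_strands, pid))
    return pd.DataFrame(data, index=list(window_sequences), columns=names)


def presence_matrix(occurrence: pd.DataFrame) -> pd.DataFrame:
    """Boolean presence matrix derived from an occurrence-count matrix."""
    return occurrence >= 1


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return (s.count("G") + s.count("C") + s.count("S")) / len(s)


def sample_gc_matched_background(
    windows: dict[str, PromoterWindow],
    genome: dict[str, str],
    ratio: float = 2.0,
    gc_bin_width: float = 0.025,
    seed: int = 0,
    max_tries: int = 200,
    include_clipped: bool = False,
) -> dict[str, str]:
    """Sample background windows from the genome matched for GC% to the
    foreground windows.

    Background windows have the foreground window length, avoid positions
    overlapping any foreground window, and reproduce the foreground per-GC-bin
    histogram scaled by ``ratio``.  A bin still short after
    ``max_tries * demand`` draws is relaxed by one neighboring bin (with a
    warning); if still unsatisfiable an error is raised.  Sampling is
    reproducible under ``seed``.
    """
    import warnings

    from .genomic_io import window_sequence

    rng = np.random.default_rng(seed)
    fg = {
        pid: w for pid, w in windows.items() if include_clipped or not w.clipped
    }
    if not fg:
        raise ValueError("no unclipped foreground windows")
    lengths = {len(w.interval) for w in fg.values()}
    length = max(lengths)
    fg_seqs = window_sequence(fg, genome)

    def gc_bin(gc: float) -> int:
        return min(int(gc / gc_bin_width), int(round(1 / gc_bin_width)) - 1)

    demand: dict[int, int] = collections.Counter()
    for seq in fg_seqs.values():
        demand[gc_bin(gc_fraction(seq))] += 1
    demand = {b: int(round(c * ratio)) for b, c in demand.items()}

    # foreground-occupied positions, per contig, for overlap exclusion
    occupied: dict[str, set[int]] = collections.defaultdict(set)
    for w in windows.values():
        occupied[w.interval.contig].update(
            range(w.interval.start, w.interval.end)
        )

    contigs = sorted(genome)
    weights = np.array([max(len(genome[c]) - length + 1, 0) for c in contigs], float)
    if weights.sum() <= 0:
        raise ValueError("genome contigs shorter than the window length")
    weights /= weights.sum()

    got: dict[int, list[tuple[str, int]]] = collections.defaultdict(list)
    need_total = sum(demand.values())
    tries_budget = max_tries * max(need_total, 1)
    tries = 0
    while sum(min(len(got[b]), n) for b, n in demand.items()) < need_total:
        if tries >= tries_budget:
            break
        tries += 1
        ci = rng.choice(len(contigs), p=weights)
        contig = contigs[ci]
        start = int(rng.integers(0, len(genome[contig]) - length + 1))
        if occupied[contig] and not occupied[contig].isdisjoint(
            range(start, start + length)
        ):
            continue
        seq = genome[contig][start : start + length]
        b = gc_bin(gc_fraction(seq))
        if b in demand and len(got[b]) < demand[b]:
            got[b].append((contig, start))

    background: dict[str, str] = {}
    idx = 0
    for b in sorted(demand):
        hits = got[b]
        short = demand[b] - len(hits)
        if short > 0:
            # relax by one neighboring bin: borrow surplus draws
            warnings.warn(
                f"GC bin {b * gc_bin_width:.3f} short by {short}; "
                "relaxing to neighboring bins"
            )
            for nb in (b - 1, b + 1):
                spare = got.get(nb, [])
                while short > 0 and len(spare) > demand.get(nb, 0):
                    hits.append(spare.pop())
                    short -= 1
            if short > 0:
                raise RuntimeError(
                    f"cannot satisfy GC bin {b * gc_bin_width:.3f} "
                    f"(short {short}) even after neighbor relaxation"
                )
        for contig, start in hits[: demand[b]]:
            background[f"bg{idx:06d}"] = genome[contig][start : start + length]
            idx += 1
    return background


def hypergeom_tails(N: int, K: int, n: int, x: int) -> tuple[float, float]:
    """(P(X >= x), P(X <= x)) for X ~ Hypergeometric(N, K, n).

    N = population size, K = successes in the population, n = draws,
    x = observed successes among the draws.
    """
    upper = float(stats.hypergeom.sf(x - 1, N, K, n))
    lower = float(stats.hypergeom.cdf(x, N, K, n))
    return min(max(upper, 0.0), 1.0), min(max(lower, 0.0), 1.0)


def motif_enrichment(
    motif: str, fg_n: int, fg_k: int, bg_n: int, bg_k: int
) -> EnrichmentResult:
    """Directional hypergeometric enrichment of a motif in a foreground
    promoter set against a background set.

    The union of the two sets is the urn (N = fg_n + bg_n promoters,
    K = fg_k + bg_k motif-positive); the foreground is the draw.
    """
    if fg_n < 1 or bg_n < 1:
        raise ValueError("need at least one promoter in each set")
    if fg_k > fg_n or bg_k > bg_n or min(fg_k, bg_k) < 0:
        raise ValueError("require 0 <= k <= n for both sets")
    N, K, n, x = fg_n + bg_n, fg_k + bg_k, fg_n, fg_k
    p_enrich, p_deplete = hypergeom_tails(N, K, n, x)
    direction = "+" if x >= n * K / N else "-"
    p_dir = p_enrich if direction == "+" else p_deplete
    p_dir = max(p_dir, 1e-300)
    return EnrichmentResult(
        motif, fg_n, fg_k, bg_n, bg_k, p_enrich, p_deplete,
        direction, -float(np.log10(p_dir)),
    )
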