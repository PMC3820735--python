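"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

- promoter windows with cardinal motifs planted at configurable marginal
  frequencies and pairwise dependence (odds ratios, via a Gaussian-copula
  threshold model), embedded in an i.i.d. background genome of controlled
  GC content;
- ChIP peak sets whose per-promoter binding probability is conditioned on
  planted motif presence, with Gaussian positional jitter around the TSS
  and optional distal background peaks;
- 5' read profiles drawn from a focused (tight, sd = 1) vs dispersed
  (uniform over 80 bp) mixture;
- two-treatment expression tables with genes planted into response
  Classes I–VIII.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .genomic_io import (
    GenomicInterval,
    PromoterCatalog,
    extract_promoter_windows,
    reverse_complement,
    window_sequence,
    write_bed,
    write_fasta,
    write_tss_catalog,
)
from .motif_engine import IUPAC, Motif, default_motif_library
from .peak_analysis import PeakSet
from .tss_shape import TssReadProfile

__all__ = [
    "BindingModel",
    "ExpressionDesign",
    "TssShapeMixture",
    "SimulationConfig",
    "GroundTruth",
    "joint_from_odds_ratio",
    "copula_correlation",
    "sample_presence",
    "generate_genome",
    "generate_promoters",
    "generate_peaks",
    "generate_tss_profiles",
    "generate_expression",
    "simulate_all",
]


@dataclass(frozen=True)
class BindingModel:
    """Per-factor promoter binding probabilities.

    A promoter is bound with ``conditional_rates[motif]`` when it carries
    that motif (the highest applicable rate wins), else ``base_rate``.
    Peak centers sit at TSS + Normal(0, jitter_sd), rounded.
    """

    base_rate: float = 0.01
    conditional_rates: dict[str, float] = field(default_factory=dict)
    jitter_sd: float = 50.0
    distal_rate_per_mb: float = 0.0


@dataclass(frozen=True)
class TssShapeMixture:
    """Focused/dispersed 5' profile mixture.

    Focused promoters concentrate reads in a discretized Normal(mode, sd=1);
    dispersed promoters spread them uniformly over ``dispersed_width``
    positions.  Mixture weights follow the observed promoter-shape split
    (35% focused / 65% dispersed).
    """

    focused_weight: float = 0.35
    focused_sd: float = 1.0
    dispersed_width: int = 80
    reads_per_promoter: int = 50


@dataclass(frozen=True)
class ExpressionDesign:
    """Two-treatment expression layout with planted Class I–VIII genes."""

    class_sizes: dict[str, int] = field(default_factory=lambda: {
        "I": 100, "II": 100, "III": 100, "IV": 100,
        "V": 100, "VI": 100, "VII": 100, "VIII": 100,
    })
    n_unaffected: int = 800
    effect: float = 1.5          # |log2 fold change| of a planted response
    noise_sd: float = 0.2
    replicates: int = 3
    baseline: float = 8.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full study-condition description; with a seed it fixes every output."""

    n_promoters: int = 2000
    upstream: int = 150
    downstream: int = 50
    gc_content: float = 0.5
    promoter_spacing: int = 2000
    marginals: dict[str, float] = field(default_factory=lambda: {
        "TATA": 0.10, "Sp1": 0.25, "NFY": 0.15, "ETS": 0.15, "NRF1": 0.10,
        "CREB": 0.10, "YY1": 0.05, "Clus1": 0.05, "GFY": 0.05,
    })
    odds_ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    copy_number: dict[int, float] = field(default_factory=lambda: {
        1: 0.8, 2: 0.15, 3: 0.05,
    })
    binding_models: dict[str, BindingModel] = field(default_factory=lambda: {
        "NRF1_TF": BindingModel(0.01, {"NRF1": 0.60}, 50.0),
        "NFYB": BindingModel(0.01, {"NFY": 0.55}, 50.0),
        "LSD1": BindingModel(0.02, {"NRF1": 0.60}, 60.0),
    })
    tss_shape: TssShapeMixture = field(default_factory=TssShapeMixture)
    expression: ExpressionDesign = field(default_factory=ExpressionDesign)

    @property
    def window_length(self) -> int:
        return self.upstream + self.downstream

    def motif_names(self) -> list[str]:
        return list(self.marginals)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))
        d = dataclasses.asdict(self)
        d["odds_ratios"] = {"|".join(k): v for k, v in self.odds_ratios.items()}
        return json.dumps(d, indent=2, default=enc, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted truth, consistent with the emitted files."""

    motif_presence: pd.DataFrame | None = None     # promoter x motif bool
    motif_copies: pd.DataFrame | None = None       # promoter x motif int
    bound_promoters: dict[str, set[str]] = field(default_factory=dict)
    shape_labels: dict[str, str] = field(default_factory=dict)
    gene_classes: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# presence model: marginals + pairwise odds ratios via a Gaussian copula

def joint_from_odds_ratio(p_a: float, p_b: float, odds_ratio: float) -> float:
    """P(A and B) for the 2x2 table with the given marginals and odds ratio."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be > 0")
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    if odds_ratio == 1.0:
        p11 = p_a * p_b
    else:
        a = odds_ratio - 1.0
        b = -((odds_ratio - 1.0) * (p_a + p_b) + 1.0)
        c = odds_ratio * p_a * p_b
        disc = b * b - 4 * a * c
        if disc < 0:
            raise ValueError(f"infeasible marginals/odds ratio ({p_a}, {p_b}, {odds_ratio})")
        root = (-b - np.sqrt(disc)) / (2 * a)
        p11 = float(root)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError(
            f"infeasible joint probability for marginals ({p_a}, {p_b}) "
            f"and odds ratio {odds_ratio}"
        )
    return float(np.clip(p11, lo, hi))


def copula_correlation(p_a: float, p_b: float, p11: float) -> float:
    """Gaussian correlation rho with P(Z1 > za, Z2 > zb) = p11, where
    za, zb are the upper-p_a / upper-p_b normal quantiles."""
    za, zb = stats.norm.isf(p_a), stats.norm.isf(p_b)

    def upper_joint(rho: float) -> float:
        cov = [[1.0, rho], [rho, 1.0]]
        return float(stats.multivariate_normal(cov=cov, allow_singular=True)
                     .cdf([-za, -zb]))

    target = p11
    f_lo, f_hi = upper_joint(-0.999) - target, upper_joint(0.999) - target
    if abs(f_lo) < 1e-12:
        return -0.999
    if abs(f_hi) < 1e-12:
        return 0.999
    if f_lo * f_hi > 0:
        raise ValueError("no Gaussian correlation reproduces the requested joint")
    return float(brentq(lambda r: upper_joint(r) - target, -0.999, 0.999,
                        xtol=1e-10))


def _correlation_matrix(config: SimulationConfig) -> np.ndarray:
    names = config.motif_names()
    k = len(names)
    R = np.eye(k)
    lookup = {}
    for (a, b), orr in config.odds_ratios.items():
        lookup[frozenset((a, b))] = orr
    for i in range(k):
        for j in range(i + 1, k):
            orr = lookup.get(frozenset((names[i], names[j])), 1.0)
            if orr == 1.0:
                continue
            p11 = joint_from_odds_ratio(config.marginals[names[i]],
                                        config.marginals[names[j]], orr)
            R[i, j] = R[j, i] = copula_correlation(
                config.marginals[names[i]], config.marginals[names[j]], p11)
    eigmin = np.linalg.eigvalsh(R).min()
    if eigmin < -1e-8:
        raise ValueError("requested pairwise odds ratios yield a non-positive-"
                         "definite copula correlation matrix")
    return R


def sample_presence(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Promoter x motif presence booleans under the marginal/odds-ratio model.

    Fast path used by the statistical suites: the same joint law the
    sequence generator plants, without sequence emission.
    """
    rng = np.random.default_rng(seed)
    names = config.motif_names()
    R = _correlation_matrix(config)
    eigval, eigvec = np.linalg.eigh(R)
    L = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None)))
    Z = rng.standard_normal((config.n_promoters, len(names))) @ L.T
    thresholds = stats.norm.isf([config.marginals[n] for n in names])
    presence = Z > thresholds
    index = [f"p{i:05d}" for i in range(config.n_promoters)]
    return pd.DataFrame(presence, index=index, columns=names)


# ---------------------------------------------------------------------------
# sequence-level generation

def generate_genome(
    n_contigs: int, contig_length: int, gc: float, seed: int
) -> dict[str, str]:
    """i.i.d. bases at the stated GC content; reproducible under seed."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return {
        f"chr{i + 1}": "".join(
            bases[rng.choice(4, size=contig_length, p=p)]
        )
        for i in range(n_contigs)
    }


def _resolve_consensus(consensus: str, rng: np.random.Generator) -> str:
    """A concrete instance of an IUPAC consensus (codes resolved uniformly)."""
    return "".join(
        code if code in "ACGT"
        else IUPAC[code][rng.integers(len(IUPAC[code]))]
        for code in consensus
    )


def generate_promoters(
    config: SimulationConfig,
    seed: int,
    motif_library: list[Motif] | None = None,
):
    """Synthetic genome + promoter catalog with planted motif instances.

    TSSs sit at regular spacing along one contig, alternating strand.
    Window sequences are written into the genome in gene orientation, so
    extraction via genomic_io recovers them exactly.  Planted instances
    never straddle window edges; offsets are uniform over valid positions
    and copies do not overlap within a window.

    Returns (genome, catalog, windows, window_seqs, ground_truth).
    """
    if motif_library is None:
        motif_library = default_motif_library()
    by_name = {m.name: m for m in motif_library}
    missing = set(config.marginals) - set(by_name)
    if missing:
        raise ValueError(f"marginals name motifs absent from the library: {missing}")

    rng = np.random.default_rng(seed)
    presence = sample_presence(config, int(rng.integers(2**31)))
    names = config.motif_names()
    W = config.window_length
    spacing = max(config.promoter_spacing, 2 * W + 10)
    contig_length = spacing * (config.n_promoters + 1)
    genome = generate_genome(1, contig_length, config.gc_content,
                             int(rng.integers(2**31)))
    contig = "chr1"
    seq = np.frombuffer(genome[contig].encode(), dtype="S1").copy()

    copies_vals = np.array(list(config.copy_number))
    copies_p = np.array(list(config.copy_number.values()), dtype=float)
    copies_p /= copies_p.sum()

    records = []
    copy_counts = np.zeros((config.n_promoters, len(names)), dtype=int)
    for i, pid in enumerate(presence.index):
        strand = "+" if i % 2 == 0 else "-"
        tss = spacing * (i + 1) if strand == "+" else spacing * (i + 1) - 1
        records.append((pid, f"g{i:05d}", contig, tss, strand))

        # build the window sequence in gene orientation, plant instances
        win = rng.choice(list("ACGT"), size=W, p=[
            (1 - config.gc_content) / 2, config.gc_content / 2,
            config.gc_content / 2, (1 - config.gc_content) / 2,
        ])
        win = list("".join(win))
        taken: list[tuple[int, int]] = []
        for j, name in enumerate(names):
            if not presence.iloc[i, j]:
                continue
            n_copies = int(rng.choice(copies_vals, p=copies_p))
            motif = by_name[name]
            L = len(motif)
            placed = 0
            for _ in range(200):
                if placed >= n_copies:
                    break
                off = int(rng.integers(0, W - L + 1))
                if any(off < e and off + L > s for s, e in taken):
                    continue
                inst = _resolve_consensus(motif.consensus, rng)
                if rng.random() < 0.5:
                    inst = reverse_complement(inst)
                win[off : off + L] = list(inst)
                taken.append((off, off + L))
                placed += 1
            copy_counts[i, j] = placed

        oriented = "".join(win)
        if strand == "+":
            gstart = tss - config.upstream
            genomic = oriented
        else:
            gstart = tss - config.downstream + 1
            genomic = reverse_complement(oriented)
        seq[gstart : gstart + W] = np.frombuffer(genomic.encode(), dtype="S1")

    genome = {contig: seq.tobytes().decode()}
    catalog = PromoterCatalog(records)
    windows = extract_promoter_windows(
        catalog, config.upstream, config.downstream,
        contig_lengths={c: len(s) for c, s in genome.items()},
    )
    window_seqs = window_sequence(windows, genome)
    truth = GroundTruth(
        motif_presence=presence,
        motif_copies=pd.DataFrame(copy_counts, index=presence.index,
                                  columns=names),
    )
    return genome, catalog, windows, window_seqs, truth


def generate_peaks(
    catalog: PromoterCatalog,
    presence: pd.DataFrame,
    binding_models: dict[str, BindingModel],
    seed: int,
    contig_lengths: dict[str, int] | None = None,
    peak_halfwidth: int = 100,
) -> tuple[dict[str, PeakSet], dict[str, set[str]]]:
    """Factor peak sets with binding probability conditioned on motif status.

    Returns (peak sets by factor, bound promoter ids by factor).
    """
    rng = np.random.default_rng(seed)
    tss_by_pid = {pid: (contig, tss, strand)
                  for pid, _g, contig, tss, strand in catalog}
    peak_sets: dict[str, PeakSet] = {}
    bound: dict[str, set[str]] = {}
    for factor, model in binding_models.items():
        if not 0 <= model.base_rate <= 1 or any(
            not 0 <= r <= 1 for r in model.conditional_rates.values()
        ):
            raise ValueError(f"factor {factor!r}: rates must lie in [0, 1]")
        intervals, summits = [], {}
        hit: set[str] = set()
        for pid in presence.index:
            rate = model.base_rate
            for motif, r in model.conditional_rates.items():
                if motif in presence.columns and presence.loc[pid, motif]:
                    rate = max(rate, r)
            if rng.random() >= rate:
                continue
            contig, tss, _strand = tss_by_pid[pid]
            center = int(round(tss + rng.normal(0.0, model.jitter_sd))) \
                if model.jitter_sd > 0 else tss
            start = max(center - peak_halfwidth, 0)
            end = center + peak_halfwidth + 1
            if contig_lengths is not None:
                end = min(end, contig_lengths[contig])
            summits[len(intervals)] = center
            intervals.append(GenomicInterval(contig, start, end, ".",
                                             name=f"{factor}_{pid}"))
            hit.add(pid)
        if model.distal_rate_per_mb > 0 and contig_lengths:
            for contig, length in contig_lengths.items():
                n_bg = rng.poisson(model.distal_rate_per_mb * length / 1e6)
                for _ in range(n_bg):
                    center = int(rng.integers(peak_halfwidth,
                                              length - peak_halfwidth - 1))
                    summits[len(intervals)] = center
                    intervals.append(GenomicInterval(
                        contig, center - peak_halfwidth,
                        center + peak_halfwidth + 1, "."))
        peak_sets[factor] = PeakSet(factor, intervals, summits)
        bound[factor] = hit
    return peak_sets, bound


def generate_tss_profiles(
    promoter_ids,
    mixture: TssShapeMixture,
    seed: int,
) -> tuple[list[TssReadProfile], dict[str, str]]:
    """5' read profiles from the focused/dispersed mixture, plus true labels."""
    rng = np.random.default_rng(seed)
    profiles, labels = [], {}
    half = mixture.dispersed_width // 2
    for pid in promoter_ids:
        focused = rng.random() < mixture.focused_weight
        n_reads = mixture.reads_per_promoter
        if focused:
            positions = np.rint(rng.normal(0.0, mixture.focused_sd,
                                           size=n_reads)).astype(int)
        else:
            positions = rng.integers(-half, mixture.dispersed_width - half,
                                     size=n_reads)
        pos, cnt = np.unique(positions, return_counts=True)
        profiles.append(TssReadProfile(pid, tuple(int(p) for p in pos),
                                       tuple(int(c) for c in cnt)))
        labels[pid] = "focused" if focused else "dispersed"
    return profiles, labels


def generate_expression(
    design: ExpressionDesign, seed: int
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, str]]:
    """Two-treatment expression table with planted Class I–VIII genes.

    Classes shift the treatment arms by +/-effect according to the class
    truth table (treatment A = first knockdown, B = second); replicates are
    independent Normal(., noise_sd) on the log2 scale.

    Returns (table, arm columns, true class per gene).
    """
    shift = {
        "I": (-1, -1), "II": (+1, +1), "III": (-1, +1), "IV": (+1, -1),
        "V": (0, -1), "VI": (0, +1), "VII": (-1, 0), "VIII": (+1, 0),
        "Unaffected": (0, 0),
    }
    total = sum(design.class_sizes.values()) + design.n_unaffected
    plan = []
    for cls, n in design.class_sizes.items():
        if cls not in shift:
            raise ValueError(f"unknown class {cls!r}")
        plan += [cls] * n
    plan += ["Unaffected"] * design.n_unaffected
    if len(plan) != total:
        raise ValueError("class sizes exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(total)]
    arms = {
        "control": [f"ctl_{r + 1}" for r in range(design.replicates)],
        "A": [f"kdA_{r + 1}" for r in range(design.replicates)],
        "B": [f"kdB_{r + 1}" for r in range(design.replicates)],
    }
    data = {}
    truth = dict(zip(genes, plan))
    sa = np.array([shift[c][0] for c in plan], dtype=float) * design.effect
    sb = np.array([shift[c][1] for c in plan], dtype=float) * design.effect
    base = design.baseline + rng.normal(0, 1.0, size=total)
    for col in arms["control"]:
        data[col] = base + rng.normal(0, design.noise_sd, size=total)
    for col in arms["A"]:
        data[col] = base + sa + rng.normal(0, design.noise_sd, size=total)
    for col in arms["B"]:
        data[col] = base + sb + rng.normal(0, design.noise_sd, size=total)
    table = pd.DataFrame(data, index=genes)
    return table, arms, truth


# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, seed: int, outdir) -> dict:
    """Run every generator under one config and emit all files + manifest.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    seeds = {k: int(rng.integers(2**31)) for k in
             ("promoters", "peaks", "profiles", "expression")}

    genome, catalog, windows, window_seqs, truth = generate_promoters(
        config, seeds["promoters"])
    contig_lengths = {c: len(s) for c, s in genome.items()}
    peak_sets, bound = generate_peaks(catalog, truth.motif_presence,
                                      config.binding_models, seeds["peaks"],
                                      contig_lengths)
    truth.bound_promoters = bound
    profiles, shape_labels = generate_tss_profiles(
        catalog.promoter_ids, config.tss_shape, seeds["profiles"])
    truth.shape_labels = shape_labels
    expr, arms, gene_classes = generate_expression(config.expression,
                                                   seeds["expression"])
    truth.gene_classes = gene_classes

    files = {}
    write_fasta(genome, out / "genome.fa")
    files["genome"] = "genome.fa"
    write_tss_catalog(catalog, out / "tss_catalog.tsv")
    files["tss_catalog"] = "tss_catalog.tsv"
    for factor, ps in peak_sets.items():
        path = out / f"peaks_{factor}.bed"
        write_bed(ps.peaks, path)
        files[f"peaks_{factor}"] = path.name
    with open(out / "tss_profiles.tsv", "w") as fh:
        fh.write("promoter_id\trelative_position\tcount\n")
        for p in profiles:
            for pos, cnt in zip(p.positions, p.counts):
                fh.write(f"{p.promoter_id}\t{pos}\t{cnt}\n")
    files["tss_profiles"] = "tss_profiles.tsv"
    expr.to_csv(out / "expression.tsv", sep="\t")
    files["expression"] = "expression.tsv"
    truth.motif_presence.astype(int).to_csv(out / "truth_motif_presence.tsv",
                                            sep="\t")
    files["truth_motif_presence"] = "truth_motif_presence.tsv"
    pd.Series(shape_labels, name="label").rename_axis("promoter_id").to_csv(
        out / "truth_shape_labels.tsv", sep="\t")
    files["truth_shape_labels"] = "truth_shape_labels.tsv"
    pd.Series(gene_classes, name="class").rename_axis("gene_id").to_csv(
        out / "truth_gene_classes.tsv", sep="\t")
    files["truth_gene_classes"] = "truth_gene_classes.tsv"

    config_json = config.to_json()
    manifest = {
        "seed": seed,
        "stage_seeds": seeds,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "arms": arms,
        "files": files,
    }
    (out / "config.json").write_text(config_json)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
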