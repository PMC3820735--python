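"""Experiment x cardinal-motif signature matrices.

Each row of a signature matrix is the vector of directional hypergeometric
motif enrichments (signed -log10 p) for the promoters occupied in one
ChIP experiment, z-scored and mean-centered so that the row expresses the
experiment's *preferences* among motifs rather than its absolute
enrichment level.  Deterministic average-linkage clustering orders the rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .genomic_io import PromoterCatalog
from .motif_engine import motif_enrichment
from .peak_analysis import PeakSet

__all__ = [
    "SignatureMatrix",
    "experiment_promoter_set",
    "enrichment_vector",
    "normalize_center",
    "cluster_rows",
    "de_gene_motif_matrix",
]


@dataclass
class SignatureMatrix:
    """Raw and transformed experiment x motif enrichment scores.

    ``raw`` holds signed -log10 hypergeometric p-values; ``transformed``
    holds the per-row z-scored, mean-centered version (every row mean 0).
    """

    raw: pd.DataFrame
    transformed: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, raw_path, transformed_path) -> None:
        self.raw.to_csv(raw_path, sep="\t")
        self.transformed.to_csv(transformed_path, sep="\t")


def experiment_promoter_set(
    peaks: PeakSet, catalog: PromoterCatalog, max_distance: int = 500
) -> set[str]:
    """Promoters whose TSS lies within ``max_distance`` bp (unsigned genomic
    distance) of any peak center; each promoter counted once."""
    if len(catalog) == 0:
        raise ValueError("empty promoter catalog")
    centers: dict[str, list[int]] = {}
    for i in range(len(peaks)):
        centers.setdefault(peaks.peaks[i].contig, []).append(peaks.location(i))
    for c in centers:
        centers[c].sort()
    subset: set[str] = set()
    for pid, _gid, contig, tss, _strand in catalog:
        cs = centers.get(contig, [])
        j = int(np.searchsorted(cs, tss))
        for cand in (j - 1, j):
            if 0 <= cand < len(cs) and abs(cs[cand] - tss) <= max_distance:
                subset.add(pid)
                break
    if not subset:
        warnings.warn(f"peak set {peaks.name!r}: no promoters within "
                      f"{max_distance} bp of a TSS")
    return subset


def enrichment_vector(
    subset,
    occurrence: pd.DataFrame,
    universe=None,
    alpha: float | None = None,
) -> pd.Series:
    """Signed -log10 directional hypergeometric enrichment per motif for a
    promoter subset against the rest of the universe.

    Foreground = subset presence counts; background = universe minus subset.
    Motifs absent from the universe score 0.  When ``alpha`` is given,
    entries whose directional p exceeds it are zeroed (white).
    """
    subset = set(subset)
    universe_ids = list(occurrence.index) if universe is None else list(universe)
    if not subset:
        raise ValueError("empty promoter subset")
    if not subset <= set(universe_ids):
        raise ValueError("subset must be contained in the universe")
    if len(subset) == len(universe_ids):
        raise ValueError("subset equals universe: no background remains")
    presence = occurrence.loc[universe_ids] >= 1
    in_subset = presence.index.isin(subset)
    fg = presence.loc[in_subset]
    bg = presence.loc[~in_subset]
    values = {}
    for motif in occurrence.columns:
        K = int(presence[motif].sum())
        if K == 0:
            values[motif] = 0.0
            continue
        res = motif_enrichment(motif, len(fg), int(fg[motif].sum()),
                               len(bg), int(bg[motif].sum()))
        v = res.signed_neg_log_p
        if alpha is not None and min(res.p_enrich, res.p_deplete) > alpha:
            v = 0.0
        values[motif] = v
    return pd.Series(values, name="signed_neg_log10_p")


def normalize_center(raw: pd.DataFrame, mode: str = "zscore") -> SignatureMatrix:
    """Per-row normalization followed by mean-centering.

    ``zscore`` (default) divides each row by its standard deviation before
    subtracting the row mean; alternatives are ``unit`` (L2 norm) and
    ``max`` (max absolute value).  Constant rows map to all zeros.
    """
    if raw.shape[0] < 1 or raw.shape[1] < 2:
        raise ValueError("need >= 1 row and >= 2 columns")
    X = raw.to_numpy(dtype=float).copy()
    if mode == "zscore":
        scale = X.std(axis=1, ddof=0)
    elif mode == "unit":
        scale = np.linalg.norm(X, axis=1)
    elif mode == "max":
        scale = np.abs(X).max(axis=1)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    nz = scale > 0
    X[nz] = X[nz] / scale[nz, None]
    X[~nz] = 0.0
    X -= X.mean(axis=1, keepdims=True)
    transformed = pd.DataFrame(X, index=raw.index, columns=raw.columns)
    return SignatureMatrix(
        raw=raw.copy(), transformed=transformed,
        metadata={"normalization": mode, "centered": "row mean subtracted"},
    )


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Leaf order by recursive traversal visiting the smaller subtree first
    (ties by lower node id, i.e. input order)."""

    sizes = {i: 1 for i in range(n)}
    for k, (a, b, _d, size) in enumerate(Z):
        sizes[n + k] = int(size)

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(Z[node - n][0]), int(Z[node - n][1])
        first, second = (a, b)
        if (sizes[b], b) < (sizes[a], a):
            first, second = b, a
        return walk(first) + walk(second)

    return walk(n + len(Z) - 1)


def cluster_rows(
    matrix: pd.DataFrame, metric: str = "euclidean", linkage: str = "average"
) -> tuple[list[str], np.ndarray, str]:
    """Deterministic agglomerative clustering of matrix rows.

    Returns (row order, scipy linkage matrix, Newick string).  Ties are
    broken by input order; leaf order visits the smaller subtree first.
    Rows with non-finite entries are an error.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite entries")
    D = pdist(X, metric=metric)
    Z = hierarchy.linkage(D, method=linkage)
    n = matrix.shape[0]
    order = _leaf_order(Z, n)
    labels = [str(matrix.index[i]) for i in order]

    names = [str(x) for x in matrix.index]

    def newick(node: int, parent_dist: float) -> str:
        if node < n:
            return f"{names[node]}:{parent_dist:.6g}"
        a, b, d, _s = Z[node - n]
        return (f"({newick(int(a), d - _height(int(a)))},"
                f"{newick(int(b), d - _height(int(b)))}):{parent_dist:.6g}")

    def _height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n][2])

    tree = newick(n + len(Z) - 1, 0.0) + ";"
    return labels, Z, tree


def de_gene_motif_matrix(
    gene_sets: dict[str, list[str]],
    occurrence: pd.DataFrame,
    gene_to_promoter: dict[str, str],
    universe=None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Directional motif-enrichment matrix for gene sets (rows) against the
    promoter universe, white (0) where the directional p misses ``alpha``.

    Genes without a mapped promoter in the universe are dropped; the count
    of dropped genes per set is returned alongside.
    """
    universe_ids = set(occurrence.index if universe is None else universe)
    rows, dropped = {}, {}
    for set_name, genes in gene_sets.items():
        promoters = {gene_to_promoter[g] for g in genes if g in gene_to_promoter}
        promoters &= universe_ids
        dropped[set_name] = len(genes) - len(promoters)
        if not promoters:
            raise ValueError(f"gene set {set_name!r} empty after promoter mapping")
        rows[set_name] = enrichment_vector(promoters, occurrence,
                                           universe=universe, alpha=alpha)
    return pd.DataFrame(rows).T, dropped
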