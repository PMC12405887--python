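"""Population-genomic statistics and AU-supported hierarchical clustering.

Covers the SNP side of the analysis: restriction to biallelic
segregating sites, identity-by-state (IBS) distances on diploidized
dosages, nucleotide diversity, windowed homozygous-SNP density, and
hierarchical clustering whose node support is assessed by multiscale
bootstrap (approximately unbiased AU p-values alongside plain bootstrap
proportions BP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .variant_io import GenomeWindows, VariantTable

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative strain-by-strain distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class PopGenSummary:
    n_biallelic_sites: int
    callable_length: int
    pi: float


@dataclass
class HomozygosityMatrix:
    """Raw and per-window-standardized homozygous-alt SNP counts
    (strains x windows)."""

    raw: pd.DataFrame
    scaled: pd.DataFrame


@dataclass
class ClusterTree:
    """Average-linkage dendrogram with per-node AU/BP support.

    ``linkage`` is a scipy linkage matrix over ``labels``; ``clusters``
    maps each internal node id (n_leaves..2*n_leaves-2) to its leaf-label
    frozenset, with matching ``au``/``bp`` support in [0, 1].
    """

    labels: list[str]
    linkage: np.ndarray
    clusters: dict[int, frozenset]
    au: dict[int, float]
    bp: dict[int, float]

    def support_for(self, leaf_set: set[str] | frozenset) -> tuple[float, float] | None:
        """(AU, BP) of the node whose leaf set equals ``leaf_set``; None if
        that cluster is not in the tree."""
        target = frozenset(leaf_set)
        for node, cl in self.clusters.items():
            if cl == target:
                return self.au[node], self.bp[node]
        return None

    def to_newick(self) -> str:
        """Newick string with 'AU|BP' internal node labels (percent units)."""
        n = len(self.labels)

        def fmt(node: int) -> str:
            if node < n:
                return self.labels[node]
            row = self.linkage[node - n]
            left, right = fmt(int(row[0])), fmt(int(row[1]))
            lab = f"{100 * self.au[node]:.0f}|{100 * self.bp[node]:.0f}"
            return f"({left},{right}){lab}:{row[2]:.6g}"

        return fmt(2 * n - 2) + ";"


# ---------------------------------------------------------------------------
# site filtering and classic statistics


def filter_biallelic(table: VariantTable) -> VariantTable:
    """Restrict to biallelic segregating sites.

    A site is kept when exactly two distinct alleles are observed in the
    panel's genotypes and at least two genotype states (hom-ref / het /
    hom-alt after diploidized projection) are present.  Sites whose two
    observed alleles are not (ref, first alt) are recoded so that the
    observed non-reference allele becomes the single alternate.
    """
    keep = []
    recode = {}
    for i in range(table.n_sites):
        alleles = table.gt[i][table.gt[i] >= 0]
        obs = np.unique(alleles)
        if len(obs) != 2:
            continue
        keep.append(i)
        if not (obs[0] == 0 and obs[1] == 1):
            recode[i] = obs
    out = table.take_sites(np.array(keep, dtype=int))
    if recode:
        for j, i in enumerate(keep):
            if i not in recode:
                continue
            a, b = recode[i]
            g = out.gt[j]
            if a == 0:  # ref plus some later alt b
                out.alts[j] = (table.alts[i][b - 1],)
                out.ad_alt[j, :, 0] = table.ad_alt[i, :, b - 1]
                g[g == b] = 1
            else:  # two alt alleles observed, no ref: treat minor as "alt"
                out.alts[j] = (table.alts[i][b - 1],)
                out.ref[j] = table.alts[i][a - 1]
                out.ad_ref[j] = table.ad_alt[i, :, a - 1]
                out.ad_alt[j, :, 0] = table.ad_alt[i, :, b - 1]
                g[g == a] = 0
                g[g == b] = 1
            out.gt[j] = g
    dosage = out.dosage_matrix()
    states = [np.unique(row[row >= 0]) for row in dosage]
    seg = np.array([len(s) >= 2 for s in states])
    out = out.take_sites(np.flatnonzero(seg))
    logger.info("filter_biallelic: kept %d of %d sites", out.n_sites, table.n_sites)
    return out


def ibs_distance(table: VariantTable) -> DistanceMatrix:
    """1 - identity-by-state over diploidized dosages.

    d(i, j) = 1 - mean over co-called sites of (2 - |g_i - g_j|)/2 with
    g in {0, 1, 2}.
    """
    g = table.dosage_matrix().astype(float)
    g[g < 0] = np.nan
    n = table.n_strains
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(g[:, i]) & ~np.isnan(g[:, j])
            if not both.any():
                raise ValueError(f"strains {table.strains[i]} and {table.strains[j]} share no called sites")
            ibs = np.mean((2.0 - np.abs(g[both, i] - g[both, j])) / 2.0)
            d[i, j] = d[j, i] = 1.0 - ibs
    return DistanceMatrix(labels=list(table.strains), values=d)


def nucleotide_diversity(
    table: VariantTable, callable_length: int | None = None, projection: str = "diploid"
) -> PopGenSummary:
    """Per-site nucleotide diversity pi on a biallelic-filtered table.

    pi = (1/L) sum_j (n_j/(n_j-1)) 2 p_j (1-p_j), where p_j is the
    alternate-allele frequency among the n_j called allele copies at site
    j.  With the default ``projection='diploid'`` allele copies are
    counted after the diploid projection (two per called strain, the
    single convention that works across mixed-ploidy panels);
    ``projection='true'`` counts each call's actual allele copies
    instead.  L defaults to the sum of contig lengths.
    """
    L = sum(table.contigs.values()) if callable_length is None else callable_length
    if L <= 0:
        raise ValueError(f"callable length must be positive, got {L}")
    if projection not in ("diploid", "true"):
        raise ValueError(f"unknown projection {projection!r}")
    if projection == "true":
        alt = table.alt_copy_counts().astype(float)
        pl = table.call_ploidy().astype(float)
        called = alt >= 0
        n_j = np.where(called, pl, 0.0).sum(axis=1)
        g = np.where(called, alt, 0.0)
        usable = n_j >= 2
        n_skipped = int((~usable).sum())
        if n_skipped:
            logger.info("nucleotide_diversity: skipped %d sites with fewer than 2 allele copies", n_skipped)
        p = g[usable].sum(axis=1) / n_j[usable]
        terms = n_j[usable] / (n_j[usable] - 1) * 2.0 * p * (1.0 - p)
        return PopGenSummary(n_biallelic_sites=table.n_sites, callable_length=int(L), pi=float(terms.sum() / L))
    g = table.dosage_matrix().astype(float)
    called = g >= 0
    n_j = 2 * called.sum(axis=1)
    usable = n_j >= 2
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("nucleotide_diversity: skipped %d sites with fewer than 2 allele copies", n_skipped)
    gsum = np.where(called, g, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = gsum[usable] / n_j[usable]
        terms = n_j[usable] / (n_j[usable] - 1) * 2.0 * p * (1.0 - p)
    return PopGenSummary(n_biallelic_sites=table.n_sites, callable_length=int(L), pi=float(terms.sum() / L))


def homozygosity_windows(
    table: VariantTable, windows: GenomeWindows, per_strain: bool = False
) -> HomozygosityMatrix:
    """Homozygous-alt SNP counts per strain and genomic window, plus
    standardized values.

    By default each window column is z-scored across strains (population
    SD); ``per_strain=True`` standardizes each strain row across windows
    instead.  Zero-variance slices scale to all-zero.
    """
    g = table.dosage_matrix()
    hom = g == 2
    widx = windows.assign(table.chrom, table.pos)
    counts = np.zeros((table.n_strains, windows.n_windows))
    for s in range(table.n_strains):
        counts[s] = np.bincount(widx, weights=hom[:, s].astype(float), minlength=windows.n_windows)
    cols = [f"{r.chrom}:{r.start}-{r.end}" for r in windows.windows.itertuples()]
    raw = pd.DataFrame(counts, index=table.strains, columns=cols)
    if per_strain:
        mean, sd, along = raw.mean(axis=1), raw.std(axis=1, ddof=0), 0
    else:
        mean, sd, along = raw.mean(axis=0), raw.std(axis=0, ddof=0), 1
    n_const = int((sd == 0).sum())
    if n_const:
        logger.info("homozygosity_windows: %d zero-variance slices scaled to zero", n_const)
    scaled = raw.sub(mean, axis=along).div(sd.replace(0, np.nan), axis=along).fillna(0.0)
    return HomozygosityMatrix(raw=raw, scaled=scaled)


# ---------------------------------------------------------------------------
# multiscale bootstrap clustering


def _cluster_sets(Z: np.ndarray, n: int) -> dict[int, frozenset]:
    """Leaf-index sets of every internal node of a linkage matrix."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    for k, row in enumerate(Z):
        members[n + k] = members[int(row[0])] | members[int(row[1])]
    return {n + k: members[n + k] for k in range(len(Z))}


def _distance_fn(distance):
    if callable(distance):
        return distance
    return lambda sub: pdist(sub.T, metric=distance)


def au_from_bp_profile(bp: np.ndarray, scales: np.ndarray, B: int) -> tuple[float, float]:
    """Fit the multiscale-bootstrap probit model to one cluster's BP profile.

    z_r = Phi^-1(1 - BP_r) is fit as v sqrt(r) + c / sqrt(r) by weighted
    least squares (weights from the binomial variance of BP_r); the
    approximately unbiased value is AU = 1 - Phi(v - c).  Degenerate
    profiles -- a single scale, or BP identical at every scale -- carry no
    curvature information and return AU equal to the (clamped) BP itself.

    Returns (AU, BP at scale 1).
    """
    bp = np.asarray(bp, dtype=float)
    scales = np.asarray(scales, dtype=float)
    i1 = int(np.argmin(np.abs(scales - 1.0)))
    if np.all(bp == 1.0):  # cluster certain at every scale
        return 1.0, 1.0
    if np.all(bp == 0.0):
        return 0.0, 0.0
    bp_clamped = np.clip(bp, 1.0 / (B + 1), 1.0 - 1.0 / (B + 1))
    if len(scales) == 1 or np.allclose(bp, bp[0]):
        return float(bp_clamped[i1]), float(bp[i1])
    z = stats.norm.ppf(1.0 - bp_clamped)
    w = B * stats.norm.pdf(z) ** 2 / (bp_clamped * (1.0 - bp_clamped))
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ z)
    v, c = beta
    au = float(1.0 - stats.norm.cdf(v - c))
    return au, float(bp[i1])


def au_cluster(
    data: np.ndarray,
    distance="euclidean",
    linkage: str = "average",
    B: int = 1000,
    scales=DEFAULT_SCALES,
    seed: int | np.random.Generator | None = None,
    labels: list[str] | None = None,
) -> ClusterTree:
    """Hierarchical clustering with AU/BP support by multiscale bootstrap.

    ``data`` has shape (n_features, n_objects); features are the
    resampling units (SNP sites for the genetic tree, PC columns for the
    fitness tree).  ``distance`` is a scipy ``pdist`` metric name or a
    callable mapping a resampled (m', n_objects) array to condensed
    distances.  For each relative scale r in ``scales``, B feature
    resamples of size round(r * n_features) are drawn with replacement;
    each cluster of the full-data tree is scored by its occurrence
    fraction BP_r (leaf-set equality), and AU is extrapolated from the
    probit-transformed profile.
    """
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (n_features, n_objects)")
    m, n = data.shape
    if B < 100:
        logger.warning("au_cluster: B=%d below the recommended minimum of 100", B)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist_fn = _distance_fn(distance)
    labels = list(labels) if labels is not None else [str(i) for i in range(n)]

    Z = hierarchy.linkage(dist_fn(data), method=linkage)
    clusters = _cluster_sets(Z, n)
    scales = np.asarray(scales, dtype=float)
    hits = {node: np.zeros(len(scales)) for node in clusters}
    for si, r in enumerate(scales):
        size = max(2, int(round(r * m)))
        for _ in range(B):
            idx = rng.integers(0, m, size=size)
            Zb = hierarchy.linkage(dist_fn(data[idx]), method=linkage)
            got = set(_cluster_sets(Zb, n).values())
            for node, cl in clusters.items():
                if cl in got:
                    hits[node][si] += 1

    au, bp = {}, {}
    for node, cl in clusters.items():
        profile = hits[node] / B
        au[node], bp[node] = au_from_bp_profile(profile, scales, B)
    label_sets = {node: frozenset(labels[i] for i in cl) for node, cl in clusters.items()}
    return ClusterTree(labels=labels, linkage=Z, clusters=label_sets, au=au, bp=bp)


def ibs_condensed(dosage: np.ndarray) -> np.ndarray:
    """Condensed IBS distances from a (n_sites, n_strains) diploidized
    dosage array without missing values; vectorized for bootstrap use."""
    n = dosage.shape[1]
    out = np.empty(n * (n - 1) // 2)
    k = 0
    g = dosage.astype(np.float64)
    for i in range(n):
        diff = np.abs(g[:, i + 1 :] - g[:, [i]])
        vals = 1.0 - (2.0 - diff).mean(axis=0) / 2.0
        out[k : k + n - 1 - i] = vals
        k += n - 1 - i
    return out


def genetic_tree(
    table: VariantTable,
    B: int = 1000,
    scales=DEFAULT_SCALES,
    seed: int | None = None,
) -> ClusterTree:
    """SNP-based average-linkage tree with AU support, resampling sites."""
    g = table.dosage_matrix().astype(float)
    g[g < 0] = np.nan
    col_mean = np.nanmean(g, axis=1)
    ix = np.where(np.isnan(g))
    g[ix] = col_mean[ix[0]]  # mean-impute rare missing calls for resampling
    return au_cluster(
        g, distance=lambda sub: ibs_condensed(sub), B=B, scales=scales, seed=seed, labels=list(table.strains)
    )
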