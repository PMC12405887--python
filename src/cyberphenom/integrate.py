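"""Integrative statistics across genotype and phenotype tables.

PCA with cumulative-contribution PC selection, PC-score clustering with
AU support (Chebyshev distance, average linkage), PLS-DA with variable
importance in projection (VIP), the genetic-distance vs trait-profile
correlation, and the 2x2 chi-square association test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SkPCA

from .popgen import DEFAULT_SCALES, ClusterTree, DistanceMatrix, au_cluster

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    """Principal components of a strains x variables matrix.

    ``explained_pct`` covers every computed component and sums to 100;
    ``ccr`` is its running (cumulative contribution) ratio in [0, 1].
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_pct: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def ccr(self) -> np.ndarray:
        return np.cumsum(self.explained_pct) / 100.0


@dataclass
class PlsdaModel:
    """Fitted PLS-DA model (NIPALS PLS2 on centered class indicators)."""

    classes: list
    features: list[str]
    x_weights: np.ndarray  # p x a
    x_scores: np.ndarray  # n x a
    x_loadings: np.ndarray  # p x a
    y_loadings: np.ndarray  # k x a
    explained_x_pct: np.ndarray  # per component
    labels: np.ndarray


@dataclass
class GpCorrelation:
    """Pairwise genetic distance vs trait-profile similarity."""

    pairs: pd.DataFrame  # strain_a, strain_b, genetic_distance, trait_r
    r: float
    p_value: float
    mantel_p: float | None = None


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = True) -> PcaResult:
    """PCA via eigendecomposition of the (optionally autoscaled) covariance.

    Columns are centered and, by default, scaled to unit variance
    (sample SD).  Constant columns are dropped with a warning when
    scaling.  Explained percentages cover all min(n-1, p) components and
    sum to 100.
    """
    X = matrix.astype(float)
    if X.isna().any().any():
        raise ValueError("matrix contains missing values; impute before PCA")
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 rows")
    dropped = []
    if scale:
        sd = X.std(axis=0, ddof=1)
        dropped = list(X.columns[sd == 0])
        if dropped:
            logger.warning("pca: dropped %d constant column(s): %s", len(dropped), dropped)
            X = X.drop(columns=dropped)
            sd = sd.drop(labels=dropped)
        X = X / sd
    if center:
        X = X - X.mean(axis=0)
    n_comp = min(len(X) - 1, X.shape[1])
    sk = _SkPCA(n_components=n_comp, svd_solver="full")
    scores = sk.fit_transform(X.to_numpy())
    total_var = X.to_numpy().var(axis=0, ddof=1).sum()
    pct = 100.0 * sk.explained_variance_ / total_var
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(sk.components_.T, index=X.columns, columns=comp_names),
        explained_pct=pct,
        dropped_columns=dropped,
    )


def select_pcs(result: PcaResult, ccr_threshold: float = 0.90) -> int:
    """Smallest k whose cumulative contribution ratio reaches the threshold."""
    if not (0 < ccr_threshold <= 1):
        raise ValueError(f"ccr_threshold must lie in (0, 1], got {ccr_threshold}")
    ccr = result.ccr
    reached = np.flatnonzero(ccr >= ccr_threshold - 1e-12)
    return int(reached[0]) + 1 if len(reached) else len(ccr)


def pc_cluster(
    fitness: pd.DataFrame,
    ccr_threshold: float = 0.90,
    B: int = 1000,
    scales=DEFAULT_SCALES,
    seed: int | None = None,
    center: bool = True,
    scale: bool = True,
) -> ClusterTree:
    """Cluster strains on their leading PC scores with AU support.

    PCA -> first k PCs by CCR threshold -> pairwise Chebyshev (maximum
    coordinate) distance -> average-linkage tree; AU/BP by multiscale
    bootstrap with the PC columns as resampling features.
    """
    res = pca(fitness, center=center, scale=scale)
    k = select_pcs(res, ccr_threshold)
    if k == 1:
        logger.warning("pc_cluster: single PC selected; distance degenerates to |PC1 difference|")
    scores = res.scores.iloc[:, :k]
    return au_cluster(
        scores.to_numpy().T,
        distance="chebyshev",
        linkage="average",
        B=B,
        scales=scales,
        seed=seed,
        labels=list(fitness.index),
    )


def plsda(X: pd.DataFrame, labels, ncomp: int = 2) -> PlsdaModel:
    """PLS-DA: NIPALS PLS2 regression of centered class indicators on
    autoscaled predictors.

    ``X`` is strains x variables; ``labels`` the class of each row (>= 2
    classes).  Per-component explained X-variance is the score-loading
    reconstruction variance as a percentage of total X variance.
    """
    y = np.asarray(labels)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    Xv = X.astype(float).to_numpy()
    sd = Xv.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("X contains constant columns; drop them before PLS-DA")
    X0 = (Xv - Xv.mean(axis=0)) / sd
    Y = np.column_stack([(y == c).astype(float) for c in classes])
    Y0 = Y - Y.mean(axis=0)
    max_comp = min(X0.shape[0] - 1, X0.shape[1])
    if ncomp > max_comp:
        logger.warning("plsda: ncomp=%d truncated to rank bound %d", ncomp, max_comp)
        ncomp = max_comp
    pls = PLSRegression(n_components=ncomp, scale=False)
    pls.fit(X0, Y0)
    t = pls.x_scores_
    p = pls.x_loadings_
    total = (X0**2).sum()
    expl = np.array([(t[:, a] ** 2).sum() * (p[:, a] ** 2).sum() / total * 100.0 for a in range(ncomp)])
    return PlsdaModel(
        classes=classes,
        features=list(X.columns),
        x_weights=pls.x_weights_,
        x_scores=t,
        x_loadings=p,
        y_loadings=pls.y_loadings_,
        explained_x_pct=expl,
        labels=y,
    )


def vip(model: PlsdaModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a), with
    SSY_a the Y-variance explained by component a.  Satisfies
    mean(VIP^2) = 1; variables above 1 are conventionally influential.
    """
    w = model.x_weights
    t = model.x_scores
    q = model.y_loadings
    p, a = w.shape
    ssy = (q**2).sum(axis=0) * (t**2).sum(axis=0)
    if ssy.sum() <= 0:
        raise ValueError("degenerate PLS-DA fit: no Y variance explained")
    wnorm2 = (w**2).sum(axis=0)
    scores = np.sqrt(p * ((ssy * (w**2) / wnorm2).sum(axis=1)) / ssy.sum())
    return pd.Series(scores, index=model.features, name="VIP")


def gp_correlation(
    genetic: DistanceMatrix,
    traits: pd.DataFrame,
    mantel_permutations: int = 0,
    seed: int | None = None,
) -> GpCorrelation:
    """Correlate pairwise genetic distance with trait-profile similarity.

    For every unordered strain pair the Pearson correlation of the two
    strains' trait vectors is computed; the overall (R, P) is the Pearson
    correlation (t-transform P) of genetic distance vs that similarity
    across all n(n-1)/2 pairs.  Optionally a Mantel permutation P is
    added (strain-label permutations), acknowledging pair non-independence.
    """
    strains = list(genetic.labels)
    if set(strains) != set(traits.index):
        raise ValueError("genetic matrix and trait table must cover the same strains")
    T = traits.loc[strains].astype(float)
    sds = T.std(axis=1, ddof=1)
    bad = sds[sds == 0]
    if len(bad):
        raise ValueError(f"constant trait vector for strain(s): {', '.join(map(str, bad.index))}")
    Tn = T.sub(T.mean(axis=1), axis=0).div(T.std(axis=1, ddof=0) * np.sqrt(T.shape[1]), axis=0)
    corr = Tn.to_numpy() @ Tn.to_numpy().T  # pairwise Pearson of trait profiles
    rows = []
    for i, j in combinations(range(len(strains)), 2):
        rows.append((strains[i], strains[j], genetic.values[i, j], corr[i, j]))
    pairs = pd.DataFrame(rows, columns=["strain_a", "strain_b", "genetic_distance", "trait_r"])
    r, p = stats.pearsonr(pairs["genetic_distance"], pairs["trait_r"])
    mantel_p = None
    if mantel_permutations > 0:
        rng = np.random.default_rng(seed)
        n = len(strains)
        iu = np.triu_indices(n, 1)
        d = genetic.values
        obs = abs(r)
        hits = 0
        for _ in range(mantel_permutations):
            perm = rng.permutation(n)
            rp, _ = stats.pearsonr(d[perm][:, perm][iu], corr[iu])
            hits += abs(rp) >= obs
        mantel_p = (hits + 1) / (mantel_permutations + 1)
    return GpCorrelation(pairs=pairs, r=float(r), p_value=float(p), mantel_p=mantel_p)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2x2 count table.

    Returns (chi2, df, P) with df = 1 and an upper-tail P.  Yates
    continuity correction is off by default and available via
    ``correction=True``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain nonnegative integer counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return float(chi2), int(df), float(p)
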