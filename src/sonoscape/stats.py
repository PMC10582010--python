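"""Community ordination and index-based regression.

Community matrices are pandas DataFrames with plots as rows and species as
columns ("frequency per plot" abundances). The analysis chain is:

1. Bray-Curtis dissimilarity between plots.
2. Non-metric multidimensional scaling (Kruskal stress-1, isotonic fit of
   embedded distances to dissimilarity ranks, best of several random
   restarts), with the final configuration centred, PCA-rotated so axis 1
   carries maximal variance, and rescaled so embedded distances are on the
   dissimilarity scale.
3. Axis orientation: axis 1 is mirrored if needed so it ascends with a
   recovery covariate.
4. Richness measures, including the richness of species observed in
   old-growth reference plots.
5. Ordinary least squares of a response (community axis or log-richness)
   on the five acoustic indices, reporting estimates, standard errors,
   t-values and adjusted R-squared.
6. A simplified spatial-residual check: a binned Moran-style correlogram
   with a permutation envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

__all__ = [
    "OrdinationResult",
    "RegressionResult",
    "bray_curtis",
    "kruskal_stress",
    "nmds",
    "orient_axis",
    "richness_measures",
    "fit_index_model",
    "pearson",
    "spatial_correlogram",
    "correlogram_envelope",
]


@dataclass
class OrdinationResult:
    """NMDS scores (plots x k, PCA-rotated) with Kruskal stress-1."""

    scores: pd.DataFrame
    stress: float
    converged: bool
    axis1_sign: int = 1


@dataclass
class RegressionResult:
    """OLS fit: estimates, SEs, t-values, adjusted R-squared, residuals."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    r2: float
    adj_r2: float
    n: int
    residuals: pd.Series
    log_response: bool = False

    def table(self) -> pd.DataFrame:
        """Estimate / SE / t-value table, one row per predictor."""
        return pd.DataFrame({"estimate": self.params, "se": self.bse,
                             "t": self.tvalues})


def bray_curtis(community: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis distance matrix between plots.

    d(i, j) = sum |x_i - x_j| / sum (x_i + x_j), in [0, 1]. All-zero plots
    make the distance undefined and raise, naming the plot.
    """
    x = community.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("community matrix must be non-negative")
    zero = community.index[x.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"all-zero plot rows: {zero}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=community.index, columns=community.index)


def _pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    return iu


def kruskal_stress(d: np.ndarray, scores: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities.

    Embedded pairwise distances are fitted to the dissimilarity order by
    isotonic regression with primary tie handling (ties in dissimilarity
    are pre-sorted by embedded distance, so tied dissimilarities are free
    to take any order). stress-1 = sqrt(sum (d - dhat)^2 / sum d^2).
    """
    d = np.asarray(d, dtype=float)
    iu = _pairs(d.shape[0])
    delta = d[iu]
    dist = pdist(np.asarray(scores, dtype=float))
    order = np.lexsort((dist, delta))
    fitted = IsotonicRegression(increasing=True).fit_transform(
        np.arange(len(order)), dist[order])
    resid = dist[order] - fitted
    return float(np.sqrt(np.sum(resid ** 2) / np.sum(dist ** 2)))


def nmds(d: pd.DataFrame | np.ndarray, k: int = 2, n_restarts: int = 20,
         max_iter: int = 300, tol: float = 1e-6,
         seed: int = 0) -> OrdinationResult:
    """Non-metric MDS of a distance matrix, PCA-rotated.

    The SMACOF-based non-metric optimiser is run from ``n_restarts`` random
    starts; the best configuration is centred, rotated by PCA so axis 1
    accounts for maximal variance, and rescaled so embedded distances
    regress onto the dissimilarities with unit slope. The reported stress
    is Kruskal stress-1 of the returned configuration.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        labels = [f"obj{i}" for i in range(dm.shape[0])]
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(dm), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need at least 2 objects")

    mds = MDS(n_components=k, metric=False, dissimilarity="precomputed",
              n_init=n_restarts, max_iter=max_iter, eps=tol,
              random_state=np.random.RandomState(seed),
              normalized_stress=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X = mds.fit_transform(dm)

    X = X - X.mean(axis=0)
    # PCA rotation: axis 1 = direction of maximal variance
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    # rescale so embedded distances sit on the dissimilarity scale
    emb = pdist(X)
    denom = float(np.sum(emb ** 2))
    if denom > 0:
        X = X * (np.sum(dm[_pairs(n)] * emb) / denom)

    stress = kruskal_stress(dm, X)
    scores = pd.DataFrame(X, index=labels,
                          columns=[f"axis{i + 1}" for i in range(k)])
    return OrdinationResult(scores=scores, stress=stress,
                            converged=bool(np.isfinite(stress)))


def orient_axis(ordination: OrdinationResult,
                covariate: pd.Series | np.ndarray) -> OrdinationResult:
    """Mirror axis 1 if needed so it ascends with the recovery covariate."""
    cov = np.asarray(
        covariate.reindex(ordination.scores.index)
        if isinstance(covariate, pd.Series) else covariate, dtype=float)
    if len(cov) != len(ordination.scores):
        raise ValueError("covariate must align with plots")
    if np.std(cov) == 0:
        warnings.warn("zero-variance covariate; axis left unchanged",
                      UserWarning, stacklevel=2)
        return ordination
    axis1 = ordination.scores.iloc[:, 0].to_numpy()
    r = np.corrcoef(axis1, cov)[0, 1]
    if r < 0:
        scores = ordination.scores.copy()
        scores.iloc[:, 0] = -scores.iloc[:, 0]
        return replace(ordination, scores=scores,
                       axis1_sign=-ordination.axis1_sign)
    return ordination


def richness_measures(community: pd.DataFrame,
                      oldgrowth_plots: list[str] | set[str]) -> pd.DataFrame:
    """Per-plot total richness and old-growth richness.

    The old-growth species set contains every species present (>0) in at
    least one old-growth reference plot; a plot's old-growth richness
    counts only species from that set.
    """
    og = [p for p in oldgrowth_plots]
    missing = set(og) - set(community.index)
    if missing:
        raise ValueError(f"old-growth plots not in matrix: {sorted(missing)}")
    og_species = community.columns[(community.loc[og] > 0).any(axis=0)]
    if len(og_species) == 0:
        raise ValueError("old-growth species set is empty")
    present = community > 0
    return pd.DataFrame({
        "total_richness": present.sum(axis=1),
        "oldgrowth_richness": present[og_species].sum(axis=1),
    })


def fit_index_model(response: pd.Series | np.ndarray,
                    predictors: pd.DataFrame,
                    log_response: bool = False) -> RegressionResult:
    """OLS of a response on acoustic-index predictors, with intercept.

    When ``log_response`` is set, counts are natural-log transformed
    (log(y) when all y >= 1, else log(y + 1) with a warning) so richness
    models yield adjusted R-squared comparable with the axis models.
    """
    if isinstance(response, pd.Series):
        y = response.reindex(predictors.index).to_numpy(dtype=float)
        index = predictors.index
    else:
        y = np.asarray(response, dtype=float)
        index = predictors.index
    n, p = predictors.shape
    if n <= p + 1:
        raise ValueError(f"need more plots ({n}) than parameters ({p + 1})")
    if log_response:
        if (y >= 1).all():
            y = np.log(y)
        else:
            warnings.warn("response has values < 1; using log(y + 1)",
                          UserWarning, stacklevel=2)
            y = np.log1p(y)
    X = sm.add_constant(predictors.to_numpy(dtype=float))
    if np.linalg.cond(X) > 1e10:
        raise ValueError("collinear predictor matrix (condition number > 1e10)")
    names = ["const"] + list(predictors.columns)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        tvalues=pd.Series(fit.tvalues, index=names),
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n=n,
        residuals=pd.Series(fit.resid, index=index),
        log_response=log_response,
    )


def pearson(x, y) -> float:
    """Product-moment correlation; errors on zero variance or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(pearsonr(x, y).statistic)


def spatial_correlogram(residuals, coords, n_bins: int = 5) -> pd.DataFrame:
    """Binned Moran-style correlogram of model residuals.

    Pairs of plots are binned by planar distance; within each bin the
    statistic is the mean cross-product of standardised residuals,
    ``mean(z_i * z_j) / var(z)`` — positive when nearby residuals agree.
    Empty bins are reported with count 0 and NaN. A single bin reduces to
    a global Moran-style statistic.
    """
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("coords must be (n, 2) planar")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    z = z - z.mean()
    var = np.mean(z ** 2)
    dist = pdist(xy)
    iu = np.triu_indices(len(z), k=1)
    cross = z[iu[0]] * z[iu[1]]
    edges = np.linspace(0.0, dist.max() * (1 + 1e-9), n_bins + 1)
    rows = []
    for b in range(n_bins):
        sel = (dist >= edges[b]) & (dist < edges[b + 1])
        n_pairs = int(sel.sum())
        value = float(np.mean(cross[sel]) / var) if n_pairs else np.nan
        rows.append({"bin_center": 0.5 * (edges[b] + edges[b + 1]),
                     "correlation": value, "n_pairs": n_pairs})
    return pd.DataFrame(rows)


def correlogram_envelope(residuals, coords, n_bins: int = 5,
                         n_perm: int = 199, alpha: float = 0.05,
                         seed: int = 0) -> pd.DataFrame:
    """Permutation envelope for :func:`spatial_correlogram`.

    Residuals are randomly permuted across plots ``n_perm`` times; the
    returned frame adds the (alpha/2, 1 - alpha/2) quantiles of the null
    correlogram per distance bin to the observed one.
    """
    rng = np.random.default_rng(seed)
    obs = spatial_correlogram(residuals, coords, n_bins)
    z = np.asarray(residuals, dtype=float)
    null = np.empty((n_perm, n_bins))
    for i in range(n_perm):
        null[i] = spatial_correlogram(rng.permutation(z), coords,
                                      n_bins)["correlation"]
    lo = np.nanquantile(null, alpha / 2, axis=0)
    hi = np.nanquantile(null, 1 - alpha / 2, axis=0)
    obs["lower"] = lo
    obs["upper"] = hi
    obs["outside"] = (obs["correlation"] < lo) | (obs["correlation"] > hi)
    return obs
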