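"""Second-order analyses of manifold geometry.

Covers the log-linear model that predicts the combined Overlap from Signal
and Dimensionality,

    log N(m) = alpha * log S + beta * log D + gamma,

the resulting SNR surface over the (Signal, Dimensionality) plane with its
iso-SNR contours, permutation-tested Pearson correlations among geometric
properties, and hop-count distances on a user-supplied concept hierarchy.
Natural logarithms are used throughout (the coefficients rescale trivially
under a change of base).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import FitError, InputError, UndefinedCorrelationError

__all__ = [
    "LogLinearFit",
    "SnrSurface",
    "PermutationCorrelation",
    "CorrelationSuite",
    "fit_loglinear_overlap",
    "snr_surface",
    "pearson_permutation",
    "property_correlation_suite",
    "hierarchy_path_distance",
]

logger = logging.getLogger(__name__)


@dataclass
class LogLinearFit:
    """OLS fit of ``log N(m) = alpha log S + beta log D + gamma``.

    ``r_squared_signal_only`` is the R^2 of the single-predictor regression
    on ``log S`` alone, for comparison.  Standard errors are the usual OLS
    ones.  The coefficients depend on the shot count ``m`` because N(m)
    does, while S and D do not.
    """

    alpha: float
    beta: float
    gamma: float
    alpha_se: float
    beta_se: float
    gamma_se: float
    r_squared: float
    r_squared_signal_only: float
    m: int | None
    n_points: int
    n_excluded: int

    def predict_overlap(self, signal, dimensionality):
        """Fitted combined Overlap, ``exp(gamma) * S^alpha * D^beta``."""
        S = np.asarray(signal, dtype=float)
        D = np.asarray(dimensionality, dtype=float)
        return np.exp(self.gamma) * S**self.alpha * D**self.beta


def fit_loglinear_overlap(pairs: pd.DataFrame, m: int | None = None) -> LogLinearFit:
    """Fit the log-linear Overlap model to a per-pair geometry table.

    ``pairs`` needs columns ``signal``, ``dimensionality_a`` and
    ``combined_overlap`` (the tables produced by ``geometry_grid`` qualify).
    Rows with nonpositive S, D or N(m) are excluded with a logged count,
    since their logarithm is undefined.
    """
    required = {"signal", "dimensionality_a", "combined_overlap"}
    missing = required - set(pairs.columns)
    if missing:
        raise InputError(f"pairs table missing columns {sorted(missing)}")
    if m is None and "m" in pairs.columns:
        values = pd.unique(pairs["m"])
        m = int(values[0]) if len(values) == 1 else None
    S = pairs["signal"].to_numpy(dtype=float)
    D = pairs["dimensionality_a"].to_numpy(dtype=float)
    N = pairs["combined_overlap"].to_numpy(dtype=float)
    ok = (S > 0) & (D > 0) & (N > 0) & np.isfinite(S) & np.isfinite(D) & np.isfinite(N)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.warning(
            "excluding %d pairs with nonpositive S, D or N from log-linear fit",
            n_excluded,
        )
    if ok.sum() < 3:
        raise InputError("need at least 3 pairs with positive S, D and N")
    logS, logD, logN = np.log(S[ok]), np.log(D[ok]), np.log(N[ok])
    exog = np.column_stack([logS, logD, np.ones_like(logS)])
    if np.linalg.matrix_rank(exog) < 3:
        raise FitError("rank-deficient design (constant log S or log D)")
    res = sm.OLS(logN, exog).fit()
    res1 = sm.OLS(logN, np.column_stack([logS, np.ones_like(logS)])).fit()
    return LogLinearFit(
        alpha=float(res.params[0]),
        beta=float(res.params[1]),
        gamma=float(res.params[2]),
        alpha_se=float(res.bse[0]),
        beta_se=float(res.bse[1]),
        gamma_se=float(res.bse[2]),
        r_squared=float(res.rsquared),
        r_squared_signal_only=float(res1.rsquared),
        m=m,
        n_points=int(ok.sum()),
        n_excluded=n_excluded,
    )


@dataclass
class SnrSurface:
    """SNR as a function of Signal and Dimensionality only.

    Obtained by substituting the fitted Overlap model into the SNR
    expression while holding Bias at a constant (typically the per-dataset
    mean, which varies little).  ``snr[i, j]`` corresponds to
    ``(s_grid[i], d_grid[j])``; ``levels`` are contour levels suitable for
    drawing iso-SNR lines.
    """

    s_grid: np.ndarray
    d_grid: np.ndarray
    snr: np.ndarray
    levels: np.ndarray
    bias: float
    m: int
    fit: LogLinearFit

    def evaluate(self, signal, dimensionality):
        """SNR at arbitrary positive (S, D) points."""
        S = np.asarray(signal, dtype=float)
        D = np.asarray(dimensionality, dtype=float)
        N = self.fit.predict_overlap(S, D)
        return 0.5 * (S + self.bias / self.m) / np.sqrt(1.0 / (D * self.m) + N)


def snr_surface(
    fit: LogLinearFit,
    bias: float,
    m: int,
    s_grid,
    d_grid,
    n_levels: int = 8,
) -> SnrSurface:
    """Evaluate the fitted SNR over a positive (S, D) grid."""
    s_grid = np.asarray(list(s_grid), dtype=float)
    d_grid = np.asarray(list(d_grid), dtype=float)
    if np.any(s_grid <= 0) or np.any(d_grid <= 0):
        raise InputError("s_grid and d_grid must be strictly positive")
    surface = SnrSurface(
        s_grid=s_grid,
        d_grid=d_grid,
        snr=np.empty((s_grid.size, d_grid.size)),
        levels=np.empty(0),
        bias=float(bias),
        m=int(m),
        fit=fit,
    )
    S, D = np.meshgrid(s_grid, d_grid, indexing="ij")
    surface.snr = surface.evaluate(S, D)
    qs = np.linspace(0.05, 0.95, n_levels)
    surface.levels = np.unique(np.quantile(surface.snr, qs))
    return surface


@dataclass
class PermutationCorrelation:
    """Pearson r with a two-sided permutation p-value (add-one estimator)."""

    rho: float
    p_value: float
    n_permutations: int


def pearson_permutation(
    x, y, n_permutations: int = 1000, seed=None
) -> PermutationCorrelation:
    """Pearson correlation with a two-sided permutation test on ``y``.

    ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_permutations + 1)``, which is
    never zero and is a valid p-value under the exchangeability null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise InputError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("constant input; correlation undefined")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    r_obs = float(xs @ ys / n)
    perms = rng.permuted(np.tile(ys, (n_permutations, 1)), axis=1)
    r_perm = perms @ xs / n
    exceed = int(np.count_nonzero(np.abs(r_perm) >= np.abs(r_obs) - 1e-12))
    return PermutationCorrelation(
        rho=r_obs,
        p_value=(1 + exceed) / (n_permutations + 1),
        n_permutations=n_permutations,
    )


DEFAULT_PROPERTIES = ("snr", "signal", "bias", "combined_overlap", "dimensionality_a")


@dataclass
class CorrelationSuite:
    """Pairwise property correlations with permutation p-values."""

    correlations: pd.DataFrame
    p_values: pd.DataFrame
    grouping: str
    n_observations: int


def property_correlation_suite(
    table: pd.DataFrame,
    grouping: str = "level-average",
    level_column: str = "level",
    properties=DEFAULT_PROPERTIES,
    depth_column: str | None = None,
    max_depth_fraction: float | None = None,
    n_permutations: int = 1000,
    seed=None,
) -> CorrelationSuite:
    """Correlation structure of {SNR, S, b, N(m), D} across levels or pairs.

    ``grouping="level-average"`` first averages each property within a level
    (ROI or network layer; needs >= 3 levels); ``grouping="per-pair"`` uses
    every row as one observation.  ``depth_column``/``max_depth_fraction``
    restrict the analysis to a level subgroup (e.g. early layers with
    fractional depth below 0.5).  Properties that are constant in the data
    yield NaN entries rather than failing the suite.
    """
    properties = list(properties)
    missing = [p for p in properties if p not in table.columns]
    if missing:
        raise InputError(f"table missing property columns {missing!r}")
    data = table
    if depth_column is not None and max_depth_fraction is not None:
        data = data[data[depth_column] < max_depth_fraction]
    if grouping == "level-average":
        if level_column not in data.columns:
            raise InputError(f"missing level column {level_column!r}")
        data = data.groupby(level_column)[properties].mean()
        if len(data) < 3:
            raise InputError("need at least 3 levels for averaged correlations")
    elif grouping == "per-pair":
        data = data[properties]
        if len(data) < 3:
            raise InputError("need at least 3 rows")
    else:
        raise InputError(f"unknown grouping {grouping!r}")

    k = len(properties)
    corr = np.eye(k)
    pval = np.full((k, k), np.nan)
    master = np.random.SeedSequence(seed)
    seeds = iter(master.spawn(k * (k - 1) // 2))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                pc = pearson_permutation(
                    data[properties[i]].to_numpy(),
                    data[properties[j]].to_numpy(),
                    n_permutations=n_permutations,
                    seed=np.random.default_rng(next(seeds)),
                )
                corr[i, j] = corr[j, i] = pc.rho
                pval[i, j] = pval[j, i] = pc.p_value
            except UndefinedCorrelationError:
                logger.warning(
                    "constant property %r or %r; correlation undefined",
                    properties[i],
                    properties[j],
                )
                corr[i, j] = corr[j, i] = np.nan
    return CorrelationSuite(
        correlations=pd.DataFrame(corr, index=properties, columns=properties),
        p_values=pd.DataFrame(pval, index=properties, columns=properties),
        grouping=grouping,
        n_observations=len(data),
    )


def hierarchy_path_distance(graph, concepts=None) -> pd.DataFrame:
    """Shortest-path hop counts between concepts on an undirected hierarchy.

    ``graph`` may be a ``networkx.Graph`` or an iterable of (parent, child)
    edges; edges are treated as undirected.  Disconnected pairs are flagged
    with ``inf`` and a warning.
    """
    if isinstance(graph, nx.Graph):
        G = nx.Graph(graph)
    else:
        G = nx.Graph()
        G.add_edges_from(graph)
    if concepts is None:
        concepts = sorted(G.nodes)
    else:
        concepts = list(concepts)
        missing = [c for c in concepts if c not in G]
        if missing:
            raise InputError(f"concepts not in graph: {missing!r}")
    n = len(concepts)
    D = np.full((n, n), np.inf)
    for i, c in enumerate(concepts):
        lengths = nx.single_source_shortest_path_length(G, c)
        for j, d in enumerate(concepts):
            if d in lengths:
                D[i, j] = lengths[d]
    if np.isinf(D).any():
        logger.warning("hierarchy graph is disconnected over the requested concepts")
    return pd.DataFrame(D, index=concepts, columns=concepts)
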