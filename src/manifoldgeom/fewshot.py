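"""Empirical m-shot prototype classification and error-matrix summaries.

The m-shot classifier for a concept pair averages ``m`` exemplars per
concept into prototypes and assigns test patterns to the nearer prototype
(projection onto the prototype-difference direction, thresholded at the
midpoint — equivalent to nearest prototype in Euclidean distance).

``empirical_error_protocol`` implements the nested resampling scheme used
to validate the geometric theory: an outer loop re-splits every concept
into a ~90% geometry-estimation set and a ~10% held-out set; an inner loop
re-draws the ``m`` prototype exemplars from the held-out set and classifies
the remaining held-out patterns.  Geometry is computed on the 90% split of
each outer fold, so empirical error and geometric SNR are paired
observations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ActivityDataset, collapse_trials
from .exceptions import InputError, UndefinedBoundaryError, UndefinedCorrelationError
from .geometry import estimate_manifold, pair_geometry

__all__ = [
    "FewShotResult",
    "DistanceCurve",
    "build_prototype",
    "classify_pair",
    "empirical_error_protocol",
    "symmetry_score",
    "accuracy_vs_distance",
]

logger = logging.getLogger(__name__)


@dataclass
class FewShotResult:
    """Empirical m-shot error matrices plus per-fold geometry.

    ``error_mean[a, b]`` is the fraction of held-out concept-``a`` exemplars
    misclassified as ``b``, averaged over inner draws then outer folds;
    ``error_std`` is the across-outer-fold standard deviation.  The diagonal
    is undefined (NaN).
    """

    error_mean: pd.DataFrame
    error_std: pd.DataFrame
    m: int
    n_outer: int
    n_inner: int
    seed: int | None
    geometry: pd.DataFrame = field(repr=False, default=None)

    @property
    def concepts(self) -> list:
        return list(self.error_mean.index)

    @property
    def accuracy_mean(self) -> pd.DataFrame:
        return 1.0 - self.error_mean

    def mean_geometry(self) -> pd.DataFrame:
        """Fold-averaged geometry, one row per ordered concept pair."""
        num = self.geometry.drop(columns=["fold"])
        return (
            num.groupby(["concept_a", "concept_b"], sort=True)
            .mean()
            .reset_index()
        )


def build_prototype(exemplars: np.ndarray, m: int, seed=None) -> np.ndarray:
    """Mean of ``m`` exemplars sampled without replacement."""
    X = np.asarray(exemplars, dtype=float)
    m = int(m)
    if m < 1:
        raise InputError("m must be positive")
    if X.shape[0] < m:
        raise InputError(f"need at least {m} exemplars, got {X.shape[0]}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(X.shape[0], size=m, replace=False)
    return X[idx].mean(axis=0)


def classify_pair(test: np.ndarray, proto_a: np.ndarray, proto_b: np.ndarray) -> np.ndarray:
    """Assign each test row to the nearer prototype.

    Returns an integer array: 0 for ``proto_a``, 1 for ``proto_b``.  Rows on
    the exact midpoint hyperplane go to ``proto_a`` (deterministic tie
    convention; ties have measure zero for continuous data).
    """
    test = np.atleast_2d(np.asarray(test, dtype=float))
    pa = np.asarray(proto_a, dtype=float)
    pb = np.asarray(proto_b, dtype=float)
    w = pa - pb
    scale = max(np.abs(pa).max(), np.abs(pb).max(), 1.0)
    if np.linalg.norm(w) <= scale * 1e-12:
        raise UndefinedBoundaryError("identical prototypes; boundary undefined")
    score = (test - 0.5 * (pa + pb)) @ w
    return np.where(score >= 0.0, 0, 1)


def _holdout_size(n: int, fraction: float, m: int) -> int:
    return max(int(np.floor(fraction * n)), m + 1)


def empirical_error_protocol(
    dataset: ActivityDataset,
    m: int,
    n_outer: int = 16,
    n_inner: int = 16,
    holdout_fraction: float = 0.10,
    seed: int | None = None,
) -> FewShotResult:
    """Measure m-shot error with the nested 16x16 resampling protocol.

    When ``trial_id`` is present, repeats are first averaged into one row per
    exemplar so that splits are leakage-free.  A master seed spawns
    independent per-fold streams, making the result reproducible and
    order-independent.
    """
    if not 0 < holdout_fraction < 1:
        raise InputError("holdout_fraction must lie in (0, 1)")
    ds = collapse_trials(dataset)
    concepts = ds.concepts
    if len(concepts) < 2:
        raise InputError("need at least 2 concepts")
    groups = {c: ds.concept_patterns(c) for c in concepts}
    hold = {}
    for c, X in groups.items():
        h = _holdout_size(X.shape[0], holdout_fraction, m)
        if X.shape[0] - h < 2 or h <= m:
            raise InputError(
                f"concept {c!r} has too few exemplars ({X.shape[0]}) for "
                f"m={m} with holdout fraction {holdout_fraction}"
            )
        hold[c] = h

    K = len(concepts)
    errors = np.full((n_outer, K, K), np.nan)
    geo_rows = []
    master = np.random.SeedSequence(seed)
    for f, fold_seq in enumerate(master.spawn(n_outer)):
        split_seq, inner_seq = fold_seq.spawn(2)
        split_rng = np.random.default_rng(split_seq)
        holdouts, summaries = {}, {}
        for c in concepts:
            X = groups[c]
            perm = split_rng.permutation(X.shape[0])
            holdouts[c] = X[perm[: hold[c]]]
            summaries[c] = estimate_manifold(X[perm[hold[c]:]])
        for a, b in itertools.permutations(concepts, 2):
            pg = pair_geometry(summaries[a], summaries[b], m)
            geo_rows.append(
                {
                    "fold": f,
                    "concept_a": a,
                    "concept_b": b,
                    "m": m,
                    "signal": pg.signal,
                    "bias": pg.bias,
                    "overlap_a": pg.overlap_a,
                    "overlap_b": pg.overlap_b,
                    "overlap_ab": pg.overlap_ab,
                    "combined_overlap": pg.combined_overlap,
                    "snr": pg.snr,
                    "predicted_error": pg.predicted_error,
                    "dimensionality_a": summaries[a].dimensionality,
                    "dimensionality_b": summaries[b].dimensionality,
                }
            )
        n_pairs = K * (K - 1) // 2
        pair_seqs = inner_seq.spawn(n_pairs)
        for (i, j), pseq in zip(itertools.combinations(range(K), 2), pair_seqs):
            a, b = concepts[i], concepts[j]
            Ha, Hb = holdouts[a], holdouts[b]
            rng = np.random.default_rng(pseq)
            e_ab = e_ba = 0.0
            for _ in range(n_inner):
                ia = rng.choice(Ha.shape[0], size=m, replace=False)
                ib = rng.choice(Hb.shape[0], size=m, replace=False)
                pa, pb = Ha[ia].mean(axis=0), Hb[ib].mean(axis=0)
                rest_a = np.setdiff1d(np.arange(Ha.shape[0]), ia)
                rest_b = np.setdiff1d(np.arange(Hb.shape[0]), ib)
                e_ab += float(np.mean(classify_pair(Ha[rest_a], pa, pb) == 1))
                e_ba += float(np.mean(classify_pair(Hb[rest_b], pa, pb) == 0))
            errors[f, i, j] = e_ab / n_inner
            errors[f, j, i] = e_ba / n_inner

    mean = pd.DataFrame(errors.mean(axis=0), index=concepts, columns=concepts)
    std = pd.DataFrame(errors.std(axis=0, ddof=1), index=concepts, columns=concepts)
    return FewShotResult(
        error_mean=mean,
        error_std=std,
        m=m,
        n_outer=n_outer,
        n_inner=n_inner,
        seed=seed,
        geometry=pd.DataFrame(geo_rows),
    )


def _matrix_values(matrix) -> np.ndarray:
    M = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise InputError("expected a square concept-by-concept matrix")
    return M


def symmetry_score(error_matrix) -> float:
    """Pearson correlation between the strict upper triangle and the
    transpose-matched strict lower triangle of an error matrix."""
    M = _matrix_values(error_matrix)
    n = M.shape[0]
    if n < 3:
        raise InputError("need at least 3 concepts")
    iu = np.triu_indices(n, k=1)
    upper, lower = M[iu], M.T[iu]
    if np.std(upper) == 0 or np.std(lower) == 0:
        raise UndefinedCorrelationError("constant triangle; correlation undefined")
    return float(stats.pearsonr(upper, lower).statistic)


@dataclass
class DistanceCurve:
    """Mean m-shot error binned by concept-hierarchy hop distance."""

    bin_centers: np.ndarray
    mean_error: np.ndarray
    n_pairs: np.ndarray
    correlation: float  # Pearson r between success (1-error) and distance


def accuracy_vs_distance(result: FewShotResult, distances) -> DistanceCurve:
    """Bin error by hierarchy distance and correlate success with distance.

    ``distances`` is a symmetric nonnegative-integer hop matrix over the
    same concept set (a labeled DataFrame is aligned by concept; a bare
    array must already match the result's concept ordering).  If all
    distances are equal the correlation is undefined and returned as NaN
    with a warning.
    """
    concepts = result.concepts
    if isinstance(distances, pd.DataFrame):
        missing = [c for c in concepts if c not in distances.index or c not in distances.columns]
        if missing:
            raise InputError(f"distance matrix missing concepts {missing!r}")
        D = distances.loc[concepts, concepts].to_numpy(dtype=float)
    else:
        D = _matrix_values(distances)
        if D.shape[0] != len(concepts):
            raise InputError("distance matrix does not match the concept set")
    if not np.allclose(D, D.T):
        raise InputError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise InputError("distances must be nonnegative")

    E = result.error_mean.to_numpy(dtype=float)
    off = ~np.eye(len(concepts), dtype=bool)
    valid = off & np.isfinite(E) & np.isfinite(D)
    err, dist = E[valid], D[valid]
    if np.std(dist) == 0:
        logger.warning("all hierarchy distances equal; correlation undefined")
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(1.0 - err, dist).statistic)
    centers = np.unique(dist)
    mean_err = np.array([err[dist == d].mean() for d in centers])
    counts = np.array([int((dist == d).sum()) for d in centers])
    return DistanceCurve(
        bin_centers=centers, mean_error=mean_err, n_pairs=counts, correlation=corr
    )
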