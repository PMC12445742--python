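"""Concept-manifold geometry and the geometric signal-to-noise ratio.

A concept manifold is the cloud of activity patterns evoked by exemplars of
one concept.  Its first- and second-order structure — centroid, radii
spectrum (square roots of the covariance eigenvalues), principal directions
and participation-ratio Dimensionality — determines, through a small set of
pairwise quantities (Signal, Bias, Overlaps), the error of an m-shot
nearest-prototype linear classifier:

    SNR_ab(m) = (S_ab + b_ab/m) / 2
                ------------------------------------------------
                sqrt( (1/D_a + N^b_ab + N^ab_ab)/m + N^a_ab )

and ``error = H(SNR)`` with ``H`` the standard normal upper-tail function.
Only terms linear in ``1/m`` enter the composite.

Conventions
-----------
All pairwise quantities describe concept ``a`` relative to concept ``b``:
the centre difference and both direction matrices are normalized by the
*first* manifold's total radius ``R_a``, so the pair is ordered and
``SNR(a,b) != SNR(b,a)`` in general.  Radii satisfy ``r_i^2 = lambda_i``
where ``lambda_i`` are eigenvalues of the centered covariance normalized by
the number of exemplars ``P`` (equivalently ``r_i`` is the i-th singular
value of the centered pattern matrix divided by ``sqrt(P)``); under this
normalization sample estimates converge to the population values of the
generating distribution as ``P`` grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .dataset import ActivityDataset
from .exceptions import DegenerateManifoldError, InputError, SignalDirectionError

__all__ = [
    "ManifoldSummary",
    "PairGeometry",
    "GeometryGrid",
    "Projection2D",
    "estimate_manifold",
    "pair_geometry",
    "gaussian_tail_error",
    "geometry_grid",
    "project_2d",
]

logger = logging.getLogger(__name__)

PAIR_COLUMNS = [
    "concept_a",
    "concept_b",
    "m",
    "signal",
    "bias",
    "overlap_a",
    "overlap_b",
    "overlap_ab",
    "combined_overlap",
    "snr",
    "predicted_error",
    "dimensionality_a",
    "dimensionality_b",
]

CONCEPT_COLUMNS = ["concept", "dimensionality", "total_radius_sq", "n_exemplars"]


@dataclass
class ManifoldSummary:
    """Second-order summary of one concept manifold.

    Attributes
    ----------
    centroid
        Length-V mean pattern.
    radii
        Nonincreasing, nonnegative per-direction radii; ``radii**2`` are the
        eigenvalues of the (1/P-normalized) centered covariance.
    directions
        V-by-k orthonormal matrix of principal directions (one column per
        retained component).
    total_radius_sq
        Squared total radius ``R^2 = sum_i r_i^2`` (the total variance).
    dimensionality
        Participation ratio ``(sum r_i^2)^2 / sum r_i^4``.
    n_exemplars
        Number of rows the summary was estimated from (0 for population
        summaries).
    """

    centroid: np.ndarray
    radii: np.ndarray
    directions: np.ndarray
    total_radius_sq: float
    dimensionality: float
    n_exemplars: int

    @property
    def ambient_dim(self) -> int:
        return self.centroid.shape[0]

    @property
    def total_radius(self) -> float:
        return float(np.sqrt(self.total_radius_sq))


@dataclass
class PairGeometry:
    """All pairwise geometric quantities for an ordered concept pair (a, b)."""

    signal: float
    bias: float
    overlap_a: float
    overlap_b: float
    overlap_ab: float
    combined_overlap: float
    snr: float
    predicted_error: float
    m: int


@dataclass
class GeometryGrid:
    """Per-pair and per-concept geometry tables for a whole dataset."""

    pairs: pd.DataFrame
    concepts: pd.DataFrame
    summaries: dict = field(repr=False, default_factory=dict)


def participation_ratio(variances: np.ndarray) -> float:
    """Effective number of variance-carrying directions of a spectrum."""
    v = np.asarray(variances, dtype=float)
    total = v.sum()
    if total <= 0:
        raise DegenerateManifoldError("spectrum has zero total variance")
    return float(total**2 / np.sum(v**2))


def summary_from_spectrum(
    centroid: np.ndarray,
    variances: np.ndarray,
    directions: np.ndarray,
    n_exemplars: int = 0,
) -> ManifoldSummary:
    """Build a :class:`ManifoldSummary` from an explicit covariance spectrum.

    Used both by :func:`estimate_manifold` (sample spectrum) and by the
    synthetic generator (population spectrum), guaranteeing that estimated
    and ground-truth geometry share one convention.
    """
    variances = np.asarray(variances, dtype=float)
    if np.any(variances < -1e-12):
        raise InputError("negative variance in spectrum")
    variances = np.clip(variances, 0.0, None)
    order = np.argsort(variances)[::-1]
    variances = variances[order]
    directions = np.asarray(directions, dtype=float)[:, order]
    total = float(variances.sum())
    if total <= 0:
        raise DegenerateManifoldError("manifold has zero total variance")
    return ManifoldSummary(
        centroid=np.asarray(centroid, dtype=float),
        radii=np.sqrt(variances),
        directions=directions,
        total_radius_sq=total,
        dimensionality=participation_ratio(variances),
        n_exemplars=int(n_exemplars),
    )


def estimate_manifold(X: np.ndarray) -> ManifoldSummary:
    """Estimate the manifold summary of one concept's exemplar matrix.

    Parameters
    ----------
    X
        ``(P, V)`` matrix, one row per exemplar.  ``P >= 2`` and at least one
        row must differ from another.

    Notes
    -----
    All ``min(P-1, V)`` principal components are retained; there is no
    variance-threshold truncation.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("X must be a 2-D exemplar-by-unit matrix")
    P, V = X.shape
    if P < 2:
        raise InputError("need at least 2 exemplars to estimate a manifold")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    # Economy SVD of the centered data; singular values / sqrt(P) are radii.
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(P - 1, V)
    radii = s[:k] / np.sqrt(P)
    scale = np.abs(X).max()
    if radii.size == 0 or radii[0] <= max(scale, 1.0) * 1e-12:
        raise DegenerateManifoldError(
            "all exemplars are identical; manifold geometry is undefined"
        )
    return summary_from_spectrum(centroid, radii**2, Vt[:k].T, n_exemplars=P)


def gaussian_tail_error(snr):
    """Map an SNR value to predicted classification error.

    ``H(z) = P(Z > z)`` for standard normal ``Z``; ``H(0) = 0.5``, strictly
    decreasing, ``H(z) + H(-z) = 1``.  Accepts scalars or arrays.
    """
    z = np.asarray(snr, dtype=float)
    if not np.all(np.isfinite(z)):
        raise InputError("snr must be finite")
    out = special.ndtr(-z)
    return float(out) if np.isscalar(snr) or out.ndim == 0 else out


def pair_geometry(A: ManifoldSummary, B: ManifoldSummary, m: int) -> PairGeometry:
    """All pairwise quantities for ordered concept pair (A, B) at shot count m.

    Both direction matrices and the centre difference are normalized by
    ``R_A``, so the result describes A relative to B.
    """
    if A.ambient_dim != B.ambient_dim:
        raise InputError("manifolds live in different ambient dimensions")
    m = int(m)
    if m < 1:
        raise InputError("m must be a positive integer")
    Ra2 = A.total_radius_sq
    if Ra2 <= 0:
        raise DegenerateManifoldError("reference manifold has zero radius")
    Ra = np.sqrt(Ra2)
    dx = (A.centroid - B.centroid) / Ra
    Ua = A.directions * (A.radii / Ra)
    Ub = B.directions * (B.radii / Ra)

    signal = float(dx @ dx)
    bias = float(B.total_radius_sq / Ra2 - 1.0)
    overlap_a = float(np.sum((dx @ Ua) ** 2))
    overlap_b = float(np.sum((dx @ Ub) ** 2))
    overlap_ab = float(np.sum((Ua.T @ Ub) ** 2))
    combined = (overlap_b + overlap_ab) / m + overlap_a
    snr = (
        0.5
        * (signal + bias / m)
        / np.sqrt(1.0 / (m * A.dimensionality) + combined)
    )
    return PairGeometry(
        signal=signal,
        bias=bias,
        overlap_a=overlap_a,
        overlap_b=overlap_b,
        overlap_ab=overlap_ab,
        combined_overlap=float(combined),
        snr=float(snr),
        predicted_error=gaussian_tail_error(float(snr)),
        m=m,
    )


def geometry_grid(dataset: ActivityDataset, m: int) -> GeometryGrid:
    """Estimate geometry for every concept and every ordered concept pair.

    Degenerate concepts (zero variance or fewer than 2 exemplars) are
    excluded with a logged warning rather than failing the whole grid.
    """
    summaries: dict = {}
    concept_rows = []
    for c in dataset.concepts:
        X = dataset.concept_patterns(c)
        try:
            summ = estimate_manifold(X)
        except (DegenerateManifoldError, InputError) as exc:
            logger.warning("excluding degenerate concept %r: %s", c, exc)
            continue
        summaries[c] = summ
        concept_rows.append(
            {
                "concept": c,
                "dimensionality": summ.dimensionality,
                "total_radius_sq": summ.total_radius_sq,
                "n_exemplars": summ.n_exemplars,
            }
        )
    if len(summaries) < 2:
        raise InputError("need at least 2 non-degenerate concepts")
    pair_rows = []
    names = list(summaries)
    for a in names:
        for b in names:
            if a == b:
                continue
            pg = pair_geometry(summaries[a], summaries[b], m)
            pair_rows.append(
                {
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
    return GeometryGrid(
        pairs=pd.DataFrame(pair_rows, columns=PAIR_COLUMNS),
        concepts=pd.DataFrame(concept_rows, columns=CONCEPT_COLUMNS),
        summaries=summaries,
    )


@dataclass
class Projection2D:
    """Signal-plane coordinates for visualizing a concept pair.

    ``coords`` are exemplar coordinates (x = along the signal direction,
    y = maximum-variance direction orthogonal to it), relative to the pooled
    mean of the two concepts.
    """

    coords: np.ndarray
    labels: np.ndarray
    centroids: dict
    axes: np.ndarray


def _orthogonal_complement_vector(x_axis: np.ndarray) -> np.ndarray:
    """Any unit vector orthogonal to ``x_axis`` (degenerate-variance fallback)."""
    V = x_axis.shape[0]
    e = np.zeros(V)
    e[int(np.argmin(np.abs(x_axis)))] = 1.0
    y = e - (e @ x_axis) * x_axis
    return y / np.linalg.norm(y)


def project_2d(dataset: ActivityDataset, concept_a, concept_b) -> Projection2D:
    """Project two concepts' exemplars onto the signal plane.

    The x-axis is the unit vector along the centroid difference
    ``x0_a - x0_b``; the y-axis is the top principal direction of the pooled
    (both-concept) centered data after removing its component along the
    x-axis.  The returned axes are orthonormal.
    """
    Xa = dataset.concept_patterns(concept_a)
    Xb = dataset.concept_patterns(concept_b)
    ca, cb = Xa.mean(axis=0), Xb.mean(axis=0)
    delta = ca - cb
    norm = np.linalg.norm(delta)
    scale = max(np.abs(dataset.patterns).max(), 1.0)
    if norm <= scale * 1e-12:
        raise SignalDirectionError(
            "centroids coincide; the signal direction is undefined"
        )
    x_axis = delta / norm
    pooled = np.vstack([Xa, Xb])
    center = pooled.mean(axis=0)
    pooled_c = pooled - center
    resid = pooled_c - np.outer(pooled_c @ x_axis, x_axis)
    _, s, Vt = np.linalg.svd(resid, full_matrices=False)
    if s.size and s[0] > scale * 1e-10:
        y_axis = Vt[0]
        # re-orthogonalize against x (numerical hygiene) and fix the sign
        y_axis = y_axis - (y_axis @ x_axis) * x_axis
        y_axis = y_axis / np.linalg.norm(y_axis)
    else:
        y_axis = _orthogonal_complement_vector(x_axis)
    y_axis = y_axis * np.sign(y_axis[int(np.argmax(np.abs(y_axis)))])
    axes = np.column_stack([x_axis, y_axis])
    labels = np.concatenate(
        [np.repeat(concept_a, len(Xa)), np.repeat(concept_b, len(Xb))]
    )
    coords = (pooled - center) @ axes
    centroids = {concept_a: (ca - center) @ axes, concept_b: (cb - center) @ axes}
    return Projection2D(coords=coords, labels=labels, centroids=centroids, axes=axes)
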