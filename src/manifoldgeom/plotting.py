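"""Static figure helpers (optional; requires matplotlib).

Three views mirror the package's main outputs: the 2-D signal-plane
projection of a concept pair, error binned by hierarchy distance, and the
SNR map over the (Signal, Dimensionality) plane with iso-SNR contours.
"""

from __future__ import annotations

import numpy as np

from .covariation import SnrSurface
from .fewshot import DistanceCurve
from .geometry import Projection2D


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_projection_2d(projection: Projection2D, ax=None):
    """Scatter both concepts in the signal plane with centroid markers."""
    ax = _axes(ax)
    for label in projection.centroids:
        mask = projection.labels == label
        pts = projection.coords[mask]
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.5, label=str(label))
        cx, cy = projection.centroids[label]
        ax.plot(cx, cy, marker="s", markersize=9, color="k")
    ax.set_xlabel("signal direction")
    ax.set_ylabel("max-variance orthogonal direction")
    ax.legend()
    return ax


def plot_distance_curve(curve: DistanceCurve, ax=None):
    """Mean error as a function of hierarchy hop distance."""
    ax = _axes(ax)
    ax.plot(curve.bin_centers, curve.mean_error, marker="o")
    ax.set_xlabel("hierarchy distance (hops)")
    ax.set_ylabel("mean error")
    if np.isfinite(curve.correlation):
        ax.set_title(f"success-distance correlation r={curve.correlation:.2f}")
    return ax


def plot_snr_surface(surface: SnrSurface, ax=None, points=None):
    """SNR map over the (S, D) plane, log-log, with iso-SNR contours.

    ``points`` may be an ``(n, 2)`` array of per-pair (S, D) values to
    overlay on the map.
    """
    ax = _axes(ax)
    S, D = np.meshgrid(surface.s_grid, surface.d_grid, indexing="ij")
    mesh = ax.pcolormesh(S, D, surface.snr, shading="auto", cmap="viridis")
    cs = ax.contour(S, D, surface.snr, levels=surface.levels, colors="w", linewidths=0.8)
    ax.clabel(cs, fontsize=7, fmt="%.2f")
    if points is not None:
        pts = np.asarray(points, dtype=float)
        ax.scatter(pts[:, 0], pts[:, 1], s=12, c="r", edgecolors="none")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("Signal S")
    ax.set_ylabel("Dimensionality D")
    ax.figure.colorbar(mesh, ax=ax, label=f"SNR(m={surface.m})")
    return ax
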