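"""Random-subspace sampling and Gaussian random projection.

High-dimensional activity spaces (tens of thousands of voxels or model
features) are reduced in two stages before geometry estimation: a random
subset of units, then a dense Gaussian random projection.  Because the
manifolds of interest have low participation-ratio Dimensionality, both
stages leave the geometric estimates essentially unchanged once the target
dimension comfortably exceeds that Dimensionality (Johnson-Lindenstrauss
regime); ``convergence_sweep`` quantifies this on any dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ActivityDataset
from .exceptions import InputError
from .geometry import geometry_grid

__all__ = [
    "ProjectionConfig",
    "random_subspace",
    "random_project",
    "convergence_sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class ProjectionConfig:
    """Embedding settings: unit subsample size, projection target, seed."""

    subspace_dim: int
    projection_dim: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.subspace_dim < 1 or self.projection_dim < 1:
            raise InputError("subspace_dim and projection_dim must be >= 1")
        if self.projection_dim > self.subspace_dim:
            raise InputError("projection_dim cannot exceed subspace_dim")


def random_subspace(dataset: ActivityDataset, k: int, seed=None) -> ActivityDataset:
    """Restrict the dataset to ``k`` units sampled uniformly without
    replacement (retained in original column order).

    ``k`` larger than the ambient dimension is clamped with a warning and
    returns all columns in their original order.
    """
    k = int(k)
    if k < 1:
        raise InputError("k must be >= 1")
    V = dataset.n_units
    if k >= V:
        if k > V:
            warnings.warn(
                f"requested subspace of {k} units but only {V} available; "
                "keeping all units",
                stacklevel=2,
            )
        return dataset.select_units(np.arange(V))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = np.sort(rng.choice(V, size=k, replace=False))
    return dataset.select_units(cols)


def random_project(dataset: ActivityDataset, d: int, seed=None) -> ActivityDataset:
    """Project patterns through a ``V x d`` matrix of iid N(0, 1/d) entries.

    The 1/sqrt(d) scaling preserves expected squared norms, so geometric
    quantities are preserved in expectation.
    """
    d = int(d)
    if d < 1:
        raise InputError("d must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = rng.standard_normal((dataset.n_units, d)) / np.sqrt(d)
    return dataset.with_patterns(dataset.patterns @ G, unit_ids=None)


def convergence_sweep(
    dataset: ActivityDataset,
    subspace_dims,
    projection_dims,
    m: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Geometry estimates over a grid of embedding dimensions.

    For every (subspace_dim, projection_dim) grid point the dataset is
    subsampled, projected, and summarized by the across-pair mean SNR(m) and
    Signal; fraction-of-maximum columns express each estimate relative to
    its largest value over the grid.  The integer seeds actually used at
    each grid point are reported, so any single point can be reproduced by
    calling :func:`random_subspace` / :func:`random_project` directly.
    """
    subspace_dims = list(subspace_dims)
    projection_dims = list(projection_dims)
    if not subspace_dims or not projection_dims:
        raise InputError("dimension grids must be nonempty")
    master = np.random.default_rng(seed)
    rows = []
    for k in subspace_dims:
        for d in projection_dims:
            sub_seed = int(master.integers(2**31))
            proj_seed = int(master.integers(2**31))
            ds = random_subspace(dataset, k, seed=sub_seed)
            ds = random_project(ds, min(d, ds.n_units), seed=proj_seed)
            grid = geometry_grid(ds, m)
            rows.append(
                {
                    "subspace_dim": k,
                    "projection_dim": d,
                    "mean_snr": float(grid.pairs["snr"].mean()),
                    "mean_signal": float(grid.pairs["signal"].mean()),
                    "subspace_seed": sub_seed,
                    "projection_seed": proj_seed,
                }
            )
    table = pd.DataFrame(rows)
    table["frac_of_max_snr"] = table["mean_snr"] / table["mean_snr"].max()
    table["frac_of_max_signal"] = table["mean_signal"] / table["mean_signal"].max()
    return table
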