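"""Readers, writers and run configuration.

Canonical interchange is TSV (CSV accepted on read, selected by file
extension): human-inspectable and diff-able.  An activity file has a header
row; the first column is the concept label, an optional second column named
``trial_id`` groups repeats, and all remaining columns are units.  Every
writer here round-trips through the matching reader without loss (floats
are written at full precision).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ActivityDataset
from .exceptions import ConfigError, ParseError
from .fewshot import DistanceCurve, FewShotResult
from .geometry import GeometryGrid

__all__ = [
    "read_activity_dataset",
    "write_activity_dataset",
    "read_matrix",
    "write_matrix",
    "write_geometry_grid",
    "write_fewshot_result",
    "write_distance_curve",
    "read_edge_list",
    "RunConfig",
]

logger = logging.getLogger(__name__)


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_activity_dataset(path, sep: str | None = None) -> ActivityDataset:
    """Read a delimited activity file into an :class:`ActivityDataset`.

    Raises :class:`ParseError` (naming the offending line where possible)
    on ragged rows, non-numeric cells or missing values.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep=_sep_for(path, sep), float_precision="round_trip"
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: need a label column plus at least one unit column")
    cols = list(frame.columns)
    unit_cols = cols[2:] if (len(cols) > 2 and cols[1] == "trial_id") else cols[1:]
    for c in unit_cols:
        values = pd.to_numeric(frame[c], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float))
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ParseError(
                f"{path}: non-numeric or missing value in column {c!r}, line {line}"
            )
        frame[c] = values
    dataset = ActivityDataset.from_frame(frame)
    logger.info(
        "read %s: %d rows, %d units, %d concepts",
        path, dataset.n_rows, dataset.n_units, len(dataset.concepts),
    )
    return dataset


def write_activity_dataset(dataset: ActivityDataset, path, sep: str | None = None) -> None:
    path = Path(path)
    dataset.to_frame().to_csv(path, sep=_sep_for(path, sep), index=False)


def write_matrix(matrix: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a concept-labeled square matrix (index kept)."""
    matrix.to_csv(Path(path), sep=sep, index=True, index_label="concept")


def read_matrix(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(
        Path(path), sep=sep, index_col=0, float_precision="round_trip"
    )


def write_geometry_grid(grid: GeometryGrid, pairs_path, concepts_path) -> None:
    grid.pairs.to_csv(Path(pairs_path), sep="\t", index=False)
    grid.concepts.to_csv(Path(concepts_path), sep="\t", index=False)


def write_fewshot_result(result: FewShotResult, out_dir, prefix: str = "fewshot") -> list[Path]:
    """Write mean/std error matrices (and per-fold geometry) as TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in (
        ("error_mean", result.error_mean),
        ("error_std", result.error_std),
    ):
        p = out_dir / f"{prefix}_{name}.tsv"
        write_matrix(frame, p)
        paths.append(p)
    if result.geometry is not None:
        p = out_dir / f"{prefix}_geometry_folds.tsv"
        result.geometry.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def write_distance_curve(curve: DistanceCurve, path) -> None:
    pd.DataFrame(
        {
            "distance": curve.bin_centers,
            "mean_success": 1.0 - curve.mean_error,
            "n_pairs": curve.n_pairs,
        }
    ).to_csv(Path(path), sep="\t", index=False)


def read_edge_list(path):
    """Read a two-column (parent, child) edge-list text file as edges."""
    path = Path(path)
    edges = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}: expected two columns on line {i}")
        edges.append((parts[0], parts[1]))
    return edges


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` (an activity TSV) or ``spec_path`` (a
    generator spec JSON) provides the data.  ``seed`` is mandatory: every
    stochastic stage derives its stream from it.
    """

    seed: int
    output_dir: str = "results_run"
    input_path: str | None = None
    spec_path: str | None = None
    m: int = 5
    n_outer: int = 16
    n_inner: int = 16
    holdout_fraction: float = 0.10
    subspace_dim: int | None = None
    projection_dim: int | None = None
    hierarchy_path: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if (self.input_path is None) == (self.spec_path is None):
            raise ConfigError("provide exactly one of input_path or spec_path")
        for p in (self.input_path, self.spec_path, self.hierarchy_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"path does not exist: {p}")
        if not 0 < self.holdout_fraction < 1:
            raise ConfigError("holdout_fraction must lie in (0, 1)")
        if self.m < 1 or self.n_outer < 1 or self.n_inner < 1:
            raise ConfigError("m and fold counts must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data:
            raise ConfigError("seed is mandatory")
        return cls(**data)
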