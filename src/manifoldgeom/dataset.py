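"""Labeled exemplar-by-unit activity matrices.

An :class:`ActivityDataset` is the universal input of the pipeline: one row
per exemplar presentation, one column per unit (voxel, model feature, ...),
a concept label per row and, optionally, a ``trial_id`` grouping repeated
presentations of the same exemplar.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

__all__ = ["ActivityDataset", "collapse_trials"]


@dataclass
class ActivityDataset:
    """Activity patterns with concept labels.

    Parameters
    ----------
    patterns
        Real matrix of shape ``(n_rows, n_units)``; no missing values.
    labels
        Concept identifier per row.
    trial_id
        Optional integer per row grouping repeats of the same exemplar.
        Rows sharing a ``trial_id`` must share the same label.
    unit_ids
        Optional column names, one per unit.
    """

    patterns: np.ndarray
    labels: np.ndarray
    trial_id: np.ndarray | None = None
    unit_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 2:
            raise InputError("patterns must be a 2-D exemplar-by-unit matrix")
        if not np.all(np.isfinite(self.patterns)):
            raise InputError("patterns contain non-finite values")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.patterns.shape[0],):
            raise InputError("labels must match the number of pattern rows")
        if self.trial_id is not None:
            self.trial_id = np.asarray(self.trial_id, dtype=int)
            if self.trial_id.shape != (self.patterns.shape[0],):
                raise InputError("trial_id must match the number of pattern rows")
            frame = pd.DataFrame({"t": self.trial_id, "l": self.labels})
            if (frame.groupby("t")["l"].nunique() > 1).any():
                raise InputError("rows sharing a trial_id must share a label")
        if self.unit_ids is not None:
            self.unit_ids = [str(u) for u in self.unit_ids]
            if len(self.unit_ids) != self.patterns.shape[1]:
                raise InputError("unit_ids must match the number of unit columns")

    # -- basic introspection -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_units(self) -> int:
        return self.patterns.shape[1]

    @property
    def concepts(self) -> list:
        """Distinct concept labels, sorted for deterministic ordering."""
        return sorted(np.unique(self.labels).tolist())

    def concept_patterns(self, label) -> np.ndarray:
        """Rows belonging to one concept."""
        mask = self.labels == label
        if not mask.any():
            raise InputError(f"unknown concept {label!r}")
        return self.patterns[mask]

    # -- derived datasets ----------------------------------------------------

    def with_patterns(
        self, patterns: np.ndarray, unit_ids: list[str] | None = None
    ) -> "ActivityDataset":
        """Same rows/labels with a new unit space (projection, subsetting)."""
        return ActivityDataset(
            patterns=patterns,
            labels=self.labels.copy(),
            trial_id=None if self.trial_id is None else self.trial_id.copy(),
            unit_ids=unit_ids,
        )

    def select_units(self, indices: Sequence[int]) -> "ActivityDataset":
        idx = np.asarray(indices, dtype=int)
        unit_ids = None
        if self.unit_ids is not None:
            unit_ids = [self.unit_ids[i] for i in idx]
        return self.with_patterns(self.patterns[:, idx], unit_ids=unit_ids)

    # -- tabular round-trip --------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        units = self.unit_ids or [f"unit_{i}" for i in range(self.n_units)]
        data: dict = {"concept": self.labels}
        if self.trial_id is not None:
            data["trial_id"] = self.trial_id
        frame = pd.DataFrame(data)
        return pd.concat(
            [frame, pd.DataFrame(self.patterns, columns=units)], axis=1
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ActivityDataset":
        if frame.shape[1] < 2:
            raise InputError("need a label column plus at least one unit column")
        cols = list(frame.columns)
        labels = frame[cols[0]].to_numpy()
        trial = None
        unit_cols = cols[1:]
        if len(cols) > 2 and cols[1] == "trial_id":
            trial = frame["trial_id"].to_numpy()
            unit_cols = cols[2:]
        patterns = frame[unit_cols].to_numpy(dtype=float)
        return cls(patterns, labels, trial_id=trial, unit_ids=list(unit_cols))


def collapse_trials(dataset: ActivityDataset) -> ActivityDataset:
    """Average all repeats of each exemplar into a single row.

    Datasets without a ``trial_id`` column are returned unchanged.  Exemplar
    order follows the first appearance of each ``trial_id``, so collapsing is
    deterministic.
    """
    if dataset.trial_id is None:
        return dataset
    order = pd.unique(dataset.trial_id)
    rows, labels = [], []
    for t in order:
        mask = dataset.trial_id == t
        rows.append(dataset.patterns[mask].mean(axis=0))
        labels.append(dataset.labels[mask][0])
    return ActivityDataset(
        patterns=np.asarray(rows),
        labels=np.asarray(labels),
        trial_id=None,
        unit_ids=None if dataset.unit_ids is None else list(dataset.unit_ids),
    )
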