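"""Data containers for the census layer, survey table and QA resurvey table.

The census layer is the dense source (one remote-sensing proportion per grid
cell, with coordinates); the survey table is the sparse, unbiased source
(ground-survey proportions for a subset of cells); the QA table holds paired
independent resurveys used to elicit the prior on survey error.

All three round-trip through delimited text tables with headers
(``cell_id,easting,northing,q`` / ``cell_id,y`` / ``cell_id,y_first,y_second``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CensusLayer", "SurveyTable", "QATable", "DataConsistencyError"]

# round-trip noise this small is clamped with a warning; larger is an error
_CLAMP_TOL = 1e-9


class DataConsistencyError(ValueError):
    """Raised when tables disagree (e.g. survey cell absent from census)."""


def _check_proportions(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    low, high = values.min(initial=0.0), values.max(initial=1.0)
    if low < -_CLAMP_TOL or high > 1.0 + _CLAMP_TOL:
        raise ValueError(f"{name} outside [0, 1]: range [{low}, {high}]")
    if low < 0.0 or high > 1.0:
        warnings.warn(
            f"{name} marginally outside [0, 1] (<= {_CLAMP_TOL}); clamping",
            stacklevel=3,
        )
        values = np.clip(values, 0.0, 1.0)
    return values


def _check_unique(cell_id: np.ndarray, name: str) -> None:
    if len(np.unique(cell_id)) != len(cell_id):
        raise ValueError(f"duplicate cell_ids in {name}")


@dataclass
class CensusLayer:
    """Dense grid of remote-sensing proportions with cell coordinates."""

    cell_id: np.ndarray
    easting: np.ndarray
    northing: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id)
        self.easting = np.asarray(self.easting, dtype=float)
        self.northing = np.asarray(self.northing, dtype=float)
        n = len(self.cell_id)
        if not (len(self.easting) == len(self.northing) == len(np.asarray(self.q)) == n):
            raise ValueError("census columns have unequal lengths")
        _check_unique(self.cell_id, "census layer")
        if n and not (np.all(np.isfinite(self.easting)) and np.all(np.isfinite(self.northing))):
            raise ValueError("census coordinates must be finite")
        self.q = _check_proportions(self.q, "census q")

    def __len__(self) -> int:
        return len(self.cell_id)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CensusLayer":
        return cls(
            cell_id=frame["cell_id"].to_numpy(),
            easting=frame["easting"].to_numpy(dtype=float),
            northing=frame["northing"].to_numpy(dtype=float),
            q=frame["q"].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "CensusLayer":
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "easting": self.easting,
                "northing": self.northing,
                "q": self.q,
            }
        )

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    def index_of(self, cell_id: np.ndarray) -> np.ndarray:
        """Positions of ``cell_id`` within the layer; error if any missing."""
        order = np.argsort(self.cell_id, kind="stable")
        pos = np.searchsorted(self.cell_id[order], cell_id)
        pos = np.clip(pos, 0, len(self) - 1)
        idx = order[pos]
        if len(self) == 0 or not np.array_equal(self.cell_id[idx], np.asarray(cell_id)):
            raise DataConsistencyError("cell_id not present in census layer")
        return idx


@dataclass
class SurveyTable:
    """Sparse ground-survey proportions keyed to census cells."""

    cell_id: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id)
        if len(self.cell_id) != len(np.asarray(self.y)):
            raise ValueError("survey columns have unequal lengths")
        _check_unique(self.cell_id, "survey table")
        self.y = _check_proportions(self.y, "survey y")

    def __len__(self) -> int:
        return len(self.cell_id)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurveyTable":
        return cls(
            cell_id=frame["cell_id"].to_numpy(),
            y=frame["y"].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "SurveyTable":
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_id, "y": self.y})

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class QATable:
    """Paired independent resurveys of the same cells (quality assurance).

    The two visits record the same ground truth with independent errors, so
    their difference carries twice the survey error variance; at least two
    rows are required to estimate it.
    """

    cell_id: np.ndarray
    y_first: np.ndarray
    y_second: np.ndarray

    def __post_init__(self) -> None:
        self.cell_id = np.asarray(self.cell_id)
        n = len(self.cell_id)
        if not (len(np.asarray(self.y_first)) == len(np.asarray(self.y_second)) == n):
            raise ValueError("QA columns have unequal lengths")
        self.y_first = _check_proportions(self.y_first, "QA y_first")
        self.y_second = _check_proportions(self.y_second, "QA y_second")

    def __len__(self) -> int:
        return len(self.cell_id)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "QATable":
        return cls(
            cell_id=frame["cell_id"].to_numpy(),
            y_first=frame["y_first"].to_numpy(dtype=float),
            y_second=frame["y_second"].to_numpy(dtype=float),
        )

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "QATable":
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cell_id": self.cell_id, "y_first": self.y_first, "y_second": self.y_second}
        )

    def to_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)
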