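"""Single-source extent estimators and the source-agreement diagnostic.

These are the two baselines the combined model is compared against: the
census total just sums the remote-sensing proportions over every cell, and
the survey total expands the mean of the sampled ground-survey proportions to
the full grid (unstratified mean expansion — the simulation design has no
strata).  ``source_agreement`` is the squared Pearson correlation between the
two sources on the cells where both are observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import CensusLayer, SurveyTable

__all__ = [
    "ExtentEstimate",
    "census_total",
    "survey_total",
    "source_agreement",
    "EstimationError",
    "DegenerateVarianceWarning",
]


class EstimationError(ValueError):
    """An estimator was asked for with insufficient data."""


class DegenerateVarianceWarning(UserWarning):
    """Agreement undefined because one source is constant."""


@dataclass(frozen=True)
class ExtentEstimate:
    """A total habitat extent (area units) and the method that produced it."""

    total: float
    method: str

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValueError("extent cannot be negative")


def census_total(census: CensusLayer, cell_area: float = 1.0) -> ExtentEstimate:
    """Census-only extent: ``cell_area * sum_i Q_i``."""
    if len(census) == 0:
        raise EstimationError("census layer is empty")
    return ExtentEstimate(
        total=float(cell_area * np.sum(census.q)), method="census_only"
    )


def survey_total(
    census_size: int, survey: SurveyTable, cell_area: float = 1.0
) -> ExtentEstimate:
    """Survey-only extent by mean expansion:
    ``cell_area * census_size * mean(Y_i)``."""
    if len(survey) == 0:
        raise EstimationError("survey table is empty")
    return ExtentEstimate(
        total=float(cell_area * census_size * np.mean(survey.y)),
        method="survey_only",
    )


def source_agreement(census: CensusLayer, survey: SurveyTable) -> float:
    """R^2 between the two sources on the jointly observed cells.

    Squared Pearson correlation between paired ``(Y_i, Q_i)``; a constant
    side makes the correlation undefined, reported as 0 with a warning.
    """
    if len(survey) < 3:
        raise EstimationError("need at least 3 paired cells for agreement")
    idx = census.index_of(survey.cell_id)
    q = census.q[idx]
    y = survey.y
    if np.ptp(q) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "one source is constant on the paired cells; agreement undefined, "
            "reporting 0",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        return 0.0
    r = np.corrcoef(y, q)[0, 1]
    return float(r * r)
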