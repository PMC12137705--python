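"""Region-specific and brain-average structure-function coupling.

Coupling of region i is the Pearson correlation r_C between the i-th column
of a similarity/communication matrix and the i-th column of a condition's FC
matrix, taken over the N-1 off-diagonal entries.  A cohort's coupling values
form a 4-D table indexed participant x condition x measure x region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    FunctionalConnectome,
    ParticipantTable,
    ValidationError,
)
from .measures import PredictorMatrix

__all__ = [
    "CouplingTable",
    "BrainAverageCoupling",
    "regional_coupling",
    "coupling_table",
    "brain_average",
]

log = logging.getLogger("couplemap")


def _offdiag_columns(m: np.ndarray) -> np.ndarray:
    """Column profiles with the diagonal entry removed; row k = column k,
    shape (N, N-1)."""
    n = m.shape[0]
    return m.T[~np.eye(n, dtype=bool)].reshape(n, n - 1)


def _column_pearson(x: np.ndarray, y: np.ndarray, warn: bool = True) -> np.ndarray:
    """Row-wise Pearson correlation of two (N, K) profile stacks; degenerate
    (zero-variance) rows yield 0."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.sum(xc**2, axis=1))
    sy = np.sqrt(np.sum(yc**2, axis=1))
    denom = sx * sy
    bad = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sum(xc * yc, axis=1) / np.where(bad, 1.0, denom)
    if bad.any():
        if warn:
            warnings.warn(
                f"constant profile for region(s) {np.flatnonzero(bad).tolist()}: "
                "coupling set to 0",
                stacklevel=3,
            )
        r[bad] = 0.0
    return np.clip(r, -1.0, 1.0)


def regional_coupling(
    pred: PredictorMatrix, fc: FunctionalConnectome
) -> np.ndarray:
    """Vector of N region-specific coupling values r_C.

    r_C[i] = pearson(pred column i, fc column i) over the off-diagonal
    entries.  Constant (degenerate) columns give r_C = 0 with a warning.
    """
    if pred.values.shape != fc.values.shape:
        raise ValidationError(
            f"predictor {pred.values.shape} and FC {fc.values.shape} differ in size"
        )
    return _column_pearson(_offdiag_columns(pred.values), _offdiag_columns(fc.values))


@dataclass
class CouplingTable:
    """r_C values indexed [participant, condition, measure, region]."""

    values: np.ndarray
    participants: list[str]
    conditions: list[str]
    measures: list[str]
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        expected = (
            len(self.participants), len(self.conditions),
            len(self.measures), v.shape[-1] if v.ndim == 4 else -1,
        )
        if v.ndim != 4 or v.shape != expected:
            raise ValidationError(
                f"coupling table shape {v.shape} does not match its axes"
            )
        if np.any(np.isnan(v)) or np.any(np.abs(v) > 1.0 + 1e-12):
            raise ValidationError("coupling values must be finite and within [-1, 1]")
        self.values = v
        if not self.region_labels:
            self.region_labels = [f"R{i + 1}" for i in range(v.shape[-1])]

    @property
    def n_regions(self) -> int:
        return self.values.shape[-1]

    def condition_slice(self, condition: str) -> np.ndarray:
        """(n_participants, n_regions, n_measures) slice for one condition."""
        c = self.conditions.index(condition)
        return np.moveaxis(self.values[:, c], 1, 2)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (participant, condition, measure, region, r_C)."""
        idx = pd.MultiIndex.from_product(
            [self.participants, self.conditions, self.measures, self.region_labels],
            names=["participant", "condition", "measure", "region"],
        )
        return pd.DataFrame({"r_C": self.values.ravel()}, index=idx).reset_index()


@dataclass
class BrainAverageCoupling:
    """Brain-average coupling per participant, averaged over one axis.

    ``axis`` records what was averaged out: ``over_measures`` leaves one value
    per participant x condition, ``over_conditions`` one per participant x
    measure.  ``df`` is participants x remaining-levels.
    """

    df: pd.DataFrame
    axis: str

    @property
    def levels(self) -> list[str]:
        return list(self.df.columns)

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)


def coupling_table(
    participants: ParticipantTable | Sequence[str],
    predictors: Mapping[str, Sequence[PredictorMatrix]],
    fcs: Mapping[tuple[str, str], FunctionalConnectome],
    conditions: Sequence[str],
    measures: Sequence[str] | None = None,
) -> CouplingTable:
    """Full 4-D coupling table for a cohort.

    ``predictors`` maps participant id -> list of predictor matrices (one per
    measure); ``fcs`` maps (participant id, condition) -> FC.  Participants
    missing any condition are excluded with a log entry.
    """
    if isinstance(participants, ParticipantTable):
        pids = participants.participant_ids
    else:
        pids = [str(p) for p in participants]
    conditions = list(conditions)
    kept, rows = [], []
    for pid in pids:
        if pid not in predictors:
            log.warning("participant %s: no predictor matrices; excluded", pid)
            continue
        missing = [c for c in conditions if (pid, c) not in fcs]
        if missing:
            log.warning("participant %s: missing condition(s) %s; excluded",
                        pid, missing)
            continue
        preds = predictors[pid]
        if measures is None:
            measures = [p.measure for p in preds]
        pred_profiles = [_offdiag_columns(p.values) for p in preds]
        cond_rows = []
        for cond in conditions:
            fc_prof = _offdiag_columns(fcs[(pid, cond)].values)
            cond_rows.append(
                [_column_pearson(pp, fc_prof) for pp in pred_profiles]
            )
        rows.append(cond_rows)
        kept.append(pid)
    if not kept:
        raise ValidationError("no participant has complete data")
    values = np.asarray(rows, dtype=float)
    labels = list(next(iter(predictors.values()))[0].meta.get("region_labels", []))
    return CouplingTable(values, kept, conditions, list(measures), labels)


def brain_average(table: CouplingTable, axis: str) -> BrainAverageCoupling:
    """Mean coupling over regions, then over measures or conditions.

    ``axis="over_measures"`` -> one value per participant x condition;
    ``axis="over_conditions"`` -> one per participant x measure.
    """
    region_mean = table.values.mean(axis=3)  # (part, cond, meas)
    if axis == "over_measures":
        vals, cols = region_mean.mean(axis=2), table.conditions
    elif axis == "over_conditions":
        vals, cols = region_mean.mean(axis=1), table.measures
    else:
        raise ValueError("axis must be 'over_measures' or 'over_conditions'")
    df = pd.DataFrame(vals, index=table.participants, columns=cols)
    return BrainAverageCoupling(df, axis)
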