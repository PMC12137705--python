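"""Core data containers for connectome-based coupling analyses.

The analysis operates on three kinds of per-participant objects: a weighted
structural connectome (SC, e.g. streamline-density weights on a cortical
parcellation), one functional connectome (FC) per scanning condition
(Fisher z-transformed correlations of regional activity time courses), and a
participant table holding the phenotype plus nuisance covariates (age, gender,
handedness, condition-specific in-scanner head motion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "HCP_CONDITIONS",
    "ValidationError",
    "StructuralConnectome",
    "FunctionalConnectome",
    "ParticipantTable",
    "AnalysisConfig",
]

#: canonical measure order: cosine similarity, path length, communicability,
#: search information.  Ties downstream are always broken in this order.
MEASURES = ("CoS", "PL", "G", "SI")

#: the eight scanning conditions of a typical young-adult cohort: resting
#: state plus seven in-scanner tasks.
HCP_CONDITIONS = ("RES", "EMO", "GAM", "LAN", "MOT", "REL", "SOC", "WM")

#: asymmetry below this is treated as floating-point I/O noise and averaged out
ASYMMETRY_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a connectome matrix violates its structural invariants."""


def _symmetrize(values: np.ndarray, *, strict: bool, what: str) -> np.ndarray:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"{what}: matrix must be square, got {values.shape}")
    asym = float(np.max(np.abs(values - values.T))) if values.size else 0.0
    if asym > ASYMMETRY_TOL:
        if strict:
            raise ValidationError(
                f"{what}: max asymmetry {asym:.3g} exceeds tolerance {ASYMMETRY_TOL:g}"
            )
        warnings.warn(
            f"{what}: max asymmetry {asym:.3g} exceeds {ASYMMETRY_TOL:g}; "
            "symmetrizing by averaging",
            stacklevel=3,
        )
    return (values + values.T) / 2.0


def _default_labels(n: int) -> list[str]:
    return [f"R{i + 1}" for i in range(n)]


@dataclass
class StructuralConnectome:
    """One participant's symmetric weighted structural connectivity matrix.

    Weights are non-negative, unitless streamline-density-like values with a
    zero diagonal.  Asymmetry beyond floating-point tolerance is rejected;
    tiny asymmetry is averaged away.
    """

    participant_id: str
    weights: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        w = _symmetrize(w, strict=True, what=f"SC[{self.participant_id}]")
        if w.shape[0] < 3:
            raise ValidationError("SC needs at least 3 regions")
        if not np.all(np.isfinite(w)):
            raise ValidationError("SC weights must be finite")
        if np.any(w < 0):
            raise ValidationError("SC weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if not self.region_labels:
            self.region_labels = _default_labels(w.shape[0])
        elif len(self.region_labels) != w.shape[0]:
            raise ValidationError("region_labels length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class FunctionalConnectome:
    """One participant x condition functional connectivity matrix.

    Entries are Fisher z-transformed Pearson correlations between regional
    activity time courses.  The diagonal (self-correlation, infinite after the
    z-transform) is stored as 0 and ignored by every consumer.
    """

    participant_id: str
    condition: str
    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v = _symmetrize(
            v, strict=False, what=f"FC[{self.participant_id},{self.condition}]"
        )
        np.fill_diagonal(v, 0.0)
        if not np.all(np.isfinite(v)):
            raise ValidationError(
                f"FC[{self.participant_id},{self.condition}]: "
                "non-finite off-diagonal entries"
            )
        self.values = v
        if not self.region_labels:
            self.region_labels = _default_labels(v.shape[0])
        elif len(self.region_labels) != v.shape[0]:
            raise ValidationError("region_labels length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


class ParticipantTable:
    """Phenotype and nuisance covariates for a cohort.

    Wraps a DataFrame with columns ``participant_id``, ``g`` (phenotype
    score), ``age`` (years), ``gender`` (0/1), ``handedness`` (signed
    laterality score) and one ``motion_<condition>`` column per analyzed
    condition (mean framewise displacement in mm).
    """

    BASE_COLUMNS = ("participant_id", "g", "age", "gender", "handedness")

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True).copy()
        for col in self.BASE_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"participant table is missing column {col!r}")
        motion_cols = [c for c in df.columns if c.startswith("motion_")]
        if df[list(self.BASE_COLUMNS[1:]) + motion_cols].isna().any().any():
            raise ValidationError("participant table contains missing values")
        df["participant_id"] = df["participant_id"].astype(str)
        self.df = df

    @property
    def participant_ids(self) -> list[str]:
        return self.df["participant_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        return [c[len("motion_"):] for c in self.df.columns if c.startswith("motion_")]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def g(self) -> np.ndarray:
        return self.df["g"].to_numpy(dtype=float)

    def motion(self, condition: str) -> np.ndarray:
        col = f"motion_{condition}"
        if col not in self.df.columns:
            raise ValidationError(f"no motion covariate for condition {condition!r}")
        return self.df[col].to_numpy(dtype=float)

    def covariates(self, condition: str | None = None) -> np.ndarray:
        """Covariate matrix (age, gender, handedness[, condition motion])."""
        cols = [
            self.df["age"].to_numpy(dtype=float),
            self.df["gender"].to_numpy(dtype=float),
            self.df["handedness"].to_numpy(dtype=float),
        ]
        if condition is not None:
            cols.append(self.motion(condition))
        return np.column_stack(cols)

    def subset(self, ids: Sequence[str]) -> "ParticipantTable":
        """Row subset in the order of ``ids``; missing ids raise."""
        wanted = [str(i) for i in ids]
        indexed = self.df.set_index("participant_id", drop=False)
        missing = [i for i in wanted if i not in indexed.index]
        if missing:
            raise ValidationError(f"unknown participant id(s) {missing}")
        return ParticipantTable(indexed.loc[wanted].reset_index(drop=True))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ParticipantTable(n={len(self)}, "
            f"conditions={self.conditions})"
        )


@dataclass
class AnalysisConfig:
    """Knobs of the coupling/prediction pipeline.

    ``bonferroni_alpha`` defaults to 0.05 / 4, the corrected threshold for
    testing four coupling measures per condition.  ``weight_to_length``
    selects how structural weights map to traversal lengths for shortest-path
    based measures ("inverse" -> 1/w, "neglog" -> -log(w / max w)) and
    ``inversion`` how path length and search information are adjusted so that
    larger values always mean easier communication ("negate" or "reciprocal").
    ``perm_repetitions`` is the reduced per-permutation repetition count used
    by the permutation machinery.
    """

    n_folds: int = 5
    n_repetitions: int = 100
    n_permutations: int = 1000
    alpha: float = 0.05
    bonferroni_alpha: float = 0.0125
    rng_seed: int = 0
    measure_set: tuple[str, ...] = MEASURES
    weight_to_length: str = "inverse"
    inversion: str = "negate"
    cos_exclude_direct: bool = True
    rest_condition: str = "RES"
    perm_repetitions: int = 10
    pairwise_adjust: str = "tukey"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        for name in ("alpha", "bonferroni_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.weight_to_length not in ("inverse", "neglog"):
            raise ValidationError("weight_to_length must be 'inverse' or 'neglog'")
        if self.inversion not in ("negate", "reciprocal"):
            raise ValidationError("inversion must be 'negate' or 'reciprocal'")
        self.measure_set = tuple(self.measure_set)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)
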