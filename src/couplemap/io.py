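"""Readers and writers for connectome matrices, participant tables and cohorts.

Storage layout: one matrix per file (delimited text or an HDF5 container),
filenames free-form; a YAML manifest binds a cohort together by listing, per
participant, the structural matrix and one or more functional matrices per
condition (multiple files per condition, e.g. opposite phase-encoding runs,
are averaged on load).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    FunctionalConnectome,
    ParticipantTable,
    StructuralConnectome,
    ValidationError,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_connectome_matrix",
    "write_connectome_matrix",
    "fc_from_timeseries",
    "average_runs",
    "Cohort",
    "load_cohort",
    "save_cohort",
]

log = logging.getLogger("couplemap")

_H5_SUFFIXES = {".h5", ".hdf5", ".hdf"}


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str] | None]:
    """Read an N x N matrix plus optional region labels from disk.

    Delimited text (``.csv``/``.tsv``/anything else) may carry a header row
    and index column of region labels; HDF5 containers hold datasets
    ``matrix`` and optionally ``labels``.
    """
    path = Path(path)
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "r") as f:
            values = np.asarray(f["matrix"][()], dtype=float)
            labels = None
            if "labels" in f:
                labels = [
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["labels"][()]
                ]
        return values, labels
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    first = path.read_text().lstrip().splitlines()[0]
    has_header = any(
        not _is_number(tok) for tok in first.strip().split(delim) if tok != ""
    )
    if has_header:
        df = pd.read_csv(path, sep=delim, index_col=0, float_precision="round_trip")
        return df.to_numpy(dtype=float), [str(c) for c in df.columns]
    return np.loadtxt(path, delimiter=delim, ndmin=2), None


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_matrix(
    path: str | Path,
    values: np.ndarray,
    labels: Sequence[str] | None = None,
    attrs: dict | None = None,
) -> Path:
    """Write a matrix (plus labels) as delimited text or HDF5, by suffix."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if path.suffix.lower() in _H5_SUFFIXES:
        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=values)
            if labels is not None:
                f.create_dataset(
                    "labels", data=np.array([str(s) for s in labels], dtype="S")
                )
            for k, v in (attrs or {}).items():
                f.attrs[k] = v
    else:
        delim = "," if path.suffix.lower() == ".csv" else "\t"
        if labels is not None:
            df = pd.DataFrame(values, index=list(labels), columns=list(labels))
            # 17 significant digits round-trip float64 exactly
            df.to_csv(path, sep=delim, float_format="%.17g")
        else:
            np.savetxt(path, values, delimiter=delim, fmt="%.17g")
    return path


def read_connectome_matrix(
    path: str | Path,
    kind: str,
    participant_id: str = "unknown",
    condition: str | None = None,
) -> StructuralConnectome | FunctionalConnectome:
    """Read and validate one connectome matrix.

    ``kind`` is ``"structural"`` or ``"functional"``; validation (symmetry,
    sign, finiteness) is delegated to the container types.
    """
    values, labels = read_matrix(path)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"{path}: expected a square matrix, got {values.shape}")
    labels = labels or []
    if kind == "structural":
        return StructuralConnectome(participant_id, values, list(labels))
    if kind == "functional":
        return FunctionalConnectome(
            participant_id, condition or "NA", values, list(labels)
        )
    raise ValueError(f"kind must be 'structural' or 'functional', got {kind!r}")


def write_connectome_matrix(
    path: str | Path, conn: StructuralConnectome | FunctionalConnectome
) -> Path:
    values = conn.weights if isinstance(conn, StructuralConnectome) else conn.values
    attrs = {"participant_id": conn.participant_id}
    if isinstance(conn, FunctionalConnectome):
        attrs["condition"] = conn.condition
    return write_matrix(path, values, conn.region_labels, attrs)


def fc_from_timeseries(
    ts: np.ndarray,
    participant_id: str = "unknown",
    condition: str = "NA",
    region_labels: Sequence[str] | None = None,
) -> FunctionalConnectome:
    """Build an FC matrix from a T x N matrix of regional time courses.

    Off-diagonal entries are Fisher z-transformed Pearson correlations,
    atanh(r); the diagonal is stored as 0.  Perfectly (anti)correlated pairs
    would map to +/-inf and are rejected.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValidationError("time-series matrix must be T x N with T >= 3")
    labels = list(region_labels) if region_labels else [
        f"R{i + 1}" for i in range(ts.shape[1])
    ]
    sd = ts.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValidationError(
            f"constant time series for region(s) {[labels[i] for i in bad]}"
        )
    r = np.corrcoef(ts, rowvar=False)
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) >= 1.0 - 1e-15):
        i, j = np.unravel_index(int(np.argmax(np.abs(r))), r.shape)
        raise ValidationError(
            f"|r| = 1 between regions {labels[i]} and {labels[j]}: "
            "Fisher z-transform undefined"
        )
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return FunctionalConnectome(participant_id, condition, z, labels)


def average_runs(fc_list: Sequence[FunctionalConnectome]) -> FunctionalConnectome:
    """Element-wise mean of several FC matrices of one participant/condition
    (e.g. the two opposite phase-encoding runs)."""
    if not fc_list:
        raise ValidationError("average_runs needs at least one FC matrix")
    first = fc_list[0]
    for fc in fc_list[1:]:
        if fc.values.shape != first.values.shape:
            raise ValidationError("cannot average FC matrices of different sizes")
        if fc.region_labels != first.region_labels:
            raise ValidationError("cannot average FC matrices with different labels")
        if (fc.participant_id, fc.condition) != (first.participant_id, first.condition):
            raise ValidationError(
                "cannot average FC matrices of different participants/conditions"
            )
    mean = np.mean([fc.values for fc in fc_list], axis=0)
    return FunctionalConnectome(
        first.participant_id, first.condition, mean, list(first.region_labels)
    )


@dataclass
class Cohort:
    """In-memory cohort: structural and functional connectomes + phenotypes."""

    scs: dict[str, StructuralConnectome]
    fcs: dict[tuple[str, str], FunctionalConnectome]
    participants: ParticipantTable
    conditions: list[str] = field(default_factory=list)

    @property
    def participant_ids(self) -> list[str]:
        return list(self.scs)


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a YAML manifest.

    Manifest schema::

        conditions: [RES, WM, ...]
        participants_file: participants.tsv
        entries:
          - id: sub-01
            sc: sub-01_sc.tsv
            fc: {RES: [sub-01_RES.tsv], WM: [...]}

    Paths are resolved relative to the manifest.  Multiple FC files per
    condition are averaged run-wise on load.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    spec = yaml.safe_load(manifest_path.read_text())
    conditions = [str(c) for c in spec["conditions"]]
    participants = ParticipantTable(
        pd.read_csv(root / spec["participants_file"], sep="\t")
    )
    scs: dict[str, StructuralConnectome] = {}
    fcs: dict[tuple[str, str], FunctionalConnectome] = {}
    for entry in spec["entries"]:
        pid = str(entry["id"])
        scs[pid] = read_connectome_matrix(root / entry["sc"], "structural", pid)
        for cond, paths in entry["fc"].items():
            runs = [
                read_connectome_matrix(root / p, "functional", pid, str(cond))
                for p in (paths if isinstance(paths, list) else [paths])
            ]
            fcs[(pid, str(cond))] = average_runs(runs)
    return Cohort(scs, fcs, participants, conditions)


def save_cohort(cohort: Cohort, out_dir: str | Path, fmt: str = "tsv") -> Path:
    """Write a cohort to ``out_dir`` in the manifest + one-matrix-per-file
    layout that :func:`load_cohort` consumes.  Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = {"tsv": ".tsv", "csv": ".csv", "h5": ".h5"}[fmt]
    entries = []
    for pid, sc in cohort.scs.items():
        sc_name = f"{pid}_sc{suffix}"
        write_connectome_matrix(out / sc_name, sc)
        fc_map = {}
        for cond in cohort.conditions:
            fc = cohort.fcs.get((pid, cond))
            if fc is None:
                continue
            fc_name = f"{pid}_{cond}{suffix}"
            write_connectome_matrix(out / fc_name, fc)
            fc_map[cond] = [fc_name]
        entries.append({"id": pid, "sc": sc_name, "fc": fc_map})
    cohort.participants.df.to_csv(out / "participants.tsv", sep="\t", index=False)
    manifest = {
        "conditions": list(cohort.conditions),
        "participants_file": "participants.tsv",
        "entries": entries,
    }
    manifest_path = out / "cohort.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def validate_cohort(cohort: Cohort) -> list[str]:
    """Cross-check a cohort's internal consistency; returns problem strings."""
    problems = []
    n = None
    for pid, sc in cohort.scs.items():
        if n is None:
            n = sc.n_regions
        elif sc.n_regions != n:
            problems.append(f"{pid}: SC has {sc.n_regions} regions, expected {n}")
        for cond in cohort.conditions:
            fc = cohort.fcs.get((pid, cond))
            if fc is None:
                problems.append(f"{pid}: missing FC for condition {cond}")
            elif fc.n_regions != sc.n_regions:
                problems.append(f"{pid}: FC[{cond}] size mismatch")
    table_ids = set(cohort.participants.participant_ids)
    for pid in cohort.scs:
        if pid not in table_ids:
            problems.append(f"{pid}: not in participant table")
    missing_motion = [
        c for c in cohort.conditions if c not in cohort.participants.conditions
    ]
    if missing_motion:
        problems.append(f"participant table lacks motion for {missing_motion}")
    return problems
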