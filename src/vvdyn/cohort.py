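"""Cohort containers and long-format CSV I/O.

The unit of every analysis is a :class:`SubjectSeries`: one subject's strictly
increasing observation grid (months for the patient arm, days post-immunization
for the mouse arm) together with named, grid-aligned variable series.  A
:class:`Cohort` is an ordered collection of subjects plus optional generator
ground truth (injected couplings, event days) used by recovery tests.

On disk a cohort is a long-format CSV with header
``subject_id,group,time,time_unit,variable,value``; missing cells are written
as empty values and round-trip as NaN.  Ground truth travels in a sidecar JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SubjectSeries",
    "Cohort",
    "cohort_to_table",
    "table_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

VV = "ventricle_volume"

CSV_COLUMNS = ["subject_id", "group", "time", "time_unit", "variable", "value"]


@dataclass
class SubjectSeries:
    """One subject's aligned multivariate time series.

    Parameters
    ----------
    subject_id : str
        Unique identifier within the cohort.
    group : str
        One of ``healthy``, ``ms``, ``eae``.
    time : ndarray
        Strictly increasing observation grid.
    time_unit : str
        ``months`` or ``days``.
    variables : dict
        Variable name -> series aligned to ``time``; NaN marks missing cells.
    """

    subject_id: str
    group: str
    time: np.ndarray
    time_unit: str
    variables: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) == 0:
            raise ValueError("time grid must be a nonempty 1-D array")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"time grid of {self.subject_id!r} is not strictly increasing")
        if self.time_unit not in ("months", "days"):
            raise ValueError(f"unknown time unit {self.time_unit!r}")
        clean: dict[str, np.ndarray] = {}
        for name, series in self.variables.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(
                    f"series {name!r} of {self.subject_id!r} has length {arr.size}, "
                    f"grid has {self.time.size}"
                )
            clean[name] = arr
        self.variables = clean
        if VV in self.variables:
            vv = self.variables[VV]
            if np.any(vv[np.isfinite(vv)] <= 0):
                raise ValueError(f"ventricle volume of {self.subject_id!r} must be positive")

    @property
    def n_timepoints(self) -> int:
        return len(self.time)

    def has_complete(self, names: list[str]) -> bool:
        """True if every named series exists with no missing values."""
        return all(
            name in self.variables and np.all(np.isfinite(self.variables[name]))
            for name in names
        )


@dataclass
class Cohort:
    """Ordered collection of subjects with optional generator ground truth."""

    subjects: list[SubjectSeries]
    ground_truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectSeries]:
        return iter(self.subjects)

    def __getitem__(self, key: int | str) -> SubjectSeries:
        if isinstance(key, str):
            for s in self.subjects:
                if s.subject_id == key:
                    return s
            raise KeyError(key)
        return self.subjects[key]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def cohort_to_table(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to one record per (subject, time, variable)."""
    if len(cohort) == 0:
        raise ValueError("cannot serialize an empty cohort")
    frames = []
    for s in cohort:
        for name, series in s.variables.items():
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "group": s.group,
                        "time": s.time,
                        "time_unit": s.time_unit,
                        "variable": name,
                        "value": series,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[CSV_COLUMNS]


def table_to_cohort(table: pd.DataFrame) -> Cohort:
    """Assemble subjects from a long-format table, validating the schema."""
    missing = set(CSV_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"long-format table lacks columns: {sorted(missing)}")
    dup = table.duplicated(subset=["subject_id", "time", "variable"])
    if dup.any():
        row = table.loc[dup.idxmax()]
        raise ValueError(
            "duplicate cell for subject "
            f"{row['subject_id']!r} at time {row['time']} variable {row['variable']!r}"
        )
    subjects = []
    for sid, block in table.groupby("subject_id", sort=False):
        groups = block["group"].unique()
        units = block["time_unit"].unique()
        if len(groups) != 1 or len(units) != 1:
            raise ValueError(f"subject {sid!r} mixes groups or time units")
        per_var_sorted = block.groupby("variable")["time"].apply(
            lambda s: s.is_monotonic_increasing
        )
        if not per_var_sorted.all():
            warnings.warn(f"time points of subject {sid!r} were unsorted; sorting", stacklevel=2)
        wide = block.pivot(index="time", columns="variable", values="value").sort_index()
        subjects.append(
            SubjectSeries(
                subject_id=str(sid),
                group=str(groups[0]),
                time=wide.index.to_numpy(dtype=float),
                time_unit=str(units[0]),
                variables={str(c): wide[c].to_numpy(dtype=float) for c in wide.columns},
            )
        )
    return Cohort(subjects=subjects)


def write_cohort_csv(cohort: Cohort, path: str | Path, ground_truth_path: str | Path | None = None) -> None:
    """Write the long-format CSV, plus a ground-truth JSON sidecar if requested."""
    table = cohort_to_table(cohort)
    table.to_csv(path, index=False, float_format="%.10g")
    if ground_truth_path is not None:
        Path(ground_truth_path).write_text(json.dumps(cohort.ground_truth, indent=1, sort_keys=True))


def read_cohort_csv(path: str | Path, ground_truth_path: str | Path | None = None) -> Cohort:
    """Read a cohort written by :func:`write_cohort_csv` (lossless round trip)."""
    table = pd.read_csv(path, dtype={"subject_id": str, "group": str, "variable": str})
    cohort = table_to_cohort(table)
    if ground_truth_path is not None:
        cohort.ground_truth = json.loads(Path(ground_truth_path).read_text())
    return cohort


def _ordered_variables(mapping: Mapping[str, np.ndarray]) -> list[str]:
    return list(mapping.keys())
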