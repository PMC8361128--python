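"""Data model and CSV readers/writers for trial-level pupillometry tables.

A *trial* is one stimulus-locked pupil-diameter recording: a uniform time
axis in milliseconds and one diameter sample (arbitrary units) per tick,
where blinks and tracking dropouts appear as missing samples.  A *cohort*
groups trials by subject, each subject carrying a binary diagnostic label
(unmedicated ADHD-positive vs healthy control).  A *feature matrix* is the
subjects x features table that the statistics and classifier-evaluation
stages consume.

Missing pupil samples are represented as IEEE NaN in float arrays — the
distinguished missing marker of the numpy/pandas ecosystem — never as a
sentinel value inside the valid data range.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError, ValidationError

__all__ = [
    "Group",
    "Trial",
    "Subject",
    "Cohort",
    "FeatureMatrix",
    "read_trials",
    "write_trials",
    "read_feature_matrix",
    "write_feature_matrix",
]

#: Group labels as written in CSV files, mapped at the I/O boundary.
GROUP_LABELS = {"ADHD": "ADHD_POSITIVE", "CTRL": "CONTROL"}
_LABELS_OUT = {v: k for k, v in GROUP_LABELS.items()}

#: Decimal precision used when writing floats (round-trip safe for float64).
_FLOAT_FMT = "%.17g"


class Group(enum.Enum):
    """Binary diagnostic group of a subject."""

    ADHD_POSITIVE = "ADHD_POSITIVE"
    CONTROL = "CONTROL"

    @classmethod
    def from_label(cls, label: str) -> "Group":
        try:
            return cls(GROUP_LABELS[label.strip()])
        except KeyError:
            raise ValidationError(
                f"unknown group label {label!r}; expected one of "
                f"{sorted(GROUP_LABELS)}"
            ) from None

    @property
    def label(self) -> str:
        """The string written to files ('ADHD' or 'CTRL')."""
        return _LABELS_OUT[self.value]


@dataclass(frozen=True)
class Trial:
    """One pupil-diameter series for one subject/trial.

    Parameters
    ----------
    subject_id, trial_id
        Opaque identifiers.
    t_ms
        Strictly increasing sample times in milliseconds with constant
        spacing equal to ``sample_period_ms``.
    pupil
        Pupil diameter per sample (arbitrary units); NaN marks a missing
        sample.
    sample_period_ms
        Sampling period: 1 for raw 1 kHz data, 16 after moving-average
        reduction.
    """

    subject_id: str
    trial_id: str
    t_ms: np.ndarray
    pupil: np.ndarray
    sample_period_ms: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=float)
        p = np.asarray(self.pupil, dtype=float)
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "pupil", p)
        if t.ndim != 1 or p.ndim != 1 or len(t) != len(p):
            raise ValidationError(
                f"trial {self.trial_id}: t_ms and pupil must be 1-D and "
                f"equally long (got {len(t)} vs {len(p)})"
            )
        if len(t) < 1:
            raise ValidationError(
                f"trial {self.trial_id}: need at least 1 sample"
            )
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(
                f"trial {self.trial_id}: t_ms must be strictly increasing"
            )
        if self.sample_period_ms <= 0:
            raise ValidationError(
                f"trial {self.trial_id}: sample_period_ms must be positive"
            )
        if not np.allclose(dt, self.sample_period_ms, rtol=1e-9, atol=1e-9):
            raise ValidationError(
                f"trial {self.trial_id}: sample spacing is not constant at "
                f"{self.sample_period_ms} ms"
            )

    def __len__(self) -> int:
        return len(self.pupil)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.pupil).sum())

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / len(self)

    @property
    def duration_ms(self) -> float:
        """Trial span in ms counting the final sample's full period."""
        return float(self.t_ms[-1] - self.t_ms[0] + self.sample_period_ms)

    def with_pupil(self, pupil: np.ndarray) -> "Trial":
        return Trial(self.subject_id, self.trial_id, self.t_ms.copy(),
                     np.asarray(pupil, dtype=float), self.sample_period_ms)


@dataclass
class Subject:
    subject_id: str
    group: Group
    trials: list[Trial] = field(default_factory=list)


@dataclass
class Cohort:
    """A collection of labelled subjects; the unit the pipeline consumes."""

    subjects: list[Subject]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        for s in self.subjects:
            if not s.trials:
                raise ValidationError(
                    f"subject {s.subject_id} has no trials"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def n_trials(self) -> int:
        return sum(len(s.trials) for s in self.subjects)

    def group_counts(self) -> dict[Group, int]:
        counts: dict[Group, int] = {g: 0 for g in Group}
        for s in self.subjects:
            counts[s.group] += 1
        return counts

    def require_both_groups(self) -> None:
        counts = self.group_counts()
        if min(counts.values()) == 0:
            raise ValidationError(
                "group comparison requires both groups to be non-empty; "
                f"got { {g.label: n for g, n in counts.items()} }"
            )


@dataclass
class FeatureMatrix:
    """Subjects x named-features table with binary group labels.

    ``values[i, j]`` is feature ``feature_names[j]`` for subject
    ``subject_ids[i]``; every entry is finite after per-subject aggregation.
    """

    subject_ids: list[str]
    labels: list[Group]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = len(self.subject_ids), len(self.feature_names)
        if len(self.labels) != n:
            raise ValidationError("labels must match subject_ids in length")
        if self.values.shape != (n, m):
            raise ValidationError(
                f"values shape {self.values.shape} != ({n}, {m})"
            )
        if len(set(self.feature_names)) != m:
            raise ValidationError("feature names must be unique")
        if m == 0:
            raise ValidationError("feature matrix needs at least one feature")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value for subject {self.subject_ids[bad[0]]}, "
                f"feature {self.feature_names[bad[1]]}"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def label_array(self, positive: Group = Group.ADHD_POSITIVE) -> np.ndarray:
        """Binary 0/1 label vector with ``positive`` coded as 1."""
        return np.array([1 if g is positive else 0 for g in self.labels])

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise ParameterError(f"unknown feature {name!r}") from None
        return self.values[:, j]

    def group_values(self, name: str) -> dict[Group, np.ndarray]:
        col = self.column(name)
        lab = np.array([g.value for g in self.labels])
        return {g: col[lab == g.value] for g in Group}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "group", [g.label for g in self.labels])
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.labels == other.labels
            and self.feature_names == other.feature_names
            and np.array_equal(self.values, other.values)
        )


_REQUIRED_COLUMNS = ("subject_id", "group", "trial_id", "t_ms", "pupil")


def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None,
                   required: Sequence[str]) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing column(s) {missing}; present: {list(df.columns)}"
        )
    return df


def read_trials(path, dialect: Mapping[str, str] | None = None) -> Cohort:
    """Read a long-format trial CSV into a validated :class:`Cohort`.

    The file has one row per sample with columns ``subject_id, group,
    trial_id, t_ms, pupil`` (blank pupil cells become missing samples).
    ``dialect`` maps canonical column names to the names used in the file,
    e.g. ``{"pupil": "diameter_au"}``.  Row order across trials is
    irrelevant; within a trial, rows are sorted by time and must then have
    a strictly increasing, uniformly spaced time axis.
    """
    df = pd.read_csv(path, dtype={0: str}, low_memory=False,
                     float_precision="round_trip")
    df = _apply_dialect(df, dialect, _REQUIRED_COLUMNS)
    df["subject_id"] = df["subject_id"].astype(str)
    df["trial_id"] = df["trial_id"].astype(str)

    subjects: list[Subject] = []
    for subject_id, sdf in df.groupby("subject_id", sort=True):
        groups = sdf["group"].unique()
        if len(groups) != 1:
            raise ValidationError(
                f"subject {subject_id} has conflicting group labels: "
                f"{sorted(groups)}"
            )
        group = Group.from_label(str(groups[0]))
        trials = []
        for trial_id, tdf in sdf.groupby("trial_id", sort=True):
            tdf = tdf.sort_values("t_ms", kind="mergesort")
            t = tdf["t_ms"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"subject {subject_id} trial {trial_id}: t_ms not "
                    "strictly increasing"
                )
            period = _infer_period(t, subject_id, str(trial_id))
            trials.append(Trial(
                subject_id=str(subject_id),
                trial_id=str(trial_id),
                t_ms=t,
                pupil=tdf["pupil"].to_numpy(dtype=float),
                sample_period_ms=period,
            ))
        subjects.append(Subject(str(subject_id), group, trials))
    return Cohort(subjects)


def _infer_period(t: np.ndarray, subject_id: str, trial_id: str) -> float:
    dt = np.diff(t)
    period = float(np.median(dt))
    if not np.allclose(dt, period, rtol=1e-9, atol=1e-9):
        raise ValidationError(
            f"subject {subject_id} trial {trial_id}: non-uniform sample "
            "spacing"
        )
    return period


def write_trials(cohort: Cohort, path) -> None:
    """Write a cohort as the long-format trial CSV accepted by
    :func:`read_trials`. Missing samples become empty cells."""
    frames = []
    for s in cohort:
        for tr in s.trials:
            frames.append(pd.DataFrame({
                "subject_id": tr.subject_id,
                "group": s.group.label,
                "trial_id": tr.trial_id,
                "t_ms": tr.t_ms,
                "pupil": tr.pupil,
            }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT, na_rep=""
    )


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Write ``fm`` as CSV: header ``subject_id,group,<features...>``.

    Floats are written with 17 significant digits so a read back with
    :func:`read_feature_matrix` reproduces the matrix bit-for-bit.
    """
    fm.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_matrix(path) -> FeatureMatrix:
    """Inverse of :func:`write_feature_matrix`."""
    df = pd.read_csv(path, dtype={"subject_id": str},
                     float_precision="round_trip")
    df = _apply_dialect(df, None, ("subject_id", "group"))
    feature_names = [c for c in df.columns if c not in ("subject_id", "group")]
    if not feature_names:
        raise SchemaError("feature matrix CSV has no feature columns")
    return FeatureMatrix(
        subject_ids=[str(s) for s in df["subject_id"]],
        labels=[Group.from_label(str(g)) for g in df["group"]],
        feature_names=feature_names,
        values=df[feature_names].to_numpy(dtype=float),
    )


def ms_to_index(ms: float, sample_period_ms: float) -> int:
    """Convert a millisecond offset to a 0-based sample index (floor)."""
    return int(math.floor(ms / sample_period_ms))
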