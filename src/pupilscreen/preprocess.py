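"""Per-trial cleaning: spline imputation, trial exclusion, block reduction.

The cleaning order is: (1) trials with more than ``max_missing_fraction``
of their samples missing are excluded (missingness is assessed on the raw
series, before any imputation, so the criterion is well-defined); (2)
remaining gaps — blinks and dropouts — are filled with a cubic spline
through the observed points; (3) the dense series is decimated by
non-overlapping block means (default 16 ms blocks), mapping an 8 s, 1 kHz
trial to 500 samples. Features downstream are computed on the reduced
series.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ParameterError, TooSparseError
from .trial_io import Cohort, Subject, Trial

__all__ = [
    "interpolate_missing",
    "exclude_trials",
    "reduce_series",
    "preprocess_trial",
    "preprocess_cohort",
]

#: Trials with a missing fraction strictly above this are excluded.
DEFAULT_MAX_MISSING_FRACTION = 0.8
#: Block width of the moving-average reduction, in milliseconds.
DEFAULT_WINDOW_MS = 16


def interpolate_missing(trial: Trial) -> Trial:
    """Fill missing samples with a cubic spline through the observed points.

    Uses the not-a-knot boundary condition, which reproduces any cubic
    polynomial trend exactly regardless of gap placement (a natural
    spline's zero-curvature end condition would distort curved series by
    ~1e-2 even far from the edges). Observed samples are returned
    unchanged. Leading and trailing missing runs are filled with the
    nearest observed value before splining, because extrapolating a cubic
    beyond its support is unstable.

    Raises
    ------
    TooSparseError
        If fewer than 4 samples are observed (the caller should have
        excluded such a trial).
    """
    pupil = trial.pupil
    missing = np.isnan(pupil)
    if not missing.any():
        return trial
    observed = ~missing
    if observed.sum() < 4:
        raise TooSparseError(
            f"trial {trial.trial_id}: only {int(observed.sum())} observed "
            "samples; need at least 4 for cubic-spline imputation"
        )
    filled = pupil.copy()
    obs_idx = np.flatnonzero(observed)
    # edge handling: constant extension into leading/trailing gaps
    filled[: obs_idx[0]] = pupil[obs_idx[0]]
    filled[obs_idx[-1] + 1:] = pupil[obs_idx[-1]]
    interior = missing.copy()
    interior[: obs_idx[0]] = False
    interior[obs_idx[-1] + 1:] = False
    if interior.any():
        spline = CubicSpline(
            trial.t_ms[observed], pupil[observed], bc_type="not-a-knot"
        )
        filled[interior] = spline(trial.t_ms[interior])
    return trial.with_pupil(filled)


def exclude_trials(
    trials: list[Trial],
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
) -> tuple[list[Trial], list[str]]:
    """Partition trials into (kept, dropped trial_ids) by missingness.

    A trial is dropped iff its missing fraction is *strictly* greater than
    ``max_missing_fraction`` ("more than 80% missing"): a trial at exactly
    the boundary is kept.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ParameterError("max_missing_fraction must lie in [0, 1]")
    kept, dropped = [], []
    for tr in trials:
        if tr.missing_fraction > max_missing_fraction:
            dropped.append(tr.trial_id)
        else:
            kept.append(tr)
    return kept, dropped


def reduce_series(trial: Trial, window_ms: float = DEFAULT_WINDOW_MS) -> Trial:
    """Decimate by non-overlapping block means of width ``window_ms``.

    Output sample ``k`` is the arithmetic mean of the k-th consecutive
    block of ``w = window_ms / sample_period_ms`` input samples and is
    stamped with the block's start time; a trailing remainder shorter than
    one block is discarded. An 8000-sample 1 kHz trial with the default
    16 ms window reduces to 500 samples at a 16 ms period.

    The input must be fully observed (run after imputation).
    """
    w_float = window_ms / trial.sample_period_ms
    w = int(round(w_float))
    if w < 1 or abs(w_float - w) > 1e-9:
        raise ParameterError(
            f"window of {window_ms} ms must span a whole positive number "
            f"of {trial.sample_period_ms} ms samples"
        )
    if np.isnan(trial.pupil).any():
        raise ParameterError(
            f"trial {trial.trial_id} has missing samples; interpolate first"
        )
    n_blocks = len(trial) // w
    if n_blocks < 1:
        raise ParameterError(
            f"trial {trial.trial_id}: too short for window {window_ms} ms"
        )
    blocks = trial.pupil[: n_blocks * w].reshape(n_blocks, w)
    return Trial(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        t_ms=trial.t_ms[: n_blocks * w : w].copy(),
        pupil=blocks.mean(axis=1),
        sample_period_ms=float(window_ms),
    )


def preprocess_trial(trial: Trial,
                     window_ms: float = DEFAULT_WINDOW_MS) -> Trial:
    """Impute then reduce one trial (exclusion is a cohort-level step)."""
    return reduce_series(interpolate_missing(trial), window_ms)


def preprocess_cohort(
    cohort: Cohort,
    max_missing_fraction: float = DEFAULT_MAX_MISSING_FRACTION,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> tuple[Cohort, dict[str, list[str]]]:
    """Exclude, impute and reduce every trial of every subject.

    Returns the cleaned cohort and a map subject_id -> dropped trial ids.
    A subject whose trials are all dropped is removed from the cohort
    (and reported in the map).
    """
    subjects = []
    dropped_map: dict[str, list[str]] = {}
    for s in cohort:
        kept, dropped = exclude_trials(s.trials, max_missing_fraction)
        if dropped:
            dropped_map[s.subject_id] = dropped
        if not kept:
            continue
        subjects.append(Subject(
            s.subject_id, s.group,
            [preprocess_trial(tr, window_ms) for tr in kept],
        ))
    return Cohort(subjects), dropped_map
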