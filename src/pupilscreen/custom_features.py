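"""The 22 custom per-trial pupillometric features.

All custom features are built from three quantities defined relative to an
origin sample ``(T_0, P_0)``:

* dilation velocity      ``V_i = (P_i - P_0) / (T_i - T_0)`` (units per ms),
* dilation acceleration  ``A_i = (V_i - V_0) / (T_i - T_0)``, where ``V_0``
  is the velocity at the first post-origin sample,
* accumulated velocity   ``AV_i = V_0 + V_1 + ... + V_i`` (prefix sum).

"Before the probe" quantities use the trial start as origin; "after the
probe" quantities re-anchor the origin at the probe sample (the stimulus
presented at 5000 ms into the 8 s trial), so post-stimulus velocity is
measured from the moment of presentation.

The canonical trial layout is 8000 ms with the probe at 5000 ms, and the
fixed analysis windows (e.g. 5000-7000 ms) are defined on that layout. For
scaled-down trials the windows are rescaled affinely within the pre- and
post-probe spans, so the catalogue stays well-defined; with the default
timing the literal windows are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, ValidationError, WindowError
from .trial_io import Trial

__all__ = [
    "ProbeTiming",
    "DilationSeries",
    "dilation_velocity",
    "dilation_acceleration",
    "dilation_series",
    "extract_custom_features",
    "list_custom_features",
    "CUSTOM_FEATURE_NAMES",
]

#: The 22 custom feature names, frozen, in catalogue order.
CUSTOM_FEATURE_NAMES: tuple[str, ...] = (
    "max_size_post_probe",        # 1  max value, 5000-7000 ms
    "max_size_pre_probe",         # 2  max value, 0-5000 ms
    "min_size_late",              # 3  min value, 6500-8000 ms
    "mean_size_mid_post_probe",   # 4  mean, 5500-7000 ms
    "size_std",                   # 5
    "size_kurtosis",              # 6
    "size_skew",                  # 7
    "size_median",                # 8
    "size_mean",                  # 9
    "mean_velocity_before",       # 10
    "mean_velocity_after",        # 11
    "max_velocity_before",        # 12
    "max_velocity_after",         # 13
    "max_accum_velocity_before",  # 14
    "max_accum_velocity_after",   # 15
    "accum_velocity_gain",        # 16 = item15 - item14
    "velocity_accum_gap",         # 17 = item13 - item14
    "mean_velocity_accum_gap",    # 18 = item11 - item14
    "velocity_accum_gap_dup",     # 19 = item17 under the literal reading
    "max_accel_post_probe",       # 20 max acceleration, 5000-7000 ms
    "min_accel_post_probe",       # 21 min acceleration, 5000-7000 ms
    "mean_accel_post_probe",      # 22 mean acceleration, 5000-7000 ms
)

# canonical layout the window constants refer to
_CANON_PROBE = 5000.0
_CANON_END = 8000.0


@dataclass(frozen=True)
class ProbeTiming:
    """Stimulus timing of a trial: probe onset and trial end, in ms."""

    probe_ms: float = 5000.0
    trial_end_ms: float = 8000.0

    def __post_init__(self) -> None:
        if not 0 < self.probe_ms < self.trial_end_ms:
            raise ParameterError(
                "require 0 < probe_ms < trial_end_ms, got "
                f"{self.probe_ms} / {self.trial_end_ms}"
            )

    def scale_ms(self, canonical_ms: float) -> float:
        """Map a canonical-layout time to this timing (affine per span)."""
        if canonical_ms <= _CANON_PROBE:
            return canonical_ms / _CANON_PROBE * self.probe_ms
        frac = (canonical_ms - _CANON_PROBE) / (_CANON_END - _CANON_PROBE)
        return self.probe_ms + frac * (self.trial_end_ms - self.probe_ms)


@dataclass(frozen=True)
class DilationSeries:
    """Velocity, acceleration and accumulated velocity from one origin.

    Arrays cover the samples from ``origin_index`` to the trial end;
    position 0 is the origin itself, where velocity is undefined and
    stored as 0 by convention (likewise acceleration at positions 0-1).
    """

    v: np.ndarray
    a: np.ndarray
    av: np.ndarray
    origin_index: int


def _check_observed(trial: Trial) -> None:
    if np.isnan(trial.pupil).any():
        raise ValidationError(
            f"trial {trial.trial_id} has missing samples; preprocess first"
        )


def dilation_velocity(trial: Trial, origin_index: int) -> np.ndarray:
    """Secant velocity from the origin sample, ``(P_i - P_0)/(T_i - T_0)``.

    Returns one value per sample from the origin onward; index 0 of the
    result is the origin, stored as 0.
    """
    _check_observed(trial)
    n = len(trial)
    if not 0 <= origin_index < n - 1:
        raise ParameterError(
            f"origin_index {origin_index} invalid for trial of length {n}"
        )
    t = trial.t_ms[origin_index:]
    p = trial.pupil[origin_index:]
    v = np.zeros(len(t))
    v[1:] = (p[1:] - p[0]) / (t[1:] - t[0])
    return v


def dilation_acceleration(trial: Trial, origin_index: int) -> np.ndarray:
    """Acceleration ``(V_i - V_0)/(T_i - T_0)`` from the origin sample.

    ``V_0`` is the velocity at the first sample after the origin (the
    first index where velocity is defined).
    """
    v = dilation_velocity(trial, origin_index)
    if len(v) < 3:
        raise ParameterError(
            "acceleration needs at least 3 samples from the origin"
        )
    t = trial.t_ms[origin_index:]
    a = np.zeros(len(v))
    a[1:] = (v[1:] - v[1]) / (t[1:] - t[0])
    return a


def dilation_series(trial: Trial, origin_index: int) -> DilationSeries:
    """Bundle velocity, acceleration and accumulated velocity."""
    v = dilation_velocity(trial, origin_index)
    a = dilation_acceleration(trial, origin_index)
    return DilationSeries(v=v, a=a, av=np.cumsum(v),
                          origin_index=origin_index)


def _moments(x: np.ndarray) -> dict[str, float]:
    """Population moments with the degenerate-series convention skew =
    kurtosis = 0 when the series is constant (both are otherwise 0/0)."""
    std = float(np.std(x))
    if std == 0.0:
        skew = kurt = 0.0
    else:
        skew = float(sps.skew(x, bias=True))
        kurt = float(sps.kurtosis(x, fisher=True, bias=True))
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "std": std,
        "skew": skew,
        "kurtosis": kurt,
    }


def _window_slice(trial: Trial, timing: ProbeTiming,
                  canon_lo: float, canon_hi: float, what: str) -> slice:
    """Half-open index window [lo, hi) for a canonical ms interval."""
    dt = trial.sample_period_ms
    t0 = trial.t_ms[0]
    lo = int(np.floor((timing.scale_ms(canon_lo)) / dt))
    hi = int(np.floor((timing.scale_ms(canon_hi)) / dt))
    n = len(trial)
    if lo >= n or lo >= hi:
        raise WindowError(
            f"trial {trial.trial_id}: window {what} "
            f"({canon_lo:g}-{canon_hi:g} ms canonical) is empty for this "
            "trial"
        )
    del t0
    return slice(lo, min(hi, n))


def extract_custom_features(
    trial: Trial,
    timing: ProbeTiming = ProbeTiming(),
    item19_interpretation: str = "literal",
) -> dict[str, float]:
    """Compute the 22-feature custom catalogue for one preprocessed trial.

    Parameters
    ----------
    trial
        Fully observed, reduced trial spanning ``[0, trial_end_ms)``.
    timing
        Probe onset / trial end; windows scale with it.
    item19_interpretation
        ``"literal"`` keeps catalogue item 19 as printed (a duplicate of
        item 17, max velocity after minus max accumulated velocity
        before); ``"velocity_after_minus_accum_after"`` substitutes the
        alternative reading item13 - item15.

    Returns a dict with exactly the 22 keys of
    :data:`CUSTOM_FEATURE_NAMES`, in catalogue order.
    """
    _check_observed(trial)
    if item19_interpretation not in (
        "literal", "velocity_after_minus_accum_after"
    ):
        raise ParameterError(
            f"unknown item19_interpretation {item19_interpretation!r}"
        )
    if trial.duration_ms < timing.trial_end_ms - 1e-9:
        raise WindowError(
            f"trial {trial.trial_id} spans {trial.duration_ms:g} ms but the "
            f"catalogue needs [0, {timing.trial_end_ms:g}) ms; the first "
            "unsatisfiable window is min_size_late"
        )
    p = trial.pupil
    dt = trial.sample_period_ms
    probe_idx = int(np.floor(timing.probe_ms / dt))
    n = len(trial)
    if probe_idx < 2 or n - probe_idx < 3:
        raise WindowError(
            f"trial {trial.trial_id}: too few samples on one side of the "
            "probe"
        )

    w_post = _window_slice(trial, timing, 5000, 7000, "post-probe")
    w_pre = _window_slice(trial, timing, 0, 5000, "pre-probe")
    w_late = _window_slice(trial, timing, 6500, 8000, "late")
    w_mid = _window_slice(trial, timing, 5500, 7000, "mid-post-probe")

    m = _moments(p)

    # velocity/accumulated velocity before the probe: origin = trial start
    before = dilation_series(trial, 0)
    v_bef = before.v[1:probe_idx]           # defined entries in [0, probe)
    av_bef = before.av[1:probe_idx]
    # after the probe: origin re-anchored at the probe sample
    after = dilation_series(trial, probe_idx)
    v_aft = after.v[1:]
    av_aft = after.av[1:]

    # acceleration over the canonical 5000-7000 ms window, probe origin;
    # positions 0-1 relative to the origin are undefined and excluded
    accel = after.a
    acc_lo = max(w_post.start - probe_idx, 2)
    acc_hi = max(w_post.stop - probe_idx, acc_lo)
    a_win = accel[acc_lo:acc_hi]
    if a_win.size == 0:
        raise WindowError(
            f"trial {trial.trial_id}: acceleration window is empty"
        )

    mean_vel_before = float(np.mean(v_bef))
    mean_vel_after = float(np.mean(v_aft))
    max_vel_before = float(np.max(v_bef))
    max_vel_after = float(np.max(v_aft))
    max_av_before = float(np.max(av_bef))
    max_av_after = float(np.max(av_aft))

    feats = {
        "max_size_post_probe": float(np.max(p[w_post])),
        "max_size_pre_probe": float(np.max(p[w_pre])),
        "min_size_late": float(np.min(p[w_late])),
        "mean_size_mid_post_probe": float(np.mean(p[w_mid])),
        "size_std": m["std"],
        "size_kurtosis": m["kurtosis"],
        "size_skew": m["skew"],
        "size_median": m["median"],
        "size_mean": m["mean"],
        "mean_velocity_before": mean_vel_before,
        "mean_velocity_after": mean_vel_after,
        "max_velocity_before": max_vel_before,
        "max_velocity_after": max_vel_after,
        "max_accum_velocity_before": max_av_before,
        "max_accum_velocity_after": max_av_after,
        "accum_velocity_gain": max_av_after - max_av_before,
        "velocity_accum_gap": max_vel_after - max_av_before,
        "mean_velocity_accum_gap": mean_vel_after - max_av_before,
        "velocity_accum_gap_dup": (
            max_vel_after - max_av_before
            if item19_interpretation == "literal"
            else max_vel_after - max_av_after
        ),
        "max_accel_post_probe": float(np.max(a_win)),
        "min_accel_post_probe": float(np.min(a_win)),
        "mean_accel_post_probe": float(np.mean(a_win)),
    }
    assert tuple(feats) == CUSTOM_FEATURE_NAMES
    return feats


def list_custom_features() -> list[str]:
    """The frozen public catalogue of the 22 custom feature names."""
    return list(CUSTOM_FEATURE_NAMES)
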