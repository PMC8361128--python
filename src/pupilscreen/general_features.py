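"""General time-series features and the per-subject aggregation registry.

Implements from scratch the handful of catalogue features that proved
discriminative for task-evoked pupillometry — absolute energy, real FFT
coefficients, the change-quantiles corridor variance, approximate entropy,
peak counts, the standard error of the linear trend — plus the standard
moments. A small registry of :class:`FeatureSpec` objects makes the
catalogue extensible, and :func:`build_feature_matrix` applies every spec
per trial and averages per subject, producing the subjects x features
table the statistics and evaluation stages consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .custom_features import (
    CUSTOM_FEATURE_NAMES,
    ProbeTiming,
    _moments,
    extract_custom_features,
)
from .errors import ParameterError, PupilscreenError, ValidationError
from .trial_io import Cohort, FeatureMatrix, Trial

__all__ = [
    "absolute_energy",
    "fft_real_coefficient",
    "change_quantiles_var",
    "approximate_entropy",
    "number_peaks",
    "linear_trend_stderr",
    "basic_moments",
    "FeatureSpec",
    "general_feature_specs",
    "custom_feature_specs",
    "default_feature_specs",
    "list_general_features",
    "build_feature_matrix",
]

logger = logging.getLogger(__name__)


def _as_series(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ParameterError("expected a non-empty 1-D series")
    if np.isnan(arr).any():
        raise ParameterError("series contains missing values")
    return arr


def absolute_energy(x) -> float:
    """Sum of squared sample values, :math:`\\sum_i x_i^2`."""
    return float(np.sum(_as_series(x) ** 2))


def fft_real_coefficient(x, k: int) -> float:
    """Real part of the k-th DFT coefficient,
    :math:`\\Re\\,\\sum_n x_n e^{-2\\pi i k n / N}`."""
    arr = _as_series(x)
    if not 0 <= k < arr.size:
        raise ParameterError(
            f"coefficient index {k} out of range for length {arr.size}"
        )
    return float(np.fft.fft(arr)[k].real)


def change_quantiles_var(x, ql: float = 0.4, qh: float = 0.8,
                         absolute: bool = True) -> float:
    """Variance of consecutive changes inside a quantile corridor.

    The corridor is ``[quantile(x, ql), quantile(x, qh)]`` (linear
    interpolation quantiles, endpoints inclusive); a consecutive difference
    ``x[i+1] - x[i]`` contributes only when *both* endpoints lie inside the
    corridor. Differences are taken in absolute value when ``absolute``.
    Returns the population variance of the contributing differences, or 0
    when fewer than two pairs qualify.
    """
    arr = _as_series(x)
    if not 0 <= ql < qh <= 1:
        raise ParameterError(f"need 0 <= ql < qh <= 1, got {ql}, {qh}")
    if arr.size < 2:
        raise ParameterError("need at least 2 samples")
    lo, hi = np.quantile(arr, [ql, qh])
    inside = (arr >= lo) & (arr <= hi)
    both = inside[:-1] & inside[1:]
    if both.sum() < 2:
        return 0.0
    d = np.diff(arr)[both]
    if absolute:
        d = np.abs(d)
    return float(np.var(d))


def approximate_entropy(x, m: int = 2, r_factor: float = 0.2) -> float:
    """Pincus approximate entropy ApEn(m, r) with r = r_factor * std(x).

    :math:`\\Phi_m - \\Phi_{m+1}` where
    :math:`\\Phi_m = (N-m+1)^{-1} \\sum_i \\log C_i^m` and :math:`C_i^m`
    is the fraction of length-m template vectors within Chebyshev distance
    r of template i (self-matches included). Low for regular series, high
    for erratic ones; 0 for a constant series by convention.
    """
    arr = _as_series(x)
    if m < 1:
        raise ParameterError("embedding length m must be >= 1")
    n = arr.size
    if n <= m + 1:
        raise ParameterError(
            f"series of length {n} too short for ApEn with m={m}"
        )
    r = r_factor * float(np.std(arr))
    if r == 0.0:
        return 0.0

    def phi(mm: int) -> float:
        k = n - mm + 1
        # pairwise Chebyshev distances between all k templates,
        # accumulated per embedding offset to avoid a k*k*m tensor
        dist = np.abs(arr[:k, None] - arr[None, :k])
        for off in range(1, mm):
            np.maximum(
                dist, np.abs(arr[off:off + k, None] - arr[None, off:off + k]),
                out=dist,
            )
        c = np.count_nonzero(dist <= r, axis=1) / k
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def number_peaks(x, n: int = 10) -> int:
    """Count samples strictly greater than their n neighbours on each side.

    A sample at index i (with at least n neighbours on both sides) counts
    as a peak when it exceeds every one of ``x[i-n:i]`` and
    ``x[i+1:i+n+1]``. Series of length <= 2n have no candidate index and
    return 0 (with a warning).
    """
    arr = _as_series(x)
    if n < 1:
        raise ParameterError("peak support n must be >= 1")
    if arr.size <= 2 * n:
        logger.warning(
            "number_peaks: series of length %d has no index with %d "
            "neighbours on both sides; returning 0", arr.size, n
        )
        return 0
    core = arr[n:-n]
    is_peak = np.ones(core.size, dtype=bool)
    for off in range(1, n + 1):
        is_peak &= core > arr[n - off: n - off + core.size]
        is_peak &= core > arr[n + off: n + off + core.size]
    return int(is_peak.sum())


def linear_trend_stderr(x) -> float:
    """Standard error of the OLS slope of x against sample index.

    :math:`\\sqrt{(SSE/(N-2)) / \\sum_i (i - \\bar i)^2}` with residual
    sum of squares SSE from the least-squares line.
    """
    arr = _as_series(x)
    if arr.size < 3:
        raise ParameterError("need at least 3 samples for a trend error")
    idx = np.arange(arr.size, dtype=float)
    sxx = float(np.sum((idx - idx.mean()) ** 2))
    slope = float(np.sum((idx - idx.mean()) * (arr - arr.mean()))) / sxx
    intercept = arr.mean() - slope * idx.mean()
    sse = float(np.sum((arr - (intercept + slope * idx)) ** 2))
    return float(np.sqrt(max(sse, 0.0) / (arr.size - 2) / sxx))


def basic_moments(x) -> dict[str, float]:
    """Population mean/median/variance/std/skew/kurtosis of a series.

    Conventions match the custom catalogue: population (biased) variance,
    Fisher (excess) kurtosis without bias correction, and skew = kurtosis
    = 0 for a constant series.
    """
    arr = _as_series(x)
    m = _moments(arr)
    m["variance"] = m["std"] ** 2
    return m


@dataclass(frozen=True)
class FeatureSpec:
    """A named, parameterised, deterministic per-trial feature."""

    name: str
    compute: Callable[[Trial], float]
    params: dict = field(default_factory=dict)

    def __call__(self, trial: Trial) -> float:
        return float(self.compute(trial))


def general_feature_specs(
    fft_k: int = 2,
    ql: float = 0.4,
    qh: float = 0.8,
    apen_m: int = 2,
    apen_r_factor: float = 0.2,
    peaks_n: int = 10,
) -> list[FeatureSpec]:
    """The 12 default general specs: the six discriminative catalogue
    features plus the six standard moments."""

    def on(f, **kw):
        return lambda tr: f(tr.pupil, **kw)

    # the six moment specs share one basic_moments pass per trial
    mom_cache: dict = {"key": None, "vals": None}

    def moment_of(tr: Trial, name: str) -> float:
        if mom_cache["key"] != id(tr):
            mom_cache["vals"] = basic_moments(tr.pupil)
            mom_cache["key"] = id(tr)
        return mom_cache["vals"][name]

    moments = {
        name: (lambda tr, _n=name: moment_of(tr, _n))
        for name in ("mean", "median", "variance", "std", "skew", "kurtosis")
    }
    return [
        FeatureSpec("absolute_energy", on(absolute_energy)),
        FeatureSpec(f"fft_real_coeff_{fft_k}",
                    on(fft_real_coefficient, k=fft_k), {"k": fft_k}),
        FeatureSpec(f"change_quantiles_var_{ql:g}_{qh:g}",
                    on(change_quantiles_var, ql=ql, qh=qh),
                    {"ql": ql, "qh": qh}),
        FeatureSpec(f"approx_entropy_m{apen_m}",
                    on(approximate_entropy, m=apen_m,
                       r_factor=apen_r_factor),
                    {"m": apen_m, "r_factor": apen_r_factor}),
        FeatureSpec(f"number_peaks_{peaks_n}",
                    on(number_peaks, n=peaks_n), {"n": peaks_n}),
        FeatureSpec("linear_trend_stderr", on(linear_trend_stderr)),
        FeatureSpec("series_mean", moments["mean"]),
        FeatureSpec("series_median", moments["median"]),
        FeatureSpec("series_variance", moments["variance"]),
        FeatureSpec("series_std_general", moments["std"]),
        FeatureSpec("series_skew", moments["skew"]),
        FeatureSpec("series_kurtosis", moments["kurtosis"]),
    ]


def custom_feature_specs(
    timing: ProbeTiming = ProbeTiming(),
    item19_interpretation: str = "literal",
) -> list[FeatureSpec]:
    """The 22 custom catalogue features wrapped as specs, in order.

    The specs share a one-trial memo so evaluating all 22 on the same
    trial performs a single extraction pass.
    """
    cache: dict = {"key": None, "feats": None}

    def all_feats(trial: Trial) -> dict[str, float]:
        if cache["key"] != id(trial):
            cache["feats"] = extract_custom_features(
                trial, timing, item19_interpretation
            )
            cache["key"] = id(trial)
        return cache["feats"]

    def make(name: str) -> FeatureSpec:
        return FeatureSpec(name, lambda tr, _n=name: all_feats(tr)[_n])

    return [make(n) for n in CUSTOM_FEATURE_NAMES]


def default_feature_specs(
    timing: ProbeTiming = ProbeTiming(), **general_kw
) -> list[FeatureSpec]:
    """Default registry: 22 custom + 12 general = 34 features."""
    return custom_feature_specs(timing) + general_feature_specs(**general_kw)


def list_general_features() -> list[str]:
    """Names of the default general feature registry."""
    return [s.name for s in general_feature_specs()]


def build_feature_matrix(
    cohort: Cohort,
    specs: Sequence[FeatureSpec] | None = None,
    timing: ProbeTiming = ProbeTiming(),
) -> FeatureMatrix:
    """Per-trial features averaged per subject into a FeatureMatrix.

    Every spec is evaluated on every kept trial; the per-subject value is
    the arithmetic mean over that subject's trials. A spec failing on some
    trials of a subject averages over the successes (logged); failing on
    every trial raises, naming subject and spec. Column order follows the
    spec order.
    """
    if specs is None:
        specs = default_feature_specs(timing)
    specs = list(specs)
    if not specs:
        raise ParameterError("need at least one feature spec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ParameterError("feature spec names must be unique")

    values = np.empty((len(cohort.subjects), len(specs)))
    for i, subject in enumerate(cohort):
        # evaluate trial-by-trial so one bad trial doesn't sink a subject
        per_trial: list[list[float]] = [[] for _ in specs]
        n_failed = 0
        for trial in subject.trials:
            for j, spec in enumerate(specs):
                try:
                    per_trial[j].append(spec(trial))
                except PupilscreenError:
                    n_failed += 1
        for j, (spec, vals) in enumerate(zip(specs, per_trial)):
            if not vals:
                raise ValidationError(
                    f"feature {spec.name!r} failed on every trial of "
                    f"subject {subject.subject_id}"
                )
            if len(vals) < len(subject.trials):
                logger.info(
                    "subject %s: feature %s averaged over %d/%d trials",
                    subject.subject_id, spec.name, len(vals),
                    len(subject.trials),
                )
            values[i, j] = float(np.mean(vals))

    return FeatureMatrix(
        subject_ids=[s.subject_id for s in cohort],
        labels=[s.group for s in cohort],
        feature_names=names,
        values=values,
    )
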