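"""Synthetic task-evoked pupillometry cohorts.

Emulates the structure of a two-group visuospatial working-memory study:
each subject contributes many 8 s trials sampled at 1 kHz, with a probe
stimulus at 5000 ms that evokes a pupil dilation. Per trial the generated
signal is

    pupil(t) = baseline_s
             + evoked(t)                         (saturating exponential)
             + AR(1) slow noise                  (marginal sd sigma_s)
             + white high-frequency jitter       (sd per group)

where ``evoked(t) = A_s (1 - exp(-(t - probe)/tau_s))`` for t >= probe,
relaxing back exponentially after the late-trial decay point (canonically
7000 ms). The two free response parameters map directly onto the
discriminative quantities of interest: amplitude -> post-probe maximum
size and overall variability, time constant -> dilation velocity. Under
the "strong" effect the control group has a larger amplitude, a faster
(smaller) time constant and larger slow-noise sd, while the ADHD group
carries more white jitter (more erratic sample-to-sample movement: higher
approximate entropy and peak counts). ``effect="null"`` forces identical
group parameters.

Blink-like missingness is MCAR: Poisson blink onsets with lognormal
durations become missing runs, and a small fraction of trials are
"catastrophic" (>80% missing) so the exclusion rule has real work.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.signal import lfilter

from .errors import ParameterError
from .trial_io import Cohort, Group, Subject, Trial

__all__ = [
    "GroupParams",
    "GeneratorConfig",
    "GroundTruth",
    "generate_cohort",
    "summarize_cohort",
    "EFFECT_LEVELS",
]

EFFECT_LEVELS = ("strong", "moderate", "null")


@dataclass(frozen=True)
class GroupParams:
    """Population parameters of one diagnostic group.

    Means and between-subject standard deviations of the per-subject
    response parameters; pupil values are in arbitrary units, times in ms.
    """

    baseline_mean: float = 3.0
    baseline_sd: float = 0.25
    amplitude_mean: float = 0.6
    amplitude_sd: float = 0.12
    tau_mean_ms: float = 500.0
    tau_sd_ms: float = 90.0
    ar1_rho: float = 0.995
    noise_sd_mean: float = 0.12
    noise_sd_sd: float = 0.02
    jitter_sd_mean: float = 0.012
    jitter_sd_sd: float = 0.003
    #: correlation of the fast jitter (per raw sample). A short but
    #: non-zero correlation time (~10 ms at 1 kHz) lets the erratic
    #: component survive the 16 ms moving-average reduction, which would
    #: annihilate strictly white noise.
    jitter_rho: float = 0.9


# strong-effect group parameters: the control group dilates more and
# faster with greater overall variability; the ADHD group is noisier
# sample-to-sample.
_CTRL_STRONG = GroupParams(
    amplitude_mean=0.72, amplitude_sd=0.13,
    tau_mean_ms=420.0, tau_sd_ms=80.0,
    noise_sd_mean=0.145, noise_sd_sd=0.025,
    jitter_sd_mean=0.006, jitter_sd_sd=0.0015,
)
_ADHD_STRONG = GroupParams(
    amplitude_mean=0.54, amplitude_sd=0.13,
    tau_mean_ms=620.0, tau_sd_ms=110.0,
    noise_sd_mean=0.105, noise_sd_sd=0.025,
    jitter_sd_mean=0.018, jitter_sd_sd=0.004,
)


def _blend(a: GroupParams, b: GroupParams, w: float) -> GroupParams:
    """Parameter-wise convex combination (w=0 -> a, w=1 -> b)."""
    kw = {
        f: (1 - w) * getattr(a, f) + w * getattr(b, f)
        for f in a.__dataclass_fields__
    }
    return GroupParams(**kw)


def effect_params(effect: str) -> tuple[GroupParams, GroupParams]:
    """(control, ADHD) group parameters for an effect level."""
    if effect not in EFFECT_LEVELS:
        raise ParameterError(
            f"effect must be one of {EFFECT_LEVELS}, got {effect!r}"
        )
    mid = _blend(_CTRL_STRONG, _ADHD_STRONG, 0.5)
    if effect == "null":
        return mid, mid
    if effect == "moderate":
        return (_blend(_CTRL_STRONG, mid, 0.5),
                _blend(_ADHD_STRONG, mid, 0.5))
    return _CTRL_STRONG, _ADHD_STRONG


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design and noise/missingness settings of a synthetic cohort.

    Defaults reproduce the reference study scale: 28 unmedicated
    ADHD-positive and 22 control subjects, 160 trials each, 8000 ms trials
    at 1 kHz with the probe at 5000 ms.
    """

    n_adhd: int = 28
    n_ctrl: int = 22
    trials_per_subject: int = 160
    duration_ms: float = 8000.0
    sampling_hz: float = 1000.0
    probe_ms: float = 5000.0
    effect: str = "strong"
    ctrl_params: GroupParams | None = None
    adhd_params: GroupParams | None = None
    blink_rate_per_s: float = 0.15
    blink_duration_median_ms: float = 120.0
    blink_duration_log_sd: float = 0.4
    catastrophic_trial_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_adhd, self.n_ctrl, self.trials_per_subject) < 1:
            raise ParameterError("subject and trial counts must be positive")
        if not 0 < self.probe_ms < self.duration_ms:
            raise ParameterError("require 0 < probe_ms < duration_ms")
        if self.sampling_hz <= 0:
            raise ParameterError("sampling_hz must be positive")
        if not 0 <= self.catastrophic_trial_prob < 1:
            raise ParameterError("catastrophic_trial_prob must be in [0, 1)")
        if self.effect not in EFFECT_LEVELS:
            raise ParameterError(
                f"effect must be one of {EFFECT_LEVELS}, got {self.effect!r}"
            )
        if self.effect == "null" and (
            self.ctrl_params is not None or self.adhd_params is not None
        ) and self.ctrl_params != self.adhd_params:
            raise ParameterError(
                "effect='null' requires identical group parameters"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms * self.sampling_hz / 1000.0))

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sampling_hz

    def group_params(self) -> tuple[GroupParams, GroupParams]:
        ctrl, adhd = effect_params(self.effect)
        return (self.ctrl_params or ctrl, self.adhd_params or adhd)


@dataclass
class GroundTruth:
    """Per-subject realized generator parameters, for recovery tests."""

    subjects: list[dict] = field(default_factory=list)

    def by_id(self) -> dict[str, dict]:
        return {s["subject_id"]: s for s in self.subjects}


def _positive_normal(rng: np.random.Generator, mean: float, sd: float,
                     floor: float) -> float:
    """Normal draw truncated below (redraw) to keep parameters physical."""
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > floor:
            return float(v)
    return max(mean, floor * 1.01)


def _evoked(t_ms: np.ndarray, amplitude: float, tau_ms: float,
            probe_ms: float, decay_start_ms: float,
            decay_tau_ms: float) -> np.ndarray:
    rise = np.where(
        t_ms >= probe_ms,
        amplitude * (1.0 - np.exp(-(np.maximum(t_ms - probe_ms, 0.0))
                                  / tau_ms)),
        0.0,
    )
    late = t_ms >= decay_start_ms
    if late.any():
        peak = amplitude * (1.0 - np.exp(-(decay_start_ms - probe_ms)
                                         / tau_ms))
        rise[late] = peak * np.exp(-(t_ms[late] - decay_start_ms)
                                   / decay_tau_ms)
    return rise


def _ar1(rng: np.random.Generator, n: int, rho: float,
         marginal_sd: float) -> np.ndarray:
    innov_sd = marginal_sd * np.sqrt(max(1.0 - rho**2, 1e-12))
    e = rng.normal(0.0, innov_sd, n)
    x0 = rng.normal(0.0, marginal_sd)
    x, _ = lfilter([1.0], [1.0, -rho], e, zi=[rho * x0])
    return x


def _insert_blinks(rng: np.random.Generator, pupil: np.ndarray,
                   cfg: GeneratorConfig) -> None:
    n = pupil.size
    duration_s = cfg.duration_ms / 1000.0
    n_blinks = rng.poisson(cfg.blink_rate_per_s * duration_s)
    for _ in range(n_blinks):
        dur_ms = rng.lognormal(
            np.log(cfg.blink_duration_median_ms), cfg.blink_duration_log_sd
        )
        width = max(1, int(round(dur_ms / cfg.sample_period_ms)))
        start = rng.integers(0, n)
        pupil[start: min(start + width, n)] = np.nan


def _catastrophic(rng: np.random.Generator, pupil: np.ndarray) -> None:
    n = pupil.size
    frac = rng.uniform(0.85, 0.95)
    width = int(round(frac * n))
    start = rng.integers(0, n - width + 1)
    pupil[start: start + width] = np.nan


def _iter_subject_specs(cfg: GeneratorConfig) -> Iterator[tuple[str, Group]]:
    pad = len(str(max(cfg.n_adhd, cfg.n_ctrl)))
    for i in range(cfg.n_adhd):
        yield f"adhd_{i + 1:0{pad}d}", Group.ADHD_POSITIVE
    for i in range(cfg.n_ctrl):
        yield f"ctrl_{i + 1:0{pad}d}", Group.CONTROL


def generate_cohort(
    config: GeneratorConfig = GeneratorConfig(),
) -> tuple[Cohort, GroundTruth]:
    """Generate a labelled cohort plus the ground-truth parameters.

    Fully reproducible: the same config (including seed) yields a
    byte-identical cohort.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ctrl_p, adhd_p = cfg.group_params()
    t_ms = np.arange(cfg.n_samples) * cfg.sample_period_ms
    post_span = cfg.duration_ms - cfg.probe_ms
    decay_start = cfg.probe_ms + post_span * 2.0 / 3.0
    decay_tau = post_span / 2.0

    subjects: list[Subject] = []
    truth = GroundTruth()
    for subject_id, group in _iter_subject_specs(cfg):
        gp = adhd_p if group is Group.ADHD_POSITIVE else ctrl_p
        params = {
            "subject_id": subject_id,
            "group": group.label,
            "baseline": rng.normal(gp.baseline_mean, gp.baseline_sd),
            "amplitude": _positive_normal(
                rng, gp.amplitude_mean, gp.amplitude_sd, 0.05),
            "tau_ms": _positive_normal(
                rng, gp.tau_mean_ms, gp.tau_sd_ms, 50.0),
            "noise_sd": _positive_normal(
                rng, gp.noise_sd_mean, gp.noise_sd_sd, 1e-4),
            "jitter_sd": _positive_normal(
                rng, gp.jitter_sd_mean, gp.jitter_sd_sd, 1e-6),
            "ar1_rho": gp.ar1_rho,
        }
        truth.subjects.append(params)

        trials = []
        pad = len(str(cfg.trials_per_subject))
        for k in range(cfg.trials_per_subject):
            amp = params["amplitude"] * rng.normal(1.0, 0.08)
            pupil = (
                params["baseline"]
                + _evoked(t_ms, amp, params["tau_ms"], cfg.probe_ms,
                          decay_start, decay_tau)
                + _ar1(rng, cfg.n_samples, params["ar1_rho"],
                       params["noise_sd"])
                + _ar1(rng, cfg.n_samples, gp.jitter_rho,
                       params["jitter_sd"])
            )
            if rng.uniform() < cfg.catastrophic_trial_prob:
                _catastrophic(rng, pupil)
            else:
                _insert_blinks(rng, pupil, cfg)
            trials.append(Trial(
                subject_id=subject_id,
                trial_id=f"t{k + 1:0{pad}d}",
                t_ms=t_ms.copy(),
                pupil=pupil,
                sample_period_ms=cfg.sample_period_ms,
            ))
        subjects.append(Subject(subject_id, group, trials))
    return Cohort(subjects), truth


def summarize_cohort(cohort: Cohort) -> dict:
    """Pointwise group-mean pupil time course.

    All trials must share one time axis (true for generated and for
    uniformly preprocessed cohorts). Missing samples are ignored
    pointwise. Returns ``{"t_ms": axis, "groups": {label: mean series}}``.
    """
    t_ref = None
    stacks: dict[str, list[np.ndarray]] = {}
    for s in cohort:
        for tr in s.trials:
            if t_ref is None:
                t_ref = tr.t_ms
            elif len(tr.t_ms) != len(t_ref) or not np.allclose(
                tr.t_ms, t_ref
            ):
                raise ParameterError(
                    "summarize_cohort requires a common time axis"
                )
            stacks.setdefault(s.group.label, []).append(tr.pupil)
    return {
        "t_ms": t_ref,
        "groups": {
            label: np.nanmean(np.vstack(arrs), axis=0)
            for label, arrs in stacks.items()
        },
    }


def scaled_demo_config(
    effect: str = "strong",
    n_adhd: int = 28,
    n_ctrl: int = 22,
    trials_per_subject: int = 8,
    seed: int = 0,
) -> GeneratorConfig:
    """A desk-fast configuration: full trial layout (8 s at 1 kHz, probe
    at 5 s) with a reduced trial count per subject."""
    return GeneratorConfig(
        n_adhd=n_adhd, n_ctrl=n_ctrl,
        trials_per_subject=trials_per_subject,
        effect=effect, seed=seed,
    )
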