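"""Visualization: group-mean line plots, box/violin plots, RadViz, ROC.

Plots are deterministic file artifacts (PNG or SVG) with minimal styling.
The RadViz projection — features as anchors spaced uniformly on the unit
circle, each subject drawn at the normalized-value-weighted mean of the
anchor vectors — is exposed as a pure function so the geometry is testable
without rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .custom_features import dilation_acceleration, dilation_velocity
from .errors import ParameterError
from .evaluation import EvaluationReport
from .stats import mann_whitney_u
from .trial_io import Cohort, FeatureMatrix, Group, Trial
from .synthetic import summarize_cohort

__all__ = [
    "RadVizProjection",
    "radviz_project",
    "radviz_plot",
    "group_mean_lineplot",
    "feature_distribution_plot",
    "roc_plot",
]

_GROUP_COLORS = {"ADHD": "tab:red", "CTRL": "tab:blue"}


@dataclass(frozen=True)
class RadVizProjection:
    """2-D RadViz embedding of a feature matrix subset.

    ``anchors[j]`` is the unit-circle position of feature j (at angle
    2*pi*j/m, following the order of the requested subset); ``points[i]``
    is subject i's coordinate, always inside or on the unit circle.
    ``normalization`` records the per-feature (min, max) used.
    """

    feature_names: tuple[str, ...]
    anchors: np.ndarray
    points: np.ndarray
    normalization: tuple[tuple[float, float], ...]


def radviz_project(
    fm: FeatureMatrix, feature_subset: list[str] | None = None
) -> RadVizProjection:
    """Project subjects onto the RadViz plane.

    Each selected feature is min-max normalized to [0, 1]; subject i maps
    to ``sum_j x_ij u_j / sum_j x_ij`` with ``u_j`` the anchor unit
    vectors. A subject with all-zero normalized values sits at the origin
    (documented convention). Constant features are rejected because their
    normalization is undefined.
    """
    names = list(feature_subset) if feature_subset else list(fm.feature_names)
    if len(names) < 2:
        raise ParameterError("RadViz needs at least 2 features")
    cols = np.column_stack([fm.column(n) for n in names])
    mins, maxs = cols.min(axis=0), cols.max(axis=0)
    constant = np.flatnonzero(maxs - mins == 0)
    if constant.size:
        raise ParameterError(
            f"constant feature {names[constant[0]]!r}: min-max "
            "normalization undefined"
        )
    norm = (cols - mins) / (maxs - mins)
    m = len(names)
    theta = 2 * np.pi * np.arange(m) / m
    anchors = np.column_stack([np.cos(theta), np.sin(theta)])
    weights = norm.sum(axis=1, keepdims=True)
    points = np.divide(
        norm @ anchors, weights,
        out=np.zeros((len(norm), 2)), where=weights > 0,
    )
    return RadVizProjection(
        feature_names=tuple(names),
        anchors=anchors,
        points=points,
        normalization=tuple(zip(mins.tolist(), maxs.tolist())),
    )


def _save(fig, path) -> None:
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def radviz_plot(fm: FeatureMatrix, path,
                feature_subset: list[str] | None = None) -> RadVizProjection:
    """Render the RadViz class-separability view to ``path``."""
    proj = radviz_project(fm, feature_subset)
    fig, ax = plt.subplots(figsize=(6, 6))
    circle = plt.Circle((0, 0), 1.0, fill=False, color="grey", lw=0.8)
    ax.add_patch(circle)
    for (x, y), name in zip(proj.anchors, proj.feature_names):
        ax.annotate(name, (x, y), fontsize=7,
                    ha="center", va="center",
                    xytext=(x * 1.12, y * 1.12), textcoords="data")
        ax.plot([x], [y], "o", color="grey", ms=3)
    for group in Group:
        mask = np.array([g is group for g in fm.labels])
        ax.scatter(proj.points[mask, 0], proj.points[mask, 1],
                   s=24, alpha=0.8, label=group.label,
                   color=_GROUP_COLORS[group.label])
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="lower right")
    ax.set_title("RadViz class separability")
    _save(fig, path)
    return proj


def group_mean_lineplot(cohort: Cohort, path,
                        derivative: str = "size",
                        probe_ms: float | None = 5000.0) -> None:
    """Per-group mean time course of size, velocity or acceleration.

    Velocity and acceleration are computed from the group-mean series
    (origin at the first sample), not averaged per-trial.
    """
    if derivative not in ("size", "velocity", "acceleration"):
        raise ParameterError(f"unknown derivative {derivative!r}")
    summary = summarize_cohort(cohort)
    t = summary["t_ms"]
    fig, ax = plt.subplots(figsize=(7, 4))
    for label, series in sorted(summary["groups"].items()):
        y, t_plot = series, t
        if derivative != "size":
            period = float(t[1] - t[0])
            mean_trial = Trial("_", "_", t, series, period)
            if derivative == "velocity":
                y = dilation_velocity(mean_trial, 0)[1:]
            else:
                y = dilation_acceleration(mean_trial, 0)[2:]
            t_plot = t[len(t) - len(y):]
        ax.plot(t_plot, y, label=label,
                color=_GROUP_COLORS.get(label))
    if probe_ms is not None and t[0] <= probe_ms <= t[-1]:
        ax.axvline(probe_ms, color="grey", ls="--", lw=0.8, label="probe")
    ax.set_xlabel("time (ms)")
    ylab = {"size": "pupil size (a.u.)",
            "velocity": "dilation velocity (a.u./ms)",
            "acceleration": "dilation acceleration (a.u./ms$^2$)"}
    ax.set_ylabel(ylab[derivative])
    ax.legend()
    ax.set_title(f"Group-mean pupil {derivative}")
    _save(fig, path)


def feature_distribution_plot(fm: FeatureMatrix, feature: str, path,
                              style: str = "box") -> float:
    """Box or violin plot of one feature per group, annotated with the
    Mann-Whitney p-value. Returns the annotated p-value."""
    if style not in ("box", "violin"):
        raise ParameterError(f"unknown style {style!r}")
    by_group = fm.group_values(feature)
    adhd = by_group[Group.ADHD_POSITIVE]
    ctrl = by_group[Group.CONTROL]
    _, p = mann_whitney_u(adhd, ctrl)
    fig, ax = plt.subplots(figsize=(5, 4))
    data = [adhd, ctrl]
    labels = [Group.ADHD_POSITIVE.label, Group.CONTROL.label]
    if style == "box":
        ax.boxplot(data, tick_labels=labels)
    else:
        parts = ax.violinplot(data, showmedians=True)
        ax.set_xticks([1, 2], labels)
        del parts
    ax.set_ylabel(feature)
    ax.set_title(f"{feature} by group")
    ax.annotate(f"p = {p:.3g}", xy=(0.02, 0.95),
                xycoords="axes fraction", fontsize=9)
    _save(fig, path)
    return p


def roc_plot(reports: list[EvaluationReport], path) -> None:
    """Pooled ROC curves (first repetition of each report) with the
    aggregate AUROC in the legend."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for rep in reports:
        pts = np.asarray(rep.roc_points[0])
        auc = rep.aggregate["auroc"]["mean"]
        ax.plot(pts[:, 0], pts[:, 1],
                label=f"{rep.classifier} (AUROC {auc:.3f})")
    ax.plot([0, 1], [0, 1], color="grey", ls="--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title("Nested-CV ROC")
    ax.legend(loc="lower right", fontsize=8)
    _save(fig, path)
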