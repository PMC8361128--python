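"""Univariate feature statistics: Mann-Whitney U ranking and ANOVA-F.

The Mann-Whitney U test is the descriptive, distribution-free test used to
rank features by how well they separate the two diagnostic groups; the
one-way ANOVA F-test is the selector applied *inside* cross-validation
folds (for two groups it orders features identically to |t| and to the
squared point-biserial correlation). P-values are two-sided throughout and
reported raw — a Benjamini-Hochberg adjustment is available but off by
default.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, ValidationError
from .trial_io import FeatureMatrix

__all__ = [
    "RankMethod",
    "RankedFeatures",
    "mann_whitney_u",
    "anova_f",
    "rank_features",
    "select_top_k",
]

#: Largest pooled sample size for which the exact (enumeration) null
#: distribution of U is used; beyond this, or with ties, the normal
#: approximation with tie and continuity corrections applies.
EXACT_LIMIT = 12


class RankMethod(enum.Enum):
    MANN_WHITNEY = "mann_whitney"
    ANOVA_F = "anova_f"


@dataclass(frozen=True)
class RankedFeatures:
    """Features ordered by ascending p-value (ties broken by name)."""

    entries: tuple[tuple[str, float, float], ...]  # (name, statistic, p)
    method: RankMethod

    def __post_init__(self) -> None:
        keys = [(p, name) for name, _, p in self.entries]
        if keys != sorted(keys):
            raise ValidationError("entries must be sorted by (p_value, name)")

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def to_rows(self) -> list[dict]:
        return [
            {"feature": n, "statistic": s, "p_value": p}
            for n, s, p in self.entries
        ]


def _clean_sample(x, what: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ParameterError(f"{what} sample is empty")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{what} sample contains non-finite values")
    return arr


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U_x, p)`` where ``U_x = R_x - n_x(n_x+1)/2`` with midranks
    for ties (so ``U_x + U_y = n_x * n_y`` always). The p-value is exact —
    full enumeration of the permutation null — when the pooled sample has
    at most :data:`EXACT_LIMIT` observations and no ties; otherwise the
    normal approximation with tie correction and a 0.5 continuity
    correction is used.
    """
    x = _clean_sample(x, "x")
    y = _clean_sample(y, "y")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2)

    has_ties = np.unique(pooled).size < pooled.size
    if nx + ny <= EXACT_LIMIT and not has_ties:
        p = _exact_two_sided_p(u_x, nx, ny)
    else:
        p = _normal_two_sided_p(u_x, nx, ny, pooled)
    return u_x, min(p, 1.0)


def _exact_two_sided_p(u_obs: float, nx: int, ny: int) -> float:
    """Exact two-sided p by enumerating every group-label assignment."""
    n = nx + ny
    total = 0
    extreme = 0
    mu = nx * ny / 2
    dev = abs(u_obs - mu)
    for combo in itertools.combinations(range(1, n + 1), nx):
        u = sum(combo) - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def _normal_two_sided_p(u: float, nx: int, ny: int,
                        pooled: np.ndarray) -> float:
    n = nx + ny
    mu = nx * ny / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = nx * ny / 12 * (n + 1 - tie_term)
    if var <= 0:  # every value identical
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    return float(2 * sps.norm.sf(max(z, 0.0)))


def anova_f(values, labels) -> tuple[float, float]:
    """One-way ANOVA F-test between two groups.

    ``F = MSB/MSW`` with degrees of freedom (1, n-2); the p-value comes
    from the F distribution. Zero pooled within-group variance with
    unequal means yields ``(inf, 0.0)``.
    """
    v = _clean_sample(values, "values")
    lab = np.asarray(labels).ravel()
    if lab.size != v.size:
        raise ParameterError("values and labels must have equal length")
    groups = [v[lab == g] for g in np.unique(lab)]
    if len(groups) != 2:
        raise ParameterError(f"need exactly 2 groups, got {len(groups)}")
    if min(g.size for g in groups) < 2:
        raise ParameterError("each group needs at least 2 members")
    grand = v.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = 1, v.size - 2
    msb = ssb / df_between
    if ssw == 0.0:
        if msb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = msb / (ssw / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def rank_features(
    fm: FeatureMatrix,
    method: RankMethod = RankMethod.MANN_WHITNEY,
    adjust: str = "none",
) -> RankedFeatures:
    """Rank every feature by univariate group separation.

    Sorted ascending by p-value with name tie-breaks, so the ranking is
    deterministic and invariant to subject-row permutations. A constant
    feature column gets statistic 0 and p = 1 by convention.
    ``adjust="bh"`` applies the Benjamini-Hochberg step-up correction to
    the reported p-values (default: raw, uncorrected).
    """
    if adjust not in ("none", "bh"):
        raise ParameterError(f"unknown adjust {adjust!r}")
    labels = fm.label_array()
    if labels.min() == labels.max():
        raise ValidationError("feature ranking requires both groups")
    rows = []
    for j, name in enumerate(fm.feature_names):
        col = fm.values[:, j]
        if np.ptp(col) == 0.0:
            rows.append((name, 0.0, 1.0))
            continue
        if method is RankMethod.MANN_WHITNEY:
            stat, p = mann_whitney_u(col[labels == 1], col[labels == 0])
        elif method is RankMethod.ANOVA_F:
            stat, p = anova_f(col, labels)
        else:
            raise ParameterError(f"unknown method {method!r}")
        rows.append((name, stat, p))
    if adjust == "bh":
        ps = np.array([p for _, _, p in rows])
        rows = [
            (n, s, q) for (n, s, _), q in zip(rows, _bh_adjust(ps))
        ]
    rows.sort(key=lambda r: (r[2], r[0]))
    return RankedFeatures(entries=tuple(rows), method=method)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_i in range(m - 1, -1, -1):
        i = order[rank_i]
        running = min(running, p[i] * m / (rank_i + 1))
        q[i] = running
    return q


def select_top_k(ranked: RankedFeatures, k: int = 9) -> list[str]:
    """The first k feature names in rank order."""
    if k < 1:
        raise ParameterError("k must be at least 1")
    if k > len(ranked.entries):
        raise ParameterError(
            f"k={k} exceeds the {len(ranked.entries)} ranked features"
        )
    return ranked.names[:k]
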