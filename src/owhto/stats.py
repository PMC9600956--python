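"""Statistical battery: one-way ANOVA, Tukey HSD, ICC(A,k), Landis grades.

ANOVA and Tukey's honestly-significant-difference test are delegated to
scipy (standard procedures); the intraclass correlation is computed
from the two-way mean squares in the McGraw-Wong convention:

    ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

for n subjects (rows) rated by k raters (columns), absolute agreement,
average of k ratings, with the F-based confidence interval of the same
convention.  Agreement strength is graded on the Landis-Koch scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "IccResult",
    "anova_oneway",
    "tukey_hsd",
    "icc_ak",
    "landis_grade",
]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class TukeyResult:
    pair: str
    mean_diff: float
    ci_low: float
    ci_high: float
    p_adj: float


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_raters: int
    grade: str


def _as_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("every group needs at least two observations")
    return gs


def anova_oneway(groups) -> AnovaResult:
    """Standard between/within mean-square ratio with F-distribution p.

    The fully degenerate case (all values identical everywhere) is
    reported as F = 0, p = 1 rather than NaN.
    """
    gs = _as_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0:
        return AnovaResult(0.0, 1.0, k - 1, n_total - k)
    f, p = sps.f_oneway(*gs)
    return AnovaResult(float(f), float(p), k - 1, n_total - k)


def tukey_hsd(groups, labels=None, alpha: float = 0.05) -> list[TukeyResult]:
    """All-pairs comparison via the studentized range distribution.

    Returns one record per unordered pair (i < j) with the mean
    difference group_i - group_j, simultaneous (1 - alpha) confidence
    interval, and the adjusted p from the studentized range with
    df = N - k.
    """
    gs = _as_groups(groups)
    k = len(gs)
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")
    allv = np.concatenate(gs)
    if np.ptp(allv) == 0:
        # identical data everywhere: no differences, p = 1
        return [TukeyResult(f"{labels[i]} vs {labels[j]}", 0.0, 0.0, 0.0, 1.0)
                for i in range(k) for j in range(i + 1, k)]
    res = sps.tukey_hsd(*gs)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            out.append(TukeyResult(
                pair=f"{labels[i]} vs {labels[j]}",
                mean_diff=float(res.statistic[i, j]),
                ci_low=float(ci.low[i, j]),
                ci_high=float(ci.high[i, j]),
                p_adj=float(res.pvalue[i, j]),
            ))
    return out


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Rows = subjects, columns = raters; returns (MS_R, MS_C, MS_E)."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


def icc_ak(values, alpha: float = 0.05) -> IccResult:
    """ICC, two-way model, absolute agreement, average of k ratings.

    ``values`` is an n x k array (subjects x raters); sessions should be
    averaged or analysed as the k dimension by the caller.  The estimate
    is clamped to [-1, 1]; the CI follows the McGraw-Wong F-based
    interval for the single-rating form, Spearman-Brown-stepped up to
    the k-rating form.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 3:
        if x.shape[2] == 1:
            x = x[:, :, 0]
        else:
            raise ValueError("pass a 2D subjects x raters table "
                             "(average or split sessions first)")
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if np.isnan(x).any():
        raise ValueError("complete design required (no missing cells)")
    n, k = x.shape
    ms_r, ms_c, ms_e = _two_way_mean_squares(x)
    if ms_r <= 1e-14 * max(1.0, float(np.abs(x).mean()) ** 2):
        raise ValueError("zero between-subject variance: ICC undefined")

    denom_k = ms_r + (ms_c - ms_e) / n
    est = float(np.clip((ms_r - ms_e) / denom_k, -1.0, 1.0)) if denom_k != 0 else 1.0

    # single-rating estimate, for the CI construction
    denom_1 = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    rho1 = (ms_r - ms_e) / denom_1 if denom_1 != 0 else 1.0

    if ms_e == 0 and ms_c == 0:
        # perfect agreement: interval collapses
        return IccResult(est, est, est, n, k, landis_grade(est))

    a = k * rho1 / (n * (1.0 - rho1)) if rho1 < 1 else np.inf
    b = 1.0 + k * rho1 * (n - 1) / (n * (1.0 - rho1)) if rho1 < 1 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        num_v = (a * ms_c + b * ms_e) ** 2
        den_v = (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
        v = num_v / den_v if den_v > 0 else (n - 1) * (k - 1)
    else:
        v = (n - 1) * (k - 1)
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    low1 = (n * (ms_r - f_l * ms_e)
            / (f_l * (k * ms_c + (k * n - k - n) * ms_e) + n * ms_r))
    upp1 = (n * (f_u * ms_r - ms_e)
            / (k * ms_c + (k * n - k - n) * ms_e + n * f_u * ms_r))

    def step_up(r1: float) -> float:
        return k * r1 / (1.0 + (k - 1) * r1)

    lo = float(np.clip(step_up(low1), -1.0, 1.0))
    hi = float(np.clip(step_up(upp1), -1.0, 1.0))
    return IccResult(est, lo, hi, n, k, landis_grade(est))


LANDIS_BINS = (
    (0.00, "poor"),          # below 0
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
)


def landis_grade(icc: float) -> str:
    """Landis-Koch agreement grade of an ICC.

    Values are rounded to two decimals before binning so that the
    printed bin edges (0.2 vs 0.21 etc.) tile the range: < 0 poor,
    0-0.20 slight, 0.21-0.40 fair, 0.41-0.60 moderate, 0.61-0.80
    substantial, > 0.80 (almost) perfect.
    """
    if not -1.0 <= icc <= 1.0:
        raise ValueError("ICC must lie in [-1, 1]")
    # half-up rounding (with a float-representation nudge) so 0.205 lands
    # in the 0.21 bin even though its double is fractionally below 0.205
    r = math.floor(icc * 100 + 0.5 + 1e-9) / 100
    if r < 0:
        return "poor"
    for edge, name in LANDIS_BINS[1:]:
        if r <= edge:
            return name
    return "(almost) perfect"
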