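"""Six-condition planning experiment over a cohort.

Every knee is planned under each combination of medial osteotomy height
(default 30 and 40 mm below the medial plateau) and lateral hinge
offset (default 5, 10, 15 mm medial to the lateral cortical wall,
labelled A/B/C).  The module then computes cohort-level summaries:
per-condition wedge-width mean/sd, all pairwise mean differences with
the per-knee rate of clinically relevant (>= 2 mm) differences, and
Pearson correlations of wedge width with bone lengths.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .cohort import Cohort
from .planner import PlannerConfig, PlanningError, condition_label, plan_osteotomy

__all__ = [
    "DEFAULT_HEIGHTS",
    "DEFAULT_HINGES",
    "run_conditions",
    "condition_summary",
    "pairwise_differences",
    "length_correlations",
]

log = logging.getLogger(__name__)

DEFAULT_HEIGHTS = (30.0, 40.0)   # mm below the medial plateau
DEFAULT_HINGES = (5.0, 10.0, 15.0)  # mm medial to the lateral cortex

WEDGE_COLUMNS = ["knee_id", "condition", "wedge_mm", "alpha_deg", "L_mm", "status"]


def run_conditions(cohort: Cohort, config: PlannerConfig | None = None,
                   heights=DEFAULT_HEIGHTS, hinges=DEFAULT_HINGES) -> pd.DataFrame:
    """Plan every knee under every (height, hinge) condition.

    Returns a long-format wedge table; solver failures are recorded per
    row (status column, NaN wedge) and do not abort the run.
    """
    cfg = config or PlannerConfig()
    rows = []
    for knee_id, leg in enumerate(cohort.legs):
        for h, d in itertools.product(heights, hinges):
            label = condition_label(h, d)
            try:
                plan = plan_osteotomy(leg, h, d, cfg)
                rows.append((knee_id, label, plan.wedge_width,
                             plan.correction_angle, plan.osteotomy_length, "ok"))
            except PlanningError as exc:
                log.warning("knee %d condition %s failed: %s", knee_id, label, exc)
                rows.append((knee_id, label, np.nan, np.nan, np.nan, f"failed: {exc}"))
    return pd.DataFrame(rows, columns=WEDGE_COLUMNS)


def condition_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition wedge-width mean, sd (ddof=1) and n."""
    if table.empty:
        raise ValueError("empty wedge table")
    ok = table[table["status"] == "ok"]
    out = (ok.groupby("condition")["wedge_mm"]
             .agg(mean_mm="mean", sd_mm="std", n="count")
             .reset_index())
    missing = set(table["condition"]) - set(out["condition"])
    if missing:
        raise ValueError(f"conditions with no successful plans: {sorted(missing)}")
    return out


def _paired_wide(table: pd.DataFrame) -> pd.DataFrame:
    ok = table[table["status"] == "ok"]
    wide = ok.pivot(index="knee_id", columns="condition", values="wedge_mm")
    if wide.isna().any().any():
        raise ValueError("unpaired data: some knees lack some conditions")
    return wide


def pairwise_differences(table: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """All unordered condition pairs: mean difference and >= threshold rate.

    mean_diff_mm is mean(first) - mean(second) in the listed pair order;
    rate_ge_thr_pct is 100 x the fraction of knees whose per-knee
    absolute wedge difference reaches the clinical-relevance threshold
    (default 2 mm).
    """
    wide = _paired_wide(table)
    conds = list(wide.columns)
    rows = []
    for a, b in itertools.combinations(conds, 2):
        delta = wide[a] - wide[b]
        rows.append({
            "pair": f"{a} vs {b}",
            "cond_1": a,
            "cond_2": b,
            "mean_diff_mm": float(delta.mean()),
            "rate_ge_thr_pct": float(100.0 * (delta.abs() >= threshold).mean()),
        })
    return pd.DataFrame(rows)


def length_correlations(table: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Pearson r (with two-sided p) of wedge width vs each bone length,
    per condition."""
    wide = _paired_wide(table)
    femora = np.array([leg.femoral_length for leg in cohort.legs])
    tibiae = np.array([leg.tibial_length for leg in cohort.legs])
    rows = []
    for cond in wide.columns:
        w = wide[cond].to_numpy()
        if np.std(w) == 0:
            raise ValueError(f"zero-variance wedge widths in condition {cond}")
        for name, x in (("femoral_length", femora), ("tibial_length", tibiae)):
            if np.std(x) == 0:
                raise ValueError(f"zero-variance {name}")
            r, p = pearsonr(w, x[wide.index])
            rows.append({"condition": cond, "length": name,
                         "pearson_r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
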