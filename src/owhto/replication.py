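"""Multi-seed replication of the cohort planning experiment.

Re-runs the default 55-knee experiment over many independently seeded
cohorts and aggregates the quantities the study design asks about:
per-condition wedge-width means, selected pairwise mean differences,
the >= 2 mm clinically-relevant-difference rate, the per-10 mm hinge
shift in wedge width, and the Tukey significance pattern.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortSpec, generate_cohort
from .experiment import run_conditions
from .planner import PlannerConfig
from .stats import tukey_hsd

__all__ = ["replicate", "aggregate"]

CONDITIONS = ("3cm-A", "3cm-B", "3cm-C", "4cm-A", "4cm-B", "4cm-C")


def _wide(table: pd.DataFrame) -> pd.DataFrame:
    ok = table[table["status"] == "ok"]
    return ok.pivot(index="knee_id", columns="condition", values="wedge_mm")


def replicate(seeds, config: PlannerConfig | None = None,
              threshold: float = 2.0) -> list[dict]:
    """One summary record per seed over the full six-condition experiment."""
    out = []
    for seed in seeds:
        cohort = generate_cohort(CohortSpec(seed=int(seed)))
        wide = _wide(run_conditions(cohort, config))
        groups = [wide[c].to_numpy() for c in CONDITIONS]
        tk = {t.pair: t.p_adj for t in tukey_hsd(groups, labels=CONDITIONS)}
        d3 = wide["3cm-A"] - wide["3cm-C"]
        d4 = wide["4cm-A"] - wide["4cm-C"]
        out.append({
            "seed": int(seed),
            "means": {c: float(wide[c].mean()) for c in CONDITIONS},
            "diff_3cm_A_C": float(d3.mean()),
            "diff_4cm_A_C": float(d4.mean()),
            "diff_heights_A": float((wide["3cm-A"] - wide["4cm-A"]).mean()),
            "rate_3cm_A_C_pct": float(100.0 * (d3.abs() >= threshold).mean()),
            "mm_per_10mm_shift": float((d3.abs().mean() + d4.abs().mean()) / 2.0),
            "tukey_p": tk,
        })
    return out


def aggregate(records: list[dict]) -> dict:
    """Across-seed averages of the per-seed summaries."""
    agg = {
        "n_seeds": len(records),
        "means": {c: float(np.mean([r["means"][c] for r in records]))
                  for c in CONDITIONS},
        "diff_3cm_A_C": float(np.mean([r["diff_3cm_A_C"] for r in records])),
        "diff_4cm_A_C": float(np.mean([r["diff_4cm_A_C"] for r in records])),
        "diff_heights_A": float(np.mean([r["diff_heights_A"] for r in records])),
        "rate_3cm_A_C_pct": float(np.mean([r["rate_3cm_A_C_pct"]
                                           for r in records])),
        "mm_per_10mm_shift": float(np.mean([r["mm_per_10mm_shift"]
                                            for r in records])),
    }
    return agg
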