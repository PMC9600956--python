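"""Synthetic study cohort of varus lower limbs.

The generator emulates the frontal-plane geometry of a 55-knee varus
cohort (genu varum >= 3 degrees) as characterised by its printed
summary statistics:

* varus angles follow a fixed integer-degree frequency table
  (3x15, 4x10, 5x4, 6x8, 7x2, 8x5, 9x6, 12x3, 13x1, 17x1; mean
  327/55 = 5.945 degrees).  In the default *exact* mode the angles are
  assigned deterministically from the table -- not resampled -- which
  removes a variance source and pins the cohort mean exactly;
* plateau width, femoral length and tibial length are independent
  truncated normals (mean/sd 79.5/6.9, 475.0/34.5, 372.6/30.2 mm,
  truncated at +/-3 sd to exclude non-physical limbs);
* side is right for 31/55 of knees, carried as metadata (geometry is
  mirrored; all planning quantities are mirror-invariant).

An observer-noise overlay (:func:`simulate_raters`) turns true values
into a subjects x raters x sessions table for reliability analysis,
with a once-per-rater additive bias and i.i.d. per-cell noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .leg_model import LegGeometry, make_leg

__all__ = [
    "VARUS_TABLE",
    "CohortSpec",
    "Cohort",
    "ReliabilityTable",
    "generate_cohort",
    "simulate_raters",
    "cohort_to_csv",
    "cohort_from_csv",
]

#: integer varus degree -> number of knees (n = 55)
VARUS_TABLE: dict[int, int] = {3: 15, 4: 10, 5: 4, 6: 8, 7: 2,
                               8: 5, 9: 6, 12: 3, 13: 1, 17: 1}

CSV_COLUMNS = ["knee_id", "side", "varus_deg", "plateau_width_mm",
               "femoral_length_mm", "tibial_length_mm", "seed"]


@dataclass(frozen=True)
class CohortSpec:
    """Generation recipe; (spec, seed) fully determines the cohort."""

    n: int = 55
    varus_table: dict = field(default_factory=lambda: dict(VARUS_TABLE))
    varus_mode: str = "exact"          # "exact" (assign per table) | "sample"
    plateau_width_dist: tuple = (79.5, 6.9)
    femoral_length_dist: tuple = (475.0, 34.5)
    tibial_length_dist: tuple = (372.6, 30.2)
    side_ratio: float = 31 / 55        # right fraction
    trunc_sd: float = 3.0              # truncation bound in sd units
    seed: int = 0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["varus_table"] = {int(k): int(v) for k, v in d["varus_table"].items()}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortSpec":
        d = yaml.safe_load(text)
        for k in ("plateau_width_dist", "femoral_length_dist", "tibial_length_dist"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class Cohort:
    legs: tuple
    spec: CohortSpec
    seed: int

    def __len__(self) -> int:
        return len(self.legs)


@dataclass(frozen=True)
class ReliabilityTable:
    """subjects x raters x sessions measurement array (complete design)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("values must be subjects x raters x sessions")
        object.__setattr__(self, "values", v)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  n: int, trunc_sd: float) -> np.ndarray:
    dist = truncnorm(-trunc_sd, trunc_sd, loc=mean, scale=sd)
    return dist.rvs(size=n, random_state=rng)


def _varus_angles(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    degs = np.array(sorted(spec.varus_table), dtype=float)
    freqs = np.array([spec.varus_table[int(d)] for d in degs], dtype=int)
    if spec.varus_mode == "exact":
        if freqs.sum() != spec.n:
            raise ValueError(
                f"varus frequencies sum to {freqs.sum()}, but n={spec.n} "
                "(exact mode requires equality)")
        return np.repeat(degs, freqs)
    if spec.varus_mode == "sample":
        p = freqs / freqs.sum()
        return rng.choice(degs, size=spec.n, p=p)
    raise ValueError(f"unknown varus_mode {spec.varus_mode!r}")


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Draw a reproducible cohort of :class:`LegGeometry` from ``spec``.

    ``seed`` overrides ``spec.seed``; identical (spec, seed) pairs yield
    identical cohorts.
    """
    if spec.n < 1:
        raise ValueError("cohort size must be >= 1")
    use_seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(use_seed)

    varus = _varus_angles(spec, rng)
    widths = _trunc_normal(rng, *spec.plateau_width_dist, spec.n, spec.trunc_sd)
    femora = _trunc_normal(rng, *spec.femoral_length_dist, spec.n, spec.trunc_sd)
    tibiae = _trunc_normal(rng, *spec.tibial_length_dist, spec.n, spec.trunc_sd)

    n_right = int(round(spec.n * spec.side_ratio))
    sides = np.array(["right"] * n_right + ["left"] * (spec.n - n_right))
    rng.shuffle(sides)

    legs = tuple(
        make_leg(varus_angle=float(varus[i]), femoral_length=float(femora[i]),
                 tibial_length=float(tibiae[i]), plateau_width=float(widths[i]),
                 side=str(sides[i]))
        for i in range(spec.n)
    )
    return Cohort(legs=legs, spec=spec, seed=use_seed)


def simulate_raters(true_values, n_raters: int = 2, n_sessions: int = 2,
                    rater_bias_sd: float = 0.0, noise_sd: float = 0.0,
                    seed: int = 0, label: str = "") -> ReliabilityTable:
    """Overlay observer noise on true measurements.

    observed[i, r, s] = true[i] + bias[r] + e[i, r, s] with
    bias[r] ~ N(0, rater_bias_sd) drawn once per rater and
    e ~ N(0, noise_sd) i.i.d. per cell.
    """
    true = np.asarray(true_values, dtype=float)
    if true.ndim != 1 or true.size == 0:
        raise ValueError("true_values must be a non-empty 1D sequence")
    if n_raters < 2 or n_sessions < 1:
        raise ValueError("need >= 2 raters and >= 1 session")
    if rater_bias_sd < 0 or noise_sd < 0:
        raise ValueError("noise standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    bias = rng.normal(0.0, rater_bias_sd, size=n_raters) if rater_bias_sd else np.zeros(n_raters)
    noise = (rng.normal(0.0, noise_sd, size=(true.size, n_raters, n_sessions))
             if noise_sd else np.zeros((true.size, n_raters, n_sessions)))
    obs = true[:, None, None] + bias[None, :, None] + noise
    return ReliabilityTable(values=obs, label=label)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for i, leg in enumerate(cohort.legs):
        rows.append({
            "knee_id": i,
            "side": leg.side,
            "varus_deg": leg.varus_angle,
            "plateau_width_mm": leg.plateau_width,
            "femoral_length_mm": leg.femoral_length,
            "tibial_length_mm": leg.tibial_length,
            "seed": cohort.seed,
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def cohort_to_csv(cohort: Cohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False, float_format="%.6f")


def cohort_from_csv(path, spec: CohortSpec | None = None) -> Cohort:
    """Rebuild a cohort from its CSV serialisation (canonical embedding)."""
    df = pd.read_csv(path)
    legs = tuple(
        make_leg(varus_angle=row.varus_deg, femoral_length=row.femoral_length_mm,
                 tibial_length=row.tibial_length_mm, plateau_width=row.plateau_width_mm,
                 side=row.side)
        for row in df.itertuples()
    )
    seed = int(df["seed"].iloc[0]) if len(df) else 0
    return Cohort(legs=legs, spec=spec or CohortSpec(n=len(legs)), seed=seed)
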