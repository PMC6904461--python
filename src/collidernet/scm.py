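"""Structural causal model for the simulated lung-nodule cohort.

The data-generating mechanism couples two latent patient variables --
tumour aggressiveness ``u1`` and patient fitness ``u2`` -- to an image
collider ``x`` (nodule size), a prognostic factor ``z`` (radiodensity
heterogeneity), a binary treatment ``t`` and a continuous survival
outcome ``y``:

    u1, u2 ~ Normal(0, sd_u)            sd_u = 0.7071 ~ sqrt(2)/2
    z      ~ Normal(0, sd_z)
    x      ~ Normal(u1 - u2, sd_x_noise)
    t      ~ Bernoulli(invlogit(u2 - treat_offset + Normal(0, sd_t_noise)))
    y      ~ Normal(treatment_effect * t + coef_z * z + coef_u1 * u1
                    + outcome_offset, sd_y_noise)

All second Normal parameters are standard deviations.  ``x`` is a
collider (child of both latents): conditioning on it opens a
non-causal backdoor path between treatment and outcome, which is the
bias this package is built to remove.  With the defaults the true
average treatment effect is exactly ``treatment_effect = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "SCMParameters",
    "sample_cohort",
    "invlogit",
    "collider_scale_transform",
    "SCALE_MODES",
]

COHORT_COLUMNS = ("u1", "u2", "z", "x", "t", "y")

#: power applied on the positive (area-like) scale for each measurement mode
SCALE_MODES = {"identity": 1.0, "area": 1.0, "volume": 3.0, "diameter": 1.0 / 3.0}


@dataclass(frozen=True)
class SCMParameters:
    """Numeric constants of the structural equations.

    Defaults reproduce the published simulation setup exactly.  ``sd_u``
    is chosen so that ``x = u1 - u2 + noise`` has standard deviation ~1.
    """

    sd_u: float = 0.7071
    sd_z: float = 1.0
    sd_x_noise: float = 0.05
    treat_offset: float = 0.5
    sd_t_noise: float = 0.25
    treatment_effect: float = 1.0
    coef_z: float = -1.0
    coef_u1: float = -2.0
    outcome_offset: float = -0.5
    sd_y_noise: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sd_u", "sd_z", "sd_x_noise", "sd_t_noise", "sd_y_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SCMParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SCM parameter(s): {sorted(unknown)}")
        return cls(**d)


def invlogit(s):
    """Logistic function 1 / (1 + exp(-s)), mapping log-odds to probability."""
    return expit(s)


def sample_cohort(n: int, params: SCMParameters | None = None, seed: int = 0) -> pd.DataFrame:
    """Sample ``n`` subjects from the structural equations.

    Returns a DataFrame with columns ``u1, u2, z, x, t, y`` and a
    contiguous 0-based index.  Reproducible for a fixed ``seed``.
    """
    if n < 0:
        raise ValueError(f"cohort size must be non-negative, got {n}")
    p = params or SCMParameters()
    rng = np.random.default_rng(seed)
    u1 = rng.normal(0.0, p.sd_u, size=n)
    u2 = rng.normal(0.0, p.sd_u, size=n)
    z = rng.normal(0.0, p.sd_z, size=n)
    x = rng.normal(u1 - u2, p.sd_x_noise)
    logit = rng.normal(u2 - p.treat_offset, p.sd_t_noise)
    t = (rng.uniform(size=n) < invlogit(logit)).astype(np.int64)
    mean_y = p.treatment_effect * t + p.coef_z * z + p.coef_u1 * u1 + p.outcome_offset
    y = rng.normal(mean_y, p.sd_y_noise)
    return pd.DataFrame(
        {"u1": u1, "u2": u2, "z": z, "x": x, "t": t, "y": y},
        index=pd.RangeIndex(n),
    )


def treated_fraction(cohort: pd.DataFrame) -> float:
    """Empirical share of treated subjects (logged, never asserted)."""
    if len(cohort) == 0:
        return float("nan")
    return float(cohort["t"].mean())


def collider_scale_transform(
    x,
    mode: str = "identity",
    *,
    log_mean: float = 0.0,
    log_sd: float = 1.0,
):
    """Measured collider under a monotone power transform of size.

    The standardized collider ``x`` is treated as a z-score of log-area:
    it is mapped to a positive area-like scale ``exp(x * log_sd +
    log_mean)``, raised to the mode's power (1 for area measured as
    area, 3 for a diameter-scale collider measured as volume, 1/3 for
    the inverse mismatch), and re-standardized to zero mean and unit sd
    over the cohort.  ``identity`` returns the standardized input.
    """
    if mode not in SCALE_MODES:
        raise ValueError(f"unknown scale mode {mode!r}; expected one of {sorted(SCALE_MODES)}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("collider values must be finite")
    if mode == "identity":
        out = x
    else:
        positive = np.exp(x * log_sd + log_mean)
        out = positive ** SCALE_MODES[mode]
    sd = out.std()
    if sd == 0:
        return np.zeros_like(out)
    return (out - out.mean()) / sd


def save_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df.index = pd.RangeIndex(len(df))
    return df
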