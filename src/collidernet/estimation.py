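"""Post-hoc treatment-effect and prediction-error estimation.

After the constrained CNN converges, all its parameters are frozen and
the final-layer activations are computed per image with the
deterministic evaluation path (center crop, dropout off).  A single
ordinary least squares of the outcome on the *constrained* activations
plus the treatment indicator -- the collider slot ``a_1`` excluded --
yields the CausalNet treatment-effect estimate ``beta_t``.  The
BiasedNet contrast regresses on all activations, thereby conditioning
on the collider.  Three plain regressions on (noisy) tabular features
serve as baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .imaging import MatchedDataset
from .network import ColliderCNN, evaluate_losses

__all__ = [
    "FitSummary",
    "extract_activations",
    "causalnet_fit",
    "biasednet_fit",
    "regression_baselines",
    "independence_r2",
    "BASELINE_REGRESSOR_SETS",
]

BASELINE_REGRESSOR_SETS = {
    "Regression (t)": ("t",),
    "Regression (t, x', z')": ("t", "x_prime", "z_prime"),
    "Regression* (t, z')": ("t", "z_prime"),
}


@dataclass
class FitSummary:
    """Estimated ATE and validation outcome MSE for one model variant."""

    model_name: str
    variables: str
    ate: float
    mse_y: float
    diagnostics: dict = field(default_factory=dict)
    params: pd.Series | None = None

    def __post_init__(self):
        if self.mse_y < 0:
            raise ValueError("mse_y must be non-negative")

    def summary(self) -> str:
        lines = [
            f"{self.model_name:<24s} variables: {self.variables}",
            f"  ATE (beta_t): {self.ate: .4f}",
            f"  MSE_y (validation): {self.mse_y: .4f}",
        ]
        for k, v in self.diagnostics.items():
            lines.append(f"  {k}: {v: .4f}")
        return "\n".join(lines)


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop trailing collinear columns until the design has full rank."""
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank == mat.shape[1]:
        return X
    keep: list[str] = []
    for col in X.columns:
        trial = keep + [col]
        if np.linalg.matrix_rank(X[trial].to_numpy(dtype=float)) == len(trial):
            keep.append(col)
    dropped = [c for c in X.columns if c not in keep]
    warnings.warn(f"dropping collinear regressor(s): {dropped}", stacklevel=3)
    return X[keep]


def _ols_fit(X: pd.DataFrame, y: np.ndarray):
    X = _drop_collinear(X)
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design).fit(), design.columns


def extract_activations(
    model: ColliderCNN,
    matched: MatchedDataset,
    batch_size: int = 256,
) -> np.ndarray:
    """Deterministic per-subject final-layer activations (n, N_k).

    Uses the evaluation augmentation path (center crop, no flips) with
    dropout disabled; identical subjects give identical vectors.
    """
    if not model.trained:
        raise RuntimeError("model must be trained before extracting activations")
    from .imaging import augment  # local import to keep module deps flat

    stack = matched.image_stack()
    t = matched.table["t"].to_numpy(dtype=float)
    out = np.empty((len(matched), model.arch.n_activations))
    for start in range(0, len(matched), batch_size):
        idx = np.arange(start, min(start + batch_size, len(matched)))
        images = np.stack([augment(stack[i], "eval") for i in idx])
        _, acts = model.forward(images, t[idx], train=False)
        out[idx] = acts.data
    return out


def independence_r2(activations_rest: np.ndarray, x_prime: np.ndarray) -> float:
    """R-squared of OLS of the measured collider on the constrained
    activations: the post-training independence diagnostic."""
    X = pd.DataFrame(
        activations_rest, columns=[f"a{j}" for j in range(2, activations_rest.shape[1] + 2)]
    )
    res, _ = _ols_fit(X, np.asarray(x_prime, dtype=float))
    return float(res.rsquared)


def _split_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    train_index: np.ndarray,
    model_name: str,
    variables: str,
    diagnostics: dict | None = None,
) -> FitSummary:
    train_mask = np.zeros(len(X), dtype=bool)
    train_mask[train_index] = True
    res, cols = _ols_fit(X.iloc[np.flatnonzero(train_mask)], y[train_mask])
    design_all = sm.add_constant(X, has_constant="add")[list(cols)]
    pred = design_all.to_numpy(dtype=float) @ res.params.to_numpy()
    val_mask = ~train_mask
    if not val_mask.any():
        raise ValueError("no validation rows left for MSE evaluation")
    mse = float(((y[val_mask] - pred[val_mask]) ** 2).mean())
    ate = float(res.params.get("t", np.nan))
    return FitSummary(
        model_name, variables, ate, mse, diagnostics or {}, params=res.params
    )


def causalnet_fit(
    activations: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    train_index: np.ndarray,
    x_prime: np.ndarray | None = None,
) -> FitSummary:
    """OLS of y on {t, a_j : j > 1}: the collider slot is excluded.

    The regression is fitted on the training rows; ``mse_y`` is
    evaluated on the remaining (validation) rows.  When ``x_prime`` is
    given, the independence R^2 on the validation rows is reported as a
    diagnostic.
    """
    acts = np.asarray(activations, dtype=float)
    X = pd.DataFrame(
        {"t": np.asarray(t, dtype=float)}
        | {f"a{j}": acts[:, j - 1] for j in range(2, acts.shape[1] + 1)}
    )
    diag = {}
    if x_prime is not None:
        val_mask = np.ones(len(X), dtype=bool)
        val_mask[train_index] = False
        diag["independence_r2"] = independence_r2(
            acts[val_mask, 1:], np.asarray(x_prime)[val_mask]
        )
    return _split_fit(
        X, np.asarray(y, dtype=float), train_index,
        "CausalNet", "t, a_j (j>1)", diag,
    )


def biasednet_fit(
    activations: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    train_index: np.ndarray,
) -> FitSummary:
    """OLS of y on the treatment and ALL activations (conditions on the
    full image, hence on the collider)."""
    acts = np.asarray(activations, dtype=float)
    X = pd.DataFrame(
        {"t": np.asarray(t, dtype=float)}
        | {f"a{j}": acts[:, j - 1] for j in range(1, acts.shape[1] + 1)}
    )
    return _split_fit(X, np.asarray(y, dtype=float), train_index, "BiasedNet", "t, image")


def regression_baselines(
    cohort_train: pd.DataFrame,
    cohort_val: pd.DataFrame,
    noise_sd_x: float,
    noise_sd_z: float,
    seed: int = 0,
) -> list[FitSummary]:
    """The three tabular-regression baselines.

    The simulated (x, z) are replaced by noisy measurements
    x' = x + N(0, sd_x), z' = z + N(0, sd_z), with sds calibrated from
    the inherent measurement error of the imaging pipeline; each
    baseline is fitted on the training cohort and scored on the
    validation cohort.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for cohort in (cohort_train, cohort_val):
        df = cohort[["t", "y"]].copy()
        df["x_prime"] = cohort["x"].to_numpy() + rng.normal(0, noise_sd_x, len(cohort))
        df["z_prime"] = cohort["z"].to_numpy() + rng.normal(0, noise_sd_z, len(cohort))
        frames.append(df)
    both = pd.concat(frames, ignore_index=True)
    train_index = np.arange(len(cohort_train))
    out = []
    for name, regs in BASELINE_REGRESSOR_SETS.items():
        fs = _split_fit(
            both[list(regs)], both["y"].to_numpy(dtype=float), train_index,
            name.split(" ")[0], ", ".join(r.replace("_prime", "'") for r in regs),
        )
        fs.model_name = name.split(" (")[0]
        out.append(fs)
    return out


def mse_y_on_split(
    model: ColliderCNN, matched_val: MatchedDataset
) -> float:
    """Validation outcome MSE straight from the network head (used for
    logging; the reported MSE comes from the post-hoc OLS refit)."""
    from .network import TrainConfig

    return evaluate_losses(model, matched_val, TrainConfig(mode="biased")).L_y
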