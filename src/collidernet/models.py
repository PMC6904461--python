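"""Model objects: construct from matched data, ``fit()`` to results.

``CausalNet`` and ``BiasedNet`` wrap the CNN training plus the post-hoc
OLS; ``TreatmentRegression`` wraps the tabular baselines.  Every
``fit`` returns a results object carrying the ATE estimate, the
validation outcome MSE, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import estimation
from .estimation import FitSummary
from .imaging import MatchedDataset
from .network import ArchitectureSpec, ColliderCNN, TrainConfig, train
from .scm import SCALE_MODES

__all__ = ["CausalNet", "BiasedNet", "TreatmentRegression", "CNNResults", "RegressionResults"]


def transformed_collider(
    matched_train: MatchedDataset,
    matched_val: MatchedDataset,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Measured collider under a scale mismatch, on both splits.

    The standardized log-size feature is mapped to the positive area
    scale using the pool's log statistics, raised to the mode's power
    (1: area, 3: volume, 1/3: diameter), and re-standardized with
    training-cohort constants.
    """
    tr = matched_train.table["x_prime_std"].to_numpy(dtype=float)
    va = matched_val.table["x_prime_std"].to_numpy(dtype=float)
    if mode in ("identity", "area"):
        return tr, va
    if mode not in SCALE_MODES:
        raise ValueError(f"unknown scale mode {mode!r}")
    s = matched_train.pool.log_stats
    power = SCALE_MODES[mode]
    pos_tr = np.exp(tr * s["sd_log_x"] + s["mu_log_x"]) ** power
    pos_va = np.exp(va * s["sd_log_x"] + s["mu_log_x"]) ** power
    mu, sd = pos_tr.mean(), pos_tr.std()
    return (pos_tr - mu) / sd, (pos_va - mu) / sd


@dataclass
class CNNResults:
    """Fitted CNN variant: estimates, diagnostics and training history."""

    fit_summary: FitSummary
    network: ColliderCNN
    training_log: pd.DataFrame
    activations_train: np.ndarray
    activations_val: np.ndarray

    @property
    def ate(self) -> float:
        return self.fit_summary.ate

    @property
    def mse_y(self) -> float:
        return self.fit_summary.mse_y

    @property
    def diagnostics(self) -> dict:
        return self.fit_summary.diagnostics

    @property
    def params(self) -> pd.Series:
        return self.fit_summary.params

    def summary(self) -> str:
        n_epochs = int(self.training_log["epoch"].max()) + 1 if len(self.training_log) else 0
        head = self.fit_summary.summary()
        return f"{head}\n  epochs trained: {n_epochs}"

    def plot_training(self, ax=None):
        """Per-epoch total loss for both splits."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for split, grp in self.training_log.groupby("split"):
            ax.plot(grp["epoch"], grp["L_total"], label=split)
        ax.set_xlabel("epoch")
        ax.set_ylabel("total loss")
        ax.legend()
        return ax


class _CNNModel:
    """Shared scaffolding for the causal and biased CNN variants."""

    mode = "causal"
    name = "CausalNet"

    def __init__(
        self,
        matched_train: MatchedDataset,
        matched_val: MatchedDataset,
        arch: ArchitectureSpec | None = None,
        train_config: TrainConfig | None = None,
        scale_mode: str = "area",
    ):
        self.matched_train = matched_train
        self.matched_val = matched_val
        self.arch = arch or ArchitectureSpec()
        cfg = train_config or TrainConfig()
        self.train_config = replace(cfg, mode=self.mode)
        self.scale_mode = scale_mode

    def fit(self, seed: int = 0, verbose: bool = False) -> CNNResults:
        xp_tr, xp_va = transformed_collider(
            self.matched_train, self.matched_val, self.scale_mode
        )
        net = ColliderCNN(self.arch, seed=seed, dtype=self.train_config.dtype)
        log = train(
            net,
            self.matched_train,
            self.matched_val,
            self.train_config,
            seed=seed + 1,
            x_prime_train=xp_tr,
            x_prime_val=xp_va,
            verbose=verbose,
        )
        acts_tr = estimation.extract_activations(net, self.matched_train)
        acts_va = estimation.extract_activations(net, self.matched_val)
        acts = np.vstack([acts_tr, acts_va])
        t = np.concatenate(
            [
                self.matched_train.table["t"].to_numpy(dtype=float),
                self.matched_val.table["t"].to_numpy(dtype=float),
            ]
        )
        y = np.concatenate(
            [
                self.matched_train.table["y"].to_numpy(dtype=float),
                self.matched_val.table["y"].to_numpy(dtype=float),
            ]
        )
        x_prime = np.concatenate([xp_tr, xp_va])
        train_index = np.arange(len(self.matched_train))
        fs = self._post_hoc(acts, t, y, train_index, x_prime)
        return CNNResults(fs, net, log, acts_tr, acts_va)

    def _post_hoc(self, acts, t, y, train_index, x_prime) -> FitSummary:
        raise NotImplementedError


class CausalNet(_CNNModel):
    """Constrained variant: L_y + L_x + L_reg, collider slot excluded
    from the post-hoc treatment-effect regression."""

    mode = "causal"
    name = "CausalNet"

    def _post_hoc(self, acts, t, y, train_index, x_prime) -> FitSummary:
        return estimation.causalnet_fit(acts, t, y, train_index, x_prime=x_prime)


class BiasedNet(_CNNModel):
    """Unconstrained contrast: trains on L_y only and regresses the
    outcome on all activations, conditioning on the collider."""

    mode = "biased"
    name = "BiasedNet"

    def _post_hoc(self, acts, t, y, train_index, x_prime) -> FitSummary:
        fs = estimation.biasednet_fit(acts, t, y, train_index)
        fs.diagnostics["collider_r2"] = estimation.independence_r2(
            acts[train_index][:, :], x_prime[train_index]
        )
        return fs


@dataclass
class RegressionResults:
    fit_summary: FitSummary

    @property
    def ate(self) -> float:
        return self.fit_summary.ate

    @property
    def mse_y(self) -> float:
        return self.fit_summary.mse_y

    @property
    def params(self) -> pd.Series:
        return self.fit_summary.params

    def summary(self) -> str:
        return self.fit_summary.summary()


class TreatmentRegression:
    """Tabular OLS baseline on (t, x', z') subsets with calibrated
    measurement noise on the simulated features."""

    def __init__(
        self,
        cohort_train: pd.DataFrame,
        cohort_val: pd.DataFrame,
        regressors: tuple = ("t",),
        noise_sd_x: float = 0.0,
        noise_sd_z: float = 0.0,
    ):
        allowed = {("t",), ("t", "x_prime", "z_prime"), ("t", "z_prime")}
        if tuple(regressors) not in allowed:
            raise ValueError(f"regressor set must be one of {sorted(allowed)}")
        self.cohort_train = cohort_train
        self.cohort_val = cohort_val
        self.regressors = tuple(regressors)
        self.noise_sd_x = noise_sd_x
        self.noise_sd_z = noise_sd_z

    def fit(self, seed: int = 0) -> RegressionResults:
        fits = estimation.regression_baselines(
            self.cohort_train,
            self.cohort_val,
            self.noise_sd_x,
            self.noise_sd_z,
            seed=seed,
        )
        by_set = dict(zip(estimation.BASELINE_REGRESSOR_SETS.values(), fits))
        return RegressionResults(by_set[self.regressors])
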