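"""Constrained multi-task CNN for outcome prediction without collider bias.

A VGG-style stack of five 3x3 convolutions (16 channels, ReLU, with 2x2
max-pooling after the first four stages so a 51x51 input flattens to
144 = 16*3*3) feeds three fully connected layers (144, 144, 12; ReLU +
dropout 0.25) and a final linear layer of ``N_k = 6`` activations.  The
outcome head is ordinary linear regression on those activations plus
the treatment indicator:

    y_hat = beta0 + beta_t * t + sum_j beta_j * a_j

Three loss terms drive training of the *causal* variant:

* ``L_y``   -- minibatch MSE of the outcome;
* ``L_x``   -- MSE tying the reserved activation ``a_1`` to the measured
  (standardized) collider ``x'``;
* ``L_reg`` -- a hinge on the improvement an in-minibatch least-squares
  fit of ``x'`` on the remaining activations achieves over the batch
  mean: max(0, MSE(xbar, x') - MSE(xhat_reg, x')).  When the remaining
  activations carry no linear information about the collider the hinge
  sits at zero.

The *biased* variant trains on ``L_y`` alone; *ground-truth* variants
replace the outcome with a known label (x or z) to quantify inherent
measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .autograd import Tensor, concat, conv2d, maxpool2x2, solve_sym
from .imaging import CROP_SIZE, MatchedDataset, augment

__all__ = [
    "ArchitectureSpec",
    "TrainConfig",
    "ColliderCNN",
    "LossBreakdown",
    "loss_y",
    "loss_x",
    "loss_reg",
    "total_loss",
    "train",
    "ground_truth_measurement_error",
    "matching_measurement_error",
    "TrainingDivergence",
    "DegenerateBatchError",
]


class TrainingDivergence(RuntimeError):
    """Raised when a loss becomes non-finite during optimization."""


class DegenerateBatchError(ValueError):
    """Raised when a minibatch is too small for the in-batch regression."""


@dataclass(frozen=True)
class ArchitectureSpec:
    n_conv_layers: int = 5
    conv_kernel: int = 3
    conv_channels: int = 16
    n_pool_stages: int = 4  # 51 -> 25 -> 12 -> 6 -> 3
    flatten_dim: int = 144  # 16 channels x 3 x 3
    fc_sizes: tuple = (144, 144, 12)
    n_activations: int = 6  # N_k; slot 1 is reserved for the collider
    dropout: float = 0.25

    def __post_init__(self):
        if self.n_activations < 2:
            raise ValueError("need at least one constrained activation (N_k >= 2)")


@dataclass(frozen=True)
class TrainConfig:
    mode: str = "causal"  # causal | biased | ground_truth
    ground_truth_target: str = "z"  # only for ground_truth mode: 'x' or 'z'
    batch_size: int = 40
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    ridge: float = 1e-6
    differentiable_reg: bool = True  # gradients through the in-batch OLS fit
    precision: str = "float32"  # training dtype; losses accept float64 inputs
    #: scale on which the measured collider enters L_x / L_reg.  The hinge
    #: compares an in-minibatch OLS against the batch mean, which discounts
    #: the penalty by the overfit factor (1 - p/m); on a unit-variance
    #: collider that discount leaves leaking marginally profitable, so the
    #: collider target is amplified to let the constraint dominate (the
    #: raw measured size plays this role when it is not re-standardized).
    collider_loss_scale: float = 1.0
    #: compare the in-batch OLS against the mean with df-corrected variance
    #: estimates, so chance-level fits are not penalized (see loss_reg)
    df_correct_reg: bool = True
    #: evaluate L_x / L_reg on a dropout-free forward of the same minibatch,
    #: so the penalty prices the dependence of the deterministic activations
    #: the post-hoc estimator uses, not their dropout-corrupted versions
    clean_collider_pass: bool = True
    #: gradient carrier for the independence constraint.  "ols_hinge"
    #: differentiates the hinge itself; its gradient is a rank-one push
    #: along the in-batch OLS residual, which vanishes as the fit becomes
    #: good and in practice settles into a leak-and-push limit cycle.
    #: "decorrelation" (default) backpropagates the squared sample
    #: correlations between each constrained activation and the collider
    #: instead -- a smooth, scale-free contraction of exactly the linear
    #: dependence the constraint forbids.  The hinge value is always the
    #: one reported in the training log and used for early stopping.
    reg_gradient: str = "decorrelation"
    #: weight of the decorrelation carrier.  A leak of squared correlation
    #: rho2 buys at most ~rho2 of outcome MSE (the collider channel has
    #: unit outcome variance), so any weight above 1 makes leaking a net
    #: loss; 3 leaves margin without drowning the outcome gradient in the
    #: penalty's chance-level minibatch noise (~ p/m per batch).
    decorrelation_weight: float = 27.0
    #: epochs of L_y + L_x training before the independence constraint is
    #: enabled.  Stripping collider signal from the constrained activations
    #: is cheap once the reserved slot a_1 already carries x' (the leak is
    #: then redundant for the outcome loss); enforcing it from scratch
    #: fights the trunk's need to learn size for a_1 in the first place.
    constraint_warmup_epochs: int = 10
    #: epochs over which the constraint weight ramps linearly to full
    #: strength after the warm-up, so the representation adjusts instead
    #: of collapsing under a sudden large penalty
    constraint_ramp_epochs: int = 15
    #: recent minibatches whose (detached) activations sharpen the
    #: correlation estimate; 0 uses the current batch only.  Buffered
    #: activations come from slightly stale weights, which inflates the
    #: variance estimate when parameters move fast, so the default is off.
    decorrelation_buffer_batches: int = 0

    def __post_init__(self):
        if self.mode not in ("causal", "biased", "ground_truth"):
            raise ValueError(f"unknown training mode {self.mode!r}")
        if self.precision not in ("float32", "float64"):
            raise ValueError(f"unknown precision {self.precision!r}")
        if self.reg_gradient not in ("ols_hinge", "decorrelation"):
            raise ValueError(f"unknown reg_gradient {self.reg_gradient!r}")

    @property
    def dtype(self):
        return np.float32 if self.precision == "float32" else np.float64


@dataclass
class LossBreakdown:
    """Per-minibatch loss components; the total is their exact sum."""

    L_y: float
    L_x: float = 0.0
    L_reg: float = 0.0

    @property
    def L_total(self) -> float:
        return self.L_y + self.L_x + self.L_reg


# ---------------------------------------------------------------------------
# Loss terms (operate on Tensors or plain arrays)


def _mse(a: Tensor, b) -> Tensor:
    if not isinstance(b, Tensor):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    return ((a - b) ** 2).mean()


def loss_y(y_hat, y) -> Tensor:
    """Minibatch mean squared error of the outcome."""
    y_hat = y_hat if isinstance(y_hat, Tensor) else Tensor(y_hat)
    y = np.asarray(y, dtype=y_hat.data.dtype)
    if y.size == 0:
        raise ValueError("empty batch")
    if y_hat.data.shape != y.shape:
        raise ValueError("y_hat and y length mismatch")
    return _mse(y_hat, y)


def loss_x(a1, x_prime) -> Tensor:
    """MSE binding the reserved activation to the measured collider."""
    a1 = a1 if isinstance(a1, Tensor) else Tensor(a1)
    x_prime = np.asarray(x_prime, dtype=a1.data.dtype)
    if x_prime.size == 0:
        raise ValueError("empty batch")
    if a1.data.shape != x_prime.shape:
        raise ValueError("a1 and x_prime length mismatch")
    return _mse(a1, x_prime)


def loss_reg(
    a_rest,
    x_prime,
    ridge: float = 1e-6,
    differentiable: bool = True,
    df_correct: bool = False,
) -> Tensor:
    """Hinge penalty on linear predictability of the collider.

    Regresses ``x'`` on the constrained activations (with intercept) by
    least squares inside the minibatch; the penalty is the improvement
    of that fit over the batch-mean predictor, clipped at zero.  A ridge
    jitter of ``ridge`` stabilizes the normal equations; gradients flow
    through the closed-form solution unless ``differentiable=False``.

    With ``df_correct`` the two mean squared errors are replaced by
    their degrees-of-freedom-corrected variance estimates (factors
    m/(m-1) and m/(m-p-1)).  An in-sample OLS always beats the raw
    batch mean, so the raw hinge carries a positive floor of about
    (p/m)*var even for independent activations; the corrected
    comparison is centred at zero under independence — "no better than
    the mean" meaning no better than chance — and prices above-chance
    dependence at its full population value.
    """
    a_rest = a_rest if isinstance(a_rest, Tensor) else Tensor(a_rest)
    x_prime = np.asarray(x_prime, dtype=a_rest.data.dtype)
    m, p = a_rest.data.shape
    if m != x_prime.shape[0]:
        raise ValueError("a_rest and x_prime length mismatch")
    if m <= p + 1:
        raise DegenerateBatchError(
            f"minibatch of {m} too small for OLS on {p} regressors"
        )
    if not differentiable:
        a_rest = a_rest.detach()
    dt = a_rest.data.dtype
    design = concat([Tensor(np.ones((m, 1), dtype=dt)), a_rest], axis=1)  # (m, p+1)
    gram = design.T @ design + Tensor(ridge * np.eye(p + 1, dtype=dt))
    beta = solve_sym(gram, design.T @ Tensor(x_prime.astype(dt)))
    x_hat = design @ beta
    mse_mean = ((x_prime - x_prime.mean()) ** 2).mean()
    mse_fit = _mse(x_hat, x_prime.astype(dt))
    if df_correct:
        mse_mean = mse_mean * m / (m - 1)
        mse_fit = mse_fit * (m / (m - p - 1))
    gap = Tensor(np.asarray(mse_mean, dtype=dt)) - mse_fit
    return gap.relu()


def decorrelation_penalty(
    a_rest: Tensor,
    x_prime: np.ndarray,
    buffer_a: np.ndarray | None = None,
    buffer_x: np.ndarray | None = None,
    chance_hinge: bool = False,
) -> Tensor:
    """Sum of squared sample correlations between each constrained
    activation and the collider (scale-free; smooth at independence),
    hinged at the chance level 2/n so sampling noise goes unpunished.

    ``buffer_a``/``buffer_x`` are recent-batch activations treated as
    constants: they sharpen the correlation estimate (the chance-level
    floor of a squared sample correlation is ~1/n) while gradients flow
    through the current minibatch only.
    """
    dt = a_rest.data.dtype
    rows = [a_rest]
    x = np.asarray(x_prime, dtype=dt)
    if buffer_a is not None and len(buffer_a):
        rows.append(Tensor(np.asarray(buffer_a, dtype=dt)))
        x = np.concatenate([x, np.asarray(buffer_x, dtype=dt)])
    stacked = concat(rows, axis=0) if len(rows) > 1 else a_rest
    xc = x - x.mean()
    var_x = float((xc**2).mean()) or 1.0
    centered = stacked + Tensor(-stacked.data.mean(axis=0))
    cov = (centered * Tensor(xc[:, None])).mean(axis=0)  # (p,)
    var_a = (centered**2).mean(axis=0) + np.asarray(1e-8, dtype=dt)
    rho2 = cov**2 / (var_a * np.asarray(var_x, dtype=dt))
    if chance_hinge:
        # E[rho^2] ~ 1/n for independent columns: stay silent inside the
        # sampling band so chance correlations do not erode useful features
        thr = np.asarray(2.0 / len(x), dtype=dt)
        rho2 = (rho2 + Tensor(-thr)).relu()
    return rho2.sum()


def total_loss(parts: LossBreakdown) -> float:
    """Exact unweighted sum of the loss components."""
    for v in (parts.L_y, parts.L_x, parts.L_reg):
        if not np.isfinite(v):
            raise TrainingDivergence(f"non-finite loss component in {parts}")
    return parts.L_total


# ---------------------------------------------------------------------------
# Model


def _he(rng, *shape):
    fan_in = int(np.prod(shape[1:])) or shape[0]
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class ColliderCNN:
    """The CNN with its linear outcome head.

    Parameters live in ``self.params`` (name -> Tensor); the head is
    ``w_a`` (activation coefficients), ``w_t`` (treatment coefficient
    beta_t) and ``b0`` (intercept beta0).
    """

    def __init__(self, arch: ArchitectureSpec | None = None, seed: int = 0,
                 dtype=np.float64):
        self.arch = arch or ArchitectureSpec()
        self.dtype = np.dtype(dtype).type
        a = self.arch
        rng = np.random.default_rng(seed)
        p: dict[str, Tensor] = {}
        c_in = 1
        for i in range(a.n_conv_layers):
            p[f"conv{i}_w"] = Tensor(
                _he(rng, a.conv_channels, c_in, a.conv_kernel, a.conv_kernel),
                requires_grad=True,
            )
            p[f"conv{i}_b"] = Tensor(np.zeros(a.conv_channels), requires_grad=True)
            c_in = a.conv_channels
        d_in = a.flatten_dim
        for i, d_out in enumerate(a.fc_sizes):
            p[f"fc{i}_w"] = Tensor(_he(rng, d_in, d_out), requires_grad=True)
            p[f"fc{i}_b"] = Tensor(np.zeros(d_out), requires_grad=True)
            d_in = d_out
        p["act_w"] = Tensor(_he(rng, d_in, a.n_activations), requires_grad=True)
        p["act_b"] = Tensor(np.zeros(a.n_activations), requires_grad=True)
        p["w_a"] = Tensor(np.zeros(a.n_activations), requires_grad=True)
        p["w_t"] = Tensor(np.zeros(()), requires_grad=True)
        p["b0"] = Tensor(np.zeros(()), requires_grad=True)
        for t in p.values():
            t.data = t.data.astype(self.dtype)
        self.params = p
        self.trained = False

    def parameter_count(self) -> int:
        return sum(t.data.size for t in self.params.values())

    def forward(
        self,
        images: np.ndarray,
        t: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        """Return (y_hat, activations) for a (m, 51, 51) image batch."""
        images = np.asarray(images, dtype=self.dtype)
        t = np.asarray(t, dtype=self.dtype)
        if images.ndim != 3 or images.shape[1:] != (CROP_SIZE, CROP_SIZE):
            raise ValueError(f"expected (m, {CROP_SIZE}, {CROP_SIZE}) images")
        if images.shape[0] != t.shape[0]:
            raise ValueError("images and t batch sizes differ")
        a = self.arch
        p = self.params
        h = Tensor(images[:, None, :, :])
        for i in range(a.n_conv_layers):
            h = conv2d(h, p[f"conv{i}_w"], p[f"conv{i}_b"], pad=1).relu()
            if i < a.n_pool_stages:
                h = maxpool2x2(h)
        h = h.reshape(images.shape[0], a.flatten_dim)
        for i in range(len(a.fc_sizes)):
            h = (h @ p[f"fc{i}_w"] + p[f"fc{i}_b"]).relu()
            if train and a.dropout > 0:
                if rng is None:
                    raise ValueError("train-mode forward needs an rng for dropout")
                keep = (rng.uniform(size=h.data.shape) >= a.dropout) / (1 - a.dropout)
                h = h * Tensor(keep.astype(self.dtype))
        acts = h @ p["act_w"] + p["act_b"]  # (m, N_k), linear
        self._hidden = h  # penultimate features, for last-layer-only penalties
        y_hat = acts @ p["w_a"] + Tensor(t) * p["w_t"] + p["b0"]
        return y_hat, acts

    # -- checkpointing -----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=self.dtype).reshape(v.data.shape)
        self.trained = True

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, arch: ArchitectureSpec | None = None) -> "ColliderCNN":
        model = cls(arch)
        with np.load(path) as f:
            model.load_state_dict({k: f[k] for k in f.files})
        return model


class Adam:
    """Adam optimizer (lr 1e-3 default, no weight decay)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            step = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.data = (p.data - step).astype(p.data.dtype, copy=False)


# ---------------------------------------------------------------------------
# Training


def _batch_losses(
    model: ColliderCNN,
    images: np.ndarray,
    t: np.ndarray,
    y: np.ndarray,
    x_prime: np.ndarray,
    config: TrainConfig,
    train: bool,
    rng: np.random.Generator | None,
    reg_buffer: list | None = None,
    constraint_factor: float = 1.0,
) -> tuple[Tensor | None, LossBreakdown]:
    y = np.asarray(y, dtype=model.dtype)
    x_prime = np.asarray(x_prime, dtype=model.dtype)
    y_hat, acts = model.forward(images, t, train=train, rng=rng)
    if config.mode == "biased" or config.mode == "ground_truth":
        ly = loss_y(y_hat, y)
        return ly, LossBreakdown(L_y=float(ly.data))
    ly = loss_y(y_hat, y)
    if train and config.clean_collider_pass and model.arch.dropout > 0:
        _, acts = model.forward(images, t, train=False)
    x_scaled = x_prime * np.asarray(config.collider_loss_scale, dtype=model.dtype)
    lx = loss_x(acts[:, 0], x_scaled)
    a_rest = acts[:, 1:]
    if config.reg_gradient == "decorrelation":
        # hinge value for the log / early stopping; decorrelation carries
        # the constraint's gradient
        hinge = loss_reg(
            a_rest.detach(), x_scaled, ridge=config.ridge,
            differentiable=False, df_correct=config.df_correct_reg,
        )
        weight = np.asarray(config.decorrelation_weight, dtype=model.dtype)
        buf_a = buf_x = None
        if reg_buffer:
            buf_a = np.concatenate([b[0] for b in reg_buffer])
            buf_x = np.concatenate([b[1] for b in reg_buffer])
        lr_ = decorrelation_penalty(a_rest, x_prime, buf_a, buf_x) * Tensor(
            weight * np.asarray(constraint_factor, dtype=model.dtype)
        )
        if reg_buffer is not None and config.decorrelation_buffer_batches > 0:
            reg_buffer.append((a_rest.data.copy(), np.asarray(x_prime, dtype=model.dtype)))
            while len(reg_buffer) > config.decorrelation_buffer_batches:
                reg_buffer.pop(0)
    else:
        hinge = lr_ = loss_reg(
            a_rest, x_scaled, ridge=config.ridge,
            differentiable=config.differentiable_reg,
            df_correct=config.df_correct_reg,
        )
    parts = LossBreakdown(float(ly.data), float(lx.data), float(hinge.data))
    if constraint_factor <= 0:
        return ly + lx, parts
    return ly + lx + lr_, parts


def _targets(matched: MatchedDataset, config: TrainConfig,
             x_prime_override: np.ndarray | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tab = matched.table
    t = tab["t"].to_numpy(dtype=float)
    if config.mode == "ground_truth":
        y = tab[config.ground_truth_target].to_numpy(dtype=float)
    else:
        y = tab["y"].to_numpy(dtype=float)
    x_prime = (
        np.asarray(x_prime_override, dtype=float)
        if x_prime_override is not None
        else tab["x_prime_std"].to_numpy(dtype=float)
    )
    return t, y, x_prime


def _crop_batch(stack: np.ndarray, idx: np.ndarray, train: bool,
                rng: np.random.Generator) -> np.ndarray:
    """Augmented (len(idx), 51, 51) batch from a (n, 100, 100) stack."""
    out = np.empty((len(idx), CROP_SIZE, CROP_SIZE))
    for j, i in enumerate(idx):
        out[j] = augment(stack[i], "train" if train else "eval", rng)
    return out


def evaluate_losses(
    model: ColliderCNN,
    matched: MatchedDataset,
    config: TrainConfig,
    x_prime_override: np.ndarray | None = None,
    batch_size: int | None = None,
    image_stack: np.ndarray | None = None,
) -> LossBreakdown:
    """Mean losses over a split using the deterministic eval path."""
    t, y, x_prime = _targets(matched, config, x_prime_override)
    stack = image_stack if image_stack is not None else matched.image_stack()
    bs = batch_size or config.batch_size
    n = len(matched)
    sums = np.zeros(3)
    count = 0
    min_m = model.arch.n_activations + 1
    for start in range(0, n, bs):
        idx = np.arange(start, min(start + bs, n))
        if config.mode == "causal" and len(idx) <= min_m:
            continue  # drop degenerate tail batch
        images = _crop_batch(stack, idx, train=False, rng=np.random.default_rng(0))
        _, parts = _batch_losses(
            model, images, t[idx], y[idx], x_prime[idx], config, False, None
        )
        sums += np.array([parts.L_y, parts.L_x, parts.L_reg]) * len(idx)
        count += len(idx)
    if count == 0:
        raise ValueError("no usable batches in evaluation split")
    mean = sums / count
    return LossBreakdown(*mean)


def train(
    model: ColliderCNN,
    matched_train: MatchedDataset,
    matched_val: MatchedDataset,
    config: TrainConfig | None = None,
    seed: int = 0,
    x_prime_train: np.ndarray | None = None,
    x_prime_val: np.ndarray | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Optimize the model with Adam and early stopping.

    Stops when the validation total loss has not improved for
    ``patience`` epochs (or at ``max_epochs``) and restores the best
    epoch's parameters.  Returns the per-epoch training log with
    columns epoch, split, L_y, L_x, L_reg, L_total.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=config.learning_rate)
    t_tr, y_tr, xp_tr = _targets(matched_train, config, x_prime_train)
    stack_tr = matched_train.image_stack()
    stack_val = matched_val.image_stack()
    n = len(matched_train)
    min_m = model.arch.n_activations + 1
    reg_buffer: list = []
    log_rows = []
    best = (np.inf, None, -1)  # (val total, state, epoch)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_sums, epoch_count = np.zeros(3), 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if config.mode == "causal" and len(idx) <= min_m:
                continue
            images = _crop_batch(stack_tr, idx, train=True, rng=rng)
            opt.zero_grad()
            ramp = (epoch - config.constraint_warmup_epochs + 1) / max(
                config.constraint_ramp_epochs, 1
            )
            loss, parts = _batch_losses(
                model, images, t_tr[idx], y_tr[idx], xp_tr[idx], config, True, rng,
                reg_buffer=reg_buffer,
                constraint_factor=float(np.clip(ramp, 0.0, 1.0)),
            )
            total_loss(parts)  # divergence check
            loss.backward()
            opt.step()
            epoch_sums += np.array([parts.L_y, parts.L_x, parts.L_reg]) * len(idx)
            epoch_count += len(idx)
        tr_mean = epoch_sums / epoch_count
        val = evaluate_losses(
            model, matched_val, config, x_prime_val, image_stack=stack_val
        )
        log_rows.append(
            dict(epoch=epoch, split="train", L_y=tr_mean[0], L_x=tr_mean[1],
                 L_reg=tr_mean[2], L_total=tr_mean.sum())
        )
        log_rows.append(
            dict(epoch=epoch, split="validation", L_y=val.L_y, L_x=val.L_x,
                 L_reg=val.L_reg, L_total=val.L_total)
        )
        if verbose:
            print(f"epoch {epoch:3d}  train {tr_mean.sum():.4f}  val {val.L_total:.4f}")
        warmed = (
            epoch >= config.constraint_warmup_epochs + config.constraint_ramp_epochs - 1
            or config.mode != "causal"
        )
        if warmed and val.L_total < best[0]:
            best = (val.L_total, model.state_dict(), epoch)
        elif warmed and epoch - best[2] >= config.patience:
            break
    if best[1] is not None:
        model.load_state_dict(best[1])
    model.trained = True
    return pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# Measurement-error calibration


def matching_measurement_error(matched: MatchedDataset) -> tuple[float, float]:
    """Oracle floor: mean squared discrepancy between the simulated
    (x, z) and the matched patch's standardized (x', z')."""
    tab = matched.table
    mse_x = float(((tab["x"] - tab["x_prime_std"]) ** 2).mean())
    mse_z = float(((tab["z"] - tab["z_prime_std"]) ** 2).mean())
    return mse_x, mse_z


def ground_truth_measurement_error(
    matched_train: MatchedDataset,
    matched_val: MatchedDataset,
    config: TrainConfig | None = None,
    seed: int = 0,
    arch: ArchitectureSpec | None = None,
) -> tuple[float, float]:
    """Inherent measurement error of the imaging pipeline.

    Trains the same CNN architecture twice with the outcome replaced by
    the ground-truth labels x and z; returns the validation MSEs, used
    to calibrate the Gaussian measurement noise of the regression
    baselines.
    """
    base = config or TrainConfig(mode="ground_truth")
    out = []
    for i, target in enumerate(("x", "z")):
        cfg = replace(base, mode="ground_truth", ground_truth_target=target)
        model = ColliderCNN(arch, seed=seed + 17 * (i + 1), dtype=cfg.dtype)
        train(model, matched_train, matched_val, cfg, seed=seed + 31 * (i + 1))
        val = evaluate_losses(model, matched_val, cfg)
        out.append(val.L_y)
    return out[0], out[1]
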