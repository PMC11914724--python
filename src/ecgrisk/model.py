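"""Discrete-time survival CNNs: model and results objects.

:class:`SurvivalCNN` wraps a small residual 1D network (signal input,
4096 x 8) or a 2D convolutional network (image input) whose K-unit sigmoid
head emits per-interval conditional hazards. ``fit`` minimizes the
discrete-time survival negative log-likelihood by mini-batch Adam with
early stopping on validation loss and returns a :class:`SurvivalFit`
results object carrying the training history, predictions and a summary
table. Vanilla-gradient saliency maps come from backpropagating the
cumulative-hazard risk score to the input.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm,
    Conv1D,
    Conv2D,
    Dense,
    GlobalAvgPool,
    InvertedBottleneck2D,
    ReLU,
    ResidualBlock1D,
    Sequential,
    sigmoid,
)
from .survival import SurvivalTargets, discrete_survival_loss, hazards_to_survival


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimizer settings for a survival network.

    ``arch`` selects the 1D residual network ("residual-1d", input
    (length, leads)) or the 2D convolutional network ("conv-2d", input
    (height, width)). ``n_intervals`` fixes the size K of the hazard head.
    Defaults are the desk-scale variants: 4 residual blocks / 4 bottleneck
    stages, ~10^5 parameters.
    """

    arch: str = "residual-1d"
    input_shape: tuple[int, ...] = (4096, 8)
    n_intervals: int = 10
    channels: tuple[int, ...] = (16, 16, 24, 32, 32)
    kernel: int = 7
    stem_kernel: int = 16
    stride: int = 4
    batch_norm: bool = True
    time_shift_augment: bool = False
    seed: int = 0
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 40
    patience: int = 6

    def __post_init__(self) -> None:
        if self.arch not in ("residual-1d", "conv-2d"):
            raise ValueError(f"unknown architecture {self.arch!r}")
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        expected = 2
        if len(self.input_shape) != expected:
            raise ValueError(
                f"{self.arch} expects a {expected}-tuple input shape, got {self.input_shape}"
            )


def _build_net(config: NetConfig) -> Sequential:
    rng = np.random.default_rng(config.seed)
    ch = config.channels
    if config.arch == "residual-1d":
        n_leads = config.input_shape[1]
        layers = [Conv1D(n_leads, ch[0], config.stem_kernel, config.stride, rng)]
        if config.batch_norm:
            layers.append(BatchNorm(ch[0]))
        layers.append(ReLU())
        for cin, cout in zip(ch[:-1], ch[1:]):
            layers.append(ResidualBlock1D(cin, cout, config.kernel, config.stride, rng,
                                          batch_norm=config.batch_norm))
        layers += [GlobalAvgPool(), Dense(ch[-1], config.n_intervals, rng)]
    else:
        layers = [Conv2D(1, ch[0], 3, 2, rng), BatchNorm(ch[0]), ReLU()]
        for cin, cout in zip(ch[:-1], ch[1:]):
            layers.append(InvertedBottleneck2D(cin, cout, 2, rng))
        layers += [GlobalAvgPool(), Dense(ch[-1], config.n_intervals, rng)]
    # zero-init the hazard head: a fresh model predicts h = 0.5 everywhere,
    # which also keeps the first optimizer steps well-conditioned
    layers[-1].w.value[...] = 0.0
    return Sequential(layers)


class SurvivalCNN:
    """A survival network with a K-interval hazard head.

    Construction is deterministic given the config (including its seed).
    Use :meth:`fit` to train; prediction methods work on any compatible
    batch, trained or not.
    """

    def __init__(self, config: NetConfig):
        self.config = config
        self.net = _build_net(config)

    # -- plumbing -----------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.net.params()))

    def _as_batch(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.config.arch == "conv-2d":
            if x.ndim == 2:
                x = x[None]
            if x.ndim == 3:
                x = x[..., None]  # add channel axis
        elif x.ndim == 2:
            x = x[None]
        return x

    def _logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(self._as_batch(x), train=train)

    # -- prediction ---------------------------------------------------------

    def predict_hazards(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-interval hazards in (0, 1), shape (n, K)."""
        x = self._as_batch(x)
        out = [sigmoid(self._logits(x[i: i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.vstack(out)

    def predict_risk(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Cumulative-hazard risk score -sum_j ln(1 - h_j), shape (n,)."""
        _, risk = hazards_to_survival(self.predict_hazards(x, batch_size))
        return risk

    def predict_survival(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Survival curves S_k, shape (n, K), non-increasing along k."""
        surv, _ = hazards_to_survival(self.predict_hazards(x, batch_size))
        return surv

    # -- training -----------------------------------------------------------

    def fit(
        self,
        x_train: np.ndarray,
        targets_train: SurvivalTargets,
        x_val: np.ndarray,
        targets_val: SurvivalTargets,
    ) -> "SurvivalFit":
        """Train by mini-batch Adam with early stopping on validation loss.

        The parameters from the best validation epoch are restored before
        returning. Deterministic given the config seed up to floating-point
        reduction order.
        """
        cfg = self.config
        x_train = self._as_batch(x_train)
        x_val = self._as_batch(x_val)
        if len(x_train) == 0 or len(x_val) == 0:
            raise ValueError("train and validation splits must be non-empty")
        params = self.net.params()
        opt = Adam(params, lr=cfg.lr)
        rng = np.random.default_rng(cfg.seed + 1)

        def eval_loss(x: np.ndarray, tgt: SurvivalTargets) -> float:
            losses, counts = [], []
            for i in range(0, len(x), 64):
                h = sigmoid(self.net.forward(x[i: i + 64]))
                sub = SurvivalTargets(tgt.y[i: i + 64], tgt.mask[i: i + 64])
                losses.append(discrete_survival_loss(h, sub) * len(h))
                counts.append(len(h))
            return float(np.sum(losses) / np.sum(counts))

        history: list[dict] = []
        best_val = eval_loss(x_val, targets_val)
        initial_val = best_val
        best_params = [p.value.copy() for p in params]
        best_epoch = 0
        stall = 0
        n = len(x_train)
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for i in range(0, n, cfg.batch_size):
                idx = order[i: i + cfg.batch_size]
                xb = x_train[idx]
                if cfg.time_shift_augment and cfg.arch == "residual-1d":
                    # circular time shift: rate/morphology preserved, phase
                    # decorrelated — cheap regularization for small cohorts
                    xb = xb.copy()
                    for j, k in enumerate(rng.integers(0, xb.shape[1], size=len(xb))):
                        xb[j] = np.roll(xb[j], int(k), axis=0)
                yb = targets_train.y[idx]
                mb = targets_train.mask[idx]
                opt.zero_grad()
                z = self.net.forward(xb, train=True)
                h = sigmoid(z)
                loss = discrete_survival_loss(h, SurvivalTargets(yb, mb))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (loss={loss})"
                    )
                self.net.backward(mb * (h - yb) / len(xb))
                opt.step()
                epoch_loss += loss * len(xb)
            val_loss = eval_loss(x_val, targets_val)
            history.append({"epoch": epoch, "train_loss": epoch_loss / n,
                            "val_loss": val_loss})
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_epoch = epoch
                best_params = [p.value.copy() for p in params]
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        for p, v in zip(params, best_params):
            p.value[...] = v
        return SurvivalFit(model=self, history=history, best_epoch=best_epoch,
                           best_val_loss=best_val, initial_val_loss=initial_val)


    # -- persistence: parameters as npz, config as JSON sidecar -------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.net.params())}
        np.savez(path.with_suffix(".npz"), **arrays)
        cfg = dataclasses.asdict(self.config)
        cfg["input_shape"] = list(cfg["input_shape"])
        cfg["channels"] = list(cfg["channels"])
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SurvivalCNN":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        cfg["input_shape"] = tuple(cfg["input_shape"])
        cfg["channels"] = tuple(cfg["channels"])
        model = cls(NetConfig(**cfg))
        with np.load(path.with_suffix(".npz")) as data:
            for i, p in enumerate(model.net.params()):
                p.value[...] = data[f"p{i}"]
        return model


def build_model(config: NetConfig) -> SurvivalCNN:
    """Construct an untrained survival network from its config."""
    return SurvivalCNN(config)


@dataclass
class SurvivalFit:
    """Results of :meth:`SurvivalCNN.fit`."""

    model: SurvivalCNN
    history: list[dict]
    best_epoch: int
    best_val_loss: float
    initial_val_loss: float

    def predict_risk(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_risk(x)

    def predict_hazards(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_hazards(x)

    def predict_survival(self, x: np.ndarray) -> np.ndarray:
        return self.model.predict_survival(x)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Discrete-time survival CNN fit",
            "==============================",
            f"architecture     {cfg.arch}",
            f"input shape      {cfg.input_shape}",
            f"intervals (K)    {cfg.n_intervals}",
            f"parameters       {self.model.n_parameters()}",
            f"epochs run       {len(self.history)}",
            f"best epoch       {self.best_epoch}",
            f"initial val loss {self.initial_val_loss:.4f}",
            f"best val loss    {self.best_val_loss:.4f}",
        ]
        return "\n".join(lines)


def train_model(
    model: SurvivalCNN,
    x_train: np.ndarray,
    targets_train: SurvivalTargets,
    x_val: np.ndarray,
    targets_val: SurvivalTargets,
) -> SurvivalFit:
    """Functional alias for :meth:`SurvivalCNN.fit`."""
    return model.fit(x_train, targets_train, x_val, targets_val)


def saliency_map(model: SurvivalCNN, x: np.ndarray) -> np.ndarray:
    """Vanilla-gradient saliency of the risk score.

    Absolute gradient of the cumulative-hazard risk -sum_j ln(1 - h_j)
    with respect to the input, max-reduced over channels. Because
    -ln(1 - sigmoid(z)) = softplus(z), the upstream gradient at the head
    is simply the hazard vector itself. Returns one map per record with
    the input's spatial shape.
    """
    xb = model._as_batch(x)
    z = model.net.forward(xb)
    for p in model.net.params():
        p.grad[...] = 0.0
    dx = model.net.backward(sigmoid(z))
    sal = np.abs(dx).max(axis=-1)
    single = (np.asarray(x).ndim < xb.ndim if model.config.arch == "residual-1d"
              else np.asarray(x).ndim <= 2)
    return sal[0] if single and sal.shape[0] == 1 else sal
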