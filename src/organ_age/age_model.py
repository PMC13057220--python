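"""Uncertainty-aware convolutional age regression.

A small residual CNN predicts, for each organ image, a Gaussian over
chronological age: the mean mu(x) is the age estimate and the predicted
log standard deviation log sigma(x) carries input-dependent (heteroscedastic)
uncertainty.  Parameters are fitted by minimizing the Gaussian negative
log-likelihood

    L = (1/N) * sum_i [ (y_i - mu(x_i))^2 / (2 sigma(x_i)^2) + log sigma(x_i) ]

on healthy subjects only, where chronological age approximates biological
age; inference then runs on the full cohort and deviations from the
identity line are read as accelerated or decelerated organ aging.

Follows the statsmodels convention: :class:`AgeModel` is built from
configuration, ``fit`` returns an :class:`AgeFitResults` carrying the
trained weights, loss history and prediction/evaluation methods.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import nn
from .config import ORGAN_EXCLUSIONS, ConfigurationError, DataError, TrainConfig
from .preprocess import OrganImage


@dataclass
class HeteroscedasticPrediction:
    """Predicted Gaussian over age for one image: mean and log-SD in years."""

    mu: float
    log_sigma: float


def nll_loss(preds, labels) -> float:
    """Mean Gaussian negative log-likelihood (constant term dropped).

    ``(1/N) sum_i [(y_i - mu_i)^2 / (2 sigma_i^2) + log sigma_i]`` for
    predictions in years.
    """
    preds = list(preds)
    labels = np.asarray(list(labels), dtype=np.float64)
    if len(preds) == 0 or len(preds) != labels.size:
        raise DataError("predictions and labels must be nonempty and aligned")
    mu = np.array([p.mu for p in preds], dtype=np.float64)
    log_sigma = np.array([p.log_sigma for p in preds], dtype=np.float64)
    sigma2 = np.exp(2.0 * log_sigma)
    return float(np.mean((labels - mu) ** 2 / (2.0 * sigma2) + log_sigma))


def split_healthy(cohort: pd.DataFrame, outcome_exclusions,
                  ratio: float = 0.8, seed: int = 0,
                  ) -> tuple[list[str], list[str]]:
    """Split the healthy subjects into train/test identifier lists.

    A subject is healthy for the target organ iff none of the excluded
    outcomes was diagnosed before imaging.  The remainder is shuffled
    deterministically and split ``ratio / (1 - ratio)``.
    """
    if not 0.0 < ratio < 1.0:
        raise ConfigurationError("split ratio must be in (0, 1)")
    healthy = np.ones(len(cohort), dtype=bool)
    for outcome in outcome_exclusions:
        col = f"age_{outcome}"
        if col not in cohort.columns:
            continue
        diag = cohort[col].to_numpy()
        healthy &= ~(pd.notna(diag) & (diag < cohort["ca_at_imaging"].to_numpy()))
    ids = cohort.loc[healthy, "subject_id"].tolist()
    if not ids:
        raise DataError("no healthy subjects left after exclusions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(round(ratio * len(ids)))
    train = [ids[i] for i in order[:n_train]]
    test = [ids[i] for i in order[n_train:]]
    return train, test


def healthy_exclusions_for(organ: str) -> tuple[str, ...]:
    """Outcomes whose pre-imaging diagnosis disqualifies training subjects."""
    return ORGAN_EXCLUSIONS.get(organ, ())


def evaluate_predictions(preds, labels) -> dict[str, float]:
    """MAE (+SD of absolute errors) and Pearson r of predicted vs true age."""
    mu = np.asarray([p.mu if isinstance(p, HeteroscedasticPrediction) else p
                     for p in preds], dtype=np.float64)
    y = np.asarray(list(labels), dtype=np.float64)
    if mu.size < 3:
        raise DataError("need at least 3 predictions to evaluate")
    if np.ptp(y) == 0:
        raise DataError("zero-variance labels: Pearson r undefined")
    err = np.abs(mu - y)
    r, p = stats.pearsonr(mu, y)
    return {"mae": float(err.mean()), "mae_sd": float(err.std(ddof=1)),
            "pearson_r": float(r), "p_value": float(p)}


def _stack_images(images) -> np.ndarray:
    """Stack OrganImages / arrays into a (n, channels, *spatial) batch."""
    arrays = []
    for img in images:
        x = img.voxels if isinstance(img, OrganImage) else np.asarray(img)
        if isinstance(img, OrganImage) and not img.has_channels:
            x = x[None]
        elif not isinstance(img, OrganImage) and x.ndim in (2, 3) and x.shape[0] not in (1, 3):
            x = x[None]
        arrays.append(np.asarray(x, dtype=nn.DTYPE))
    batch = np.stack(arrays)
    if batch.ndim == 4 and batch.shape[1] not in (1, 3):
        # (n, z, y, x) single-channel volumes
        batch = batch[:, None]
    return batch


class AgeNetwork:
    """Residual CNN: per-block conv + instance norm + skip, GAP, 2-unit head."""

    def __init__(self, dims: int, in_channels: int,
                 channels: tuple[int, ...] = (8, 16, 32), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.dims = dims
        self.in_channels = in_channels
        self.channels = tuple(channels)
        self.blocks = []
        c_prev = in_channels
        for c in self.channels:
            self.blocks.append(nn.ResidualBlock(c_prev, c, dims, rng))
            c_prev = c
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Dense(c_prev, 2, rng)
        self.net = nn.Sequential(self.blocks + [self.gap, self.head])

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.net.params]

    def load_state(self, state) -> None:
        for p, s in zip(self.net.params, state):
            p[...] = s


class AgeModel:
    """Heteroscedastic age regressor for one organ.

    Parameters
    ----------
    dims : 2 for the fundus path, 3 for volumetric organs.
    in_channels : image channels (1 for MRI-like volumes, 3 for fundus).
    config : training hyperparameters (epochs, batch size, Adam step size,
        log-sigma clamp in log-years, seed).
    """

    def __init__(self, dims: int = 3, in_channels: int = 1,
                 config: TrainConfig | None = None):
        if dims not in (2, 3):
            raise ConfigurationError("dims must be 2 or 3")
        self.dims = dims
        self.in_channels = in_channels
        self.config = config or TrainConfig()
        self.config.validate()

    def fit(self, images, ages) -> "AgeFitResults":
        """Train on healthy images/ages; returns results with loss history.

        Ages are standardized internally; the network predicts in
        standardized units and results convert back to years.
        """
        cfg = self.config
        x = _stack_images(images)
        y = np.asarray(list(ages), dtype=np.float64)
        if x.shape[0] != y.size or y.size == 0:
            raise DataError("images and ages must be nonempty and aligned")
        if x.ndim - 2 != self.dims or x.shape[1] != self.in_channels:
            raise DataError(
                f"batch shape {x.shape} incompatible with a {self.dims}D "
                f"{self.in_channels}-channel architecture")
        y_mean, y_sd = float(y.mean()), float(y.std())
        if y_sd == 0:
            y_sd = 1.0
        ys = ((y - y_mean) / y_sd).astype(np.float64)

        net = AgeNetwork(self.dims, self.in_channels, cfg.channels, seed=cfg.seed)
        opt = nn.Adam(net.net.params, net.net.grads, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        n = x.shape[0]
        history: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                out = net.forward(x[idx])
                mu, log_sigma = out[:, 0].astype(np.float64), out[:, 1].astype(np.float64)
                r = mu - ys[idx]
                inv_var = np.exp(-2.0 * log_sigma)
                batch_nll = float(np.mean(0.5 * r * r * inv_var + log_sigma))
                m = idx.size
                grad = np.empty_like(out)
                grad[:, 0] = (r * inv_var / m).astype(nn.DTYPE)
                grad[:, 1] = ((1.0 - r * r * inv_var) / m).astype(nn.DTYPE)
                net.net.zero_grad()
                net.backward(grad)
                opt.step()
                epoch_loss += batch_nll * m
            # epoch NLL reported in years via the affine change of variable
            history.append(epoch_loss / n + np.log(y_sd))
        return AgeFitResults(network=net, config=cfg, label_mean=y_mean,
                             label_sd=y_sd, loss_history=history)


class AgeFitResults:
    """Trained age regressor: predictions, evaluation, persistence."""

    def __init__(self, network: AgeNetwork, config: TrainConfig,
                 label_mean: float, label_sd: float, loss_history: list[float]):
        self.network = network
        self.config = config
        self.label_mean = label_mean
        self.label_sd = label_sd
        self.loss_history = list(loss_history)

    def _forward_batches(self, x: np.ndarray, batch: int = 32) -> np.ndarray:
        outs = [self.network.forward(x[i:i + batch])
                for i in range(0, x.shape[0], batch)]
        return np.concatenate(outs, axis=0)

    def predict(self, images) -> list[HeteroscedasticPrediction]:
        """One clamped Gaussian prediction per image, order preserving."""
        x = _stack_images(images)
        if x.ndim - 2 != self.network.dims or x.shape[1] != self.network.in_channels:
            raise DataError(f"batch shape {x.shape} does not match the "
                            "trained architecture")
        out = self._forward_batches(x).astype(np.float64)
        mu = out[:, 0] * self.label_sd + self.label_mean
        lo, hi = self.config.sigma_clamp
        log_sigma = np.clip(out[:, 1] + np.log(self.label_sd), lo, hi)
        return [HeteroscedasticPrediction(float(m), float(s))
                for m, s in zip(mu, log_sigma)]

    def predict_frame(self, images, subject_ids, organ: str) -> pd.DataFrame:
        preds = self.predict(images)
        return pd.DataFrame({
            "subject_id": list(subject_ids),
            "organ": organ,
            "mu": [p.mu for p in preds],
            "log_sigma": [p.log_sigma for p in preds],
        })

    def evaluate(self, images, ages) -> dict[str, float]:
        return evaluate_predictions(self.predict(images), ages)

    def summary(self) -> str:
        lines = [
            "Heteroscedastic age regression",
            f"  architecture : {self.network.dims}D, blocks {self.network.channels}",
            f"  epochs       : {len(self.loss_history)}",
            f"  label mean/sd: {self.label_mean:.2f} / {self.label_sd:.2f} years",
        ]
        if self.loss_history:
            lines.append(f"  NLL first/last epoch: {self.loss_history[0]:.4f} / "
                         f"{self.loss_history[-1]:.4f}")
        return "\n".join(lines)

    def save(self, weights_path, arch_path) -> None:
        """Weights as .npz plus a JSON architecture sidecar."""
        state = {f"p{i}": p for i, p in enumerate(self.network.net.params)}
        np.savez(weights_path, **state)
        doc = {
            "dims": self.network.dims,
            "in_channels": self.network.in_channels,
            "channels": list(self.network.channels),
            "label_mean": self.label_mean,
            "label_sd": self.label_sd,
            "sigma_clamp": list(self.config.sigma_clamp),
            "loss_history": self.loss_history,
        }
        Path(arch_path).write_text(json.dumps(doc, indent=1))

    @staticmethod
    def load(weights_path, arch_path, config: TrainConfig | None = None,
             ) -> "AgeFitResults":
        doc = json.loads(Path(arch_path).read_text())
        cfg = config or TrainConfig()
        cfg.sigma_clamp = tuple(doc["sigma_clamp"])
        net = AgeNetwork(doc["dims"], doc["in_channels"], tuple(doc["channels"]))
        with np.load(weights_path) as data:
            net.load_state([data[f"p{i}"] for i in range(len(net.net.params))])
        return AgeFitResults(network=net, config=cfg,
                             label_mean=doc["label_mean"],
                             label_sd=doc["label_sd"],
                             loss_history=doc["loss_history"])
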