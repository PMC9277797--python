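"""Variational auto-encoder fusing coverage and composition features.

The encoder maps the 64-dim feature vector (32 coverage + 32 composition)
through two 128-unit hidden layers (batch normalisation, LeakyReLU, dropout
p=0.1) to an 8-dim latent Gaussian: a LeakyReLU head for the mean mu and a
softplus head for the standard deviation sigma. The decoder mirrors the
encoder and reconstructs the input through a final LeakyReLU. Training
minimises

    total = w_cov * E_cov + w_com * E_com + w_kld * D_KL

where E_cov / E_com are summed squared reconstruction errors over the
coverage / composition blocks and D_KL regularises the latent towards the
prior. Two D_KL variants are supported (see :func:`kld`). After training
only the deterministic latent means are used for clustering.

Implemented directly on numpy with hand-written backpropagation and an
Adam optimiser; training is CPU-only and fully deterministic under a seed.
"""

from __future__ import annotations

import logging
import math
import pickle
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

COV_SLICE = slice(0, 32)
COM_SLICE = slice(32, 64)
SIGMA_FLOOR = 1e-6


@dataclass
class VAEConfig:
    """Architecture and training hyper-parameters."""

    input_dim: int = 64
    hidden_units: int = 128
    latent_dim: int = 8
    dropout_p: float = 0.1
    # Negative slope for every LeakyReLU, including the latent-mean head.
    # A substantial slope keeps the sign structure of negative latent
    # coordinates, which the downstream cosine-distance clustering relies on;
    # a near-zero slope folds all reads into one orthant corner and lets the
    # dominant species collapse onto the origin.
    leaky_slope: float = 0.3
    w_cov: float = 0.1
    w_com: float = 1.0
    w_kld: float = 1.0 / 500.0
    kld_variant: str = "as_printed"  # or "standard"
    epochs: int = 200
    batch_size: int = 10240
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.w_cov, self.w_com, self.w_kld) <= 0:
            raise ValueError("loss weights must be positive")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.kld_variant not in ("as_printed", "standard"):
            raise ValueError(f"unknown kld_variant {self.kld_variant!r}")


def reconstruction_error(v_in: np.ndarray, v_out: np.ndarray) -> tuple[float, float]:
    """Summed squared error split into (coverage, composition) blocks."""
    v_in = np.asarray(v_in, dtype=np.float64)
    v_out = np.asarray(v_out, dtype=np.float64)
    if v_in.shape != v_out.shape or v_in.shape[-1] != 64:
        raise ValueError(f"expected matching 64-dim vectors, got {v_in.shape} vs {v_out.shape}")
    diff2 = (v_in - v_out) ** 2
    return float(diff2[..., COV_SLICE].sum()), float(diff2[..., COM_SLICE].sum())


def kld(mu: np.ndarray, sigma: np.ndarray, variant: str = "as_printed") -> float:
    """Kullback-Leibler regulariser of the latent Gaussian.

    ``as_printed`` evaluates -sum(0.5 * (1 + ln(sigma) - mu^2 - sigma)),
    which is zero at mu=0, sigma=1 and is the form used by default.
    ``standard`` evaluates the textbook Gaussian KL against N(0, I),
    -sum(0.5 * (1 + ln(sigma^2) - mu^2 - sigma^2)).
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if (sigma <= 0).any():
        raise ValueError("sigma must be strictly positive")
    if variant == "as_printed":
        return float(-np.sum(0.5 * (1.0 + np.log(sigma) - mu**2 - sigma)))
    if variant == "standard":
        return float(-np.sum(0.5 * (1.0 + 2.0 * np.log(sigma) - mu**2 - sigma**2)))
    raise ValueError(f"unknown kld variant {variant!r}")


def total_loss(
    batch_in: np.ndarray,
    batch_out: np.ndarray,
    mus: np.ndarray,
    sigmas: np.ndarray,
    config: VAEConfig,
) -> float:
    """Batch-averaged weighted loss: w_cov*E_cov + w_com*E_com + w_kld*D_KL."""
    batch_in = np.atleast_2d(np.asarray(batch_in, dtype=np.float64))
    batch_out = np.atleast_2d(np.asarray(batch_out, dtype=np.float64))
    mus = np.atleast_2d(np.asarray(mus, dtype=np.float64))
    sigmas = np.atleast_2d(np.asarray(sigmas, dtype=np.float64))
    if not (batch_in.shape == batch_out.shape and len(batch_in) == len(mus) == len(sigmas)):
        raise ValueError("batch shapes disagree")
    n = len(batch_in)
    e_cov, e_com = reconstruction_error(batch_in, batch_out)
    d_kl = kld(mus, sigmas, variant=config.kld_variant)
    return (config.w_cov * e_cov + config.w_com * e_com + config.w_kld * d_kl) / n


# ---------------------------------------------------------------------------
# Layers (forward + manual backward)
# ---------------------------------------------------------------------------


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.standard_normal((n_in, n_out)) * math.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: Optional[np.ndarray] = None

    params = property(lambda self: [(self.W, self.gW), (self.b, self.gb)])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ g
        self.gb += g.sum(axis=0)
        return g @ self.W.T


class _BatchNorm:
    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.ggamma = np.zeros(dim)
        self.gbeta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    params = property(lambda self: [(self.gamma, self.ggamma), (self.beta, self.gbeta)])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std, x - mean, var)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std, xc, var = self._cache
        n = g.shape[0]
        self.ggamma += (g * xhat).sum(axis=0)
        self.gbeta += g.sum(axis=0)
        dxhat = g * self.gamma
        dvar = np.sum(dxhat * xc, axis=0) * (-0.5) * inv_std**3
        dmean = -np.sum(dxhat, axis=0) * inv_std + dvar * np.mean(-2.0 * xc, axis=0)
        return dxhat * inv_std + dvar * 2.0 * xc / n + dmean / n


class _LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask: Optional[np.ndarray] = None

    params = property(lambda self: [])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, self.slope * g)


class _Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    params = property(lambda self: [])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        return g * self._mask


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class _Stack:
    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class VAE:
    """Encoder 64 -> 128 -> 128 -> (mu: 8, sigma: 8); mirrored decoder."""

    def __init__(self, config: VAEConfig, rng: np.random.Generator):
        self.config = config
        c = config
        self.rng = rng
        self.encoder = _Stack(
            [
                _Linear(c.input_dim, c.hidden_units, rng),
                _BatchNorm(c.hidden_units),
                _LeakyReLU(c.leaky_slope),
                _Dropout(c.dropout_p, rng),
                _Linear(c.hidden_units, c.hidden_units, rng),
                _BatchNorm(c.hidden_units),
                _LeakyReLU(c.leaky_slope),
                _Dropout(c.dropout_p, rng),
            ]
        )
        self.mu_head = _Linear(c.hidden_units, c.latent_dim, rng)
        self.mu_act = _LeakyReLU(c.leaky_slope)
        self.sigma_head = _Linear(c.hidden_units, c.latent_dim, rng)
        self.decoder = _Stack(
            [
                _Linear(c.latent_dim, c.hidden_units, rng),
                _BatchNorm(c.hidden_units),
                _LeakyReLU(c.leaky_slope),
                _Dropout(c.dropout_p, rng),
                _Linear(c.hidden_units, c.hidden_units, rng),
                _BatchNorm(c.hidden_units),
                _LeakyReLU(c.leaky_slope),
                _Dropout(c.dropout_p, rng),
                _Linear(c.hidden_units, c.input_dim, rng),
                _LeakyReLU(c.leaky_slope),
            ]
        )

    @property
    def params(self):
        return self.encoder.params + self.mu_head.params + self.sigma_head.params + self.decoder.params

    def encode_mu(self, x: np.ndarray) -> np.ndarray:
        """Deterministic latent means: inference mode, no dropout, no sampling."""
        h = self.encoder.forward(x, train=False)
        return self.mu_act.forward(self.mu_head.forward(h, train=False), train=False)

    # --- training step -----------------------------------------------------

    def _forward_train(self, x: np.ndarray):
        h = self.encoder.forward(x, train=True)
        mu = self.mu_act.forward(self.mu_head.forward(h, train=True), train=True)
        sig_pre = self.sigma_head.forward(h, train=True)
        sigma = _softplus(sig_pre) + SIGMA_FLOOR
        eps = self.rng.standard_normal(mu.shape)
        z = mu + sigma * eps
        out = self.decoder.forward(z, train=True)
        return h, mu, sig_pre, sigma, eps, z, out

    def _zero_grads(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def train_step(self, x: np.ndarray) -> tuple[float, float, float, float]:
        """One forward/backward pass; returns per-batch (e_cov, e_com, kld, total)."""
        c = self.config
        n = x.shape[0]
        self._zero_grads()
        _, mu, sig_pre, sigma, eps, _, out = self._forward_train(x)

        diff = out - x
        e_cov = float((diff[:, COV_SLICE] ** 2).sum())
        e_com = float((diff[:, COM_SLICE] ** 2).sum())
        d_kl = kld(mu, sigma, variant=c.kld_variant)
        total = (c.w_cov * e_cov + c.w_com * e_com + c.w_kld * d_kl) / n

        # d total / d out
        w_block = np.empty(c.input_dim)
        w_block[COV_SLICE] = c.w_cov
        w_block[COM_SLICE] = c.w_com
        g_out = 2.0 * w_block * diff / n
        g_z = self.decoder.backward(g_out)

        # reparameterisation: z = mu + sigma * eps
        g_mu = g_z.copy()
        g_sigma = g_z * eps
        # direct KL contributions
        if c.kld_variant == "as_printed":
            g_mu += c.w_kld * mu / n
            g_sigma += c.w_kld * 0.5 * (1.0 - 1.0 / sigma) / n
        else:
            g_mu += c.w_kld * mu / n
            g_sigma += c.w_kld * (sigma - 1.0 / sigma) / n

        g_sig_pre = g_sigma * np.exp(-np.logaddexp(0.0, -sig_pre))  # softplus' = sigmoid, overflow-safe
        g_h = self.sigma_head.backward(g_sig_pre)
        g_h += self.mu_head.backward(self.mu_act.backward(g_mu))
        self.encoder.backward(g_h)
        return e_cov / n, e_com / n, d_kl / n, total


class _Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def train_vae(features: np.ndarray, config: Optional[VAEConfig] = None) -> tuple[VAE, list[dict]]:
    """Train the auto-encoder; returns the model and the per-epoch loss trace.

    The trace rows hold batch-averaged ``e_cov``, ``e_com``, ``kld`` and
    ``total``. Identical seed and data give an identical trace.
    """
    config = config or VAEConfig()
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != config.input_dim:
        raise ValueError(f"expected n x {config.input_dim} feature matrix, got {features.shape}")
    if len(features) == 0:
        raise ValueError("no feature rows to train on")
    rng = np.random.default_rng(config.seed)
    model = VAE(config, rng)
    opt = _Adam(model.params, lr=config.learning_rate)
    n = len(features)
    trace: list[dict] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, config.batch_size):
            batch = features[order[start : start + config.batch_size]]
            if len(batch) < 2:  # batch norm needs at least 2 samples
                continue
            terms = model.train_step(batch)
            if not all(math.isfinite(t) for t in terms):
                names = ("e_cov", "e_com", "kld", "total")
                bad = [nm for nm, t in zip(names, terms) if not math.isfinite(t)]
                raise FloatingPointError(f"non-finite loss at epoch {epoch}: {', '.join(bad)}")
            opt.step()
            sums += np.array(terms)
            n_batches += 1
        if n_batches == 0:
            raise ValueError("dataset too small for one training batch")
        mean = sums / n_batches
        trace.append({"epoch": epoch, "e_cov": mean[0], "e_com": mean[1], "kld": mean[2], "total": mean[3]})
    logger.info("VAE trained %d epochs: total loss %.4f -> %.4f", config.epochs, trace[0]["total"], trace[-1]["total"])
    return model, trace


def encode(features: np.ndarray, model: VAE, batch_size: int = 65536) -> np.ndarray:
    """Deterministic n x latent_dim matrix of latent means, row-aligned with input."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != model.config.input_dim:
        raise ValueError(f"expected n x {model.config.input_dim} matrix, got {features.shape}")
    outs = [model.encode_mu(features[s : s + batch_size]) for s in range(0, len(features), batch_size)]
    return np.vstack(outs)


def save_checkpoint(model: VAE, trace: list[dict], path) -> None:
    with open(path, "wb") as fh:
        pickle.dump({"format_version": 1, "config": model.config, "model": model, "trace": trace}, fh)


def load_checkpoint(path) -> tuple[VAE, list[dict]]:
    with open(path, "rb") as fh:
        blob = pickle.load(fh)
    if blob.get("format_version") != 1:
        raise ValueError(f"unsupported checkpoint version in {path}")
    return blob["model"], blob["trace"]
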