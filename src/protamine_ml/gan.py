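"""A small fully-connected GAN for tabular feature rows, in NumPy.

The generator maps Gaussian noise through two 128-unit hidden layers to a
feature-width output; the discriminator mirrors it with a single sigmoid
output.  Hidden layers use LeakyReLU (alpha = 0.01) followed by dropout
(rate = 0.5, training time only); both networks are optimised with Adam
(learning rate 2e-4, beta1 = 0.5) against the standard non-saturating
binary cross-entropy objective.  The matrices involved are tiny (a few
hundred rows, 30 features), so explicit forward/backward passes in NumPy
train in seconds on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GANConfig:
    """Architecture and optimisation settings for the tabular GAN.

    Defaults: generator 128/128/``out_dim``, discriminator 128/128/1,
    LeakyReLU alpha 0.01, dropout 0.5, Adam(2e-4, beta1=0.5), 1000 epochs
    of batch-30 minibatches, 100-dimensional noise.
    """

    out_dim: int = 30
    noise_dim: int = 100
    hidden: tuple[int, int] = (128, 128)
    leaky_alpha: float = 0.01
    dropout: float = 0.5
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    epochs: int = 1000
    batch_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.out_dim < 1 or self.noise_dim < 1:
            raise ValueError("out_dim and noise_dim must be >= 1")
        for name in ("dropout", "learning_rate"):
            value = getattr(self, name)
            if not (0.0 < value < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


class GanTrainingError(RuntimeError):
    """Raised when a loss becomes non-finite during training."""


class _MLP:
    """Dense stack with LeakyReLU + dropout hidden layers.

    ``sigmoid_out`` selects the discriminator head; the generator output is
    linear (samples are clipped to the feature range afterwards).
    """

    def __init__(
        self,
        widths: list[int],
        alpha: float,
        dropout: float,
        rng: np.random.Generator,
        sigmoid_out: bool,
    ) -> None:
        self.alpha = alpha
        self.dropout = dropout
        self.sigmoid_out = sigmoid_out
        self.weights = [
            rng.normal(0.0, 0.02, size=(fan_in, fan_out))
            for fan_in, fan_out in zip(widths[:-1], widths[1:])
        ]
        self.biases = [np.zeros(w) for w in widths[1:]]
        self._cache: list[tuple] = []
        # Adam state
        self._step = 0
        self._m = [np.zeros_like(w) for w in self.weights] + [
            np.zeros_like(b) for b in self.biases
        ]
        self._v = [np.zeros_like(p) for p in self._m]

    def forward(
        self, x: np.ndarray, train: bool, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        self._cache = []
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = x @ w + b
            if i < n_layers - 1:
                act = np.where(z > 0, z, self.alpha * z)
                if train:
                    assert rng is not None
                    mask = (rng.random(act.shape) >= self.dropout) / (1 - self.dropout)
                    out = act * mask
                else:
                    mask = None
                    out = act
            else:
                mask = None
                out = z  # logits / linear output
            self._cache.append((x, z, mask))
            x = out
        return x

    def backward(self, grad_out: np.ndarray) -> tuple[list, list, np.ndarray]:
        """Gradients of all parameters plus the gradient w.r.t. the input.

        ``grad_out`` is d(loss)/d(final pre-activation output); for the
        sigmoid discriminator head pass d(loss)/d(logit) directly.
        """
        grad_w = [None] * len(self.weights)
        grad_b = [None] * len(self.biases)
        grad = grad_out
        n_layers = len(self.weights)
        for i in reversed(range(n_layers)):
            x, z, mask = self._cache[i]
            if i < n_layers - 1:
                if mask is not None:
                    grad = grad * mask
                grad = grad * np.where(z > 0, 1.0, self.alpha)
            grad_w[i] = x.T @ grad
            grad_b[i] = grad.sum(axis=0)
            grad = grad @ self.weights[i].T
        return grad_w, grad_b, grad

    def adam_step(
        self, grad_w: list, grad_b: list, lr: float, beta1: float, beta2: float
    ) -> None:
        self._step += 1
        params = self.weights + self.biases
        grads = grad_w + grad_b
        eps = 1e-8
        t = self._step
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)


@dataclass
class TrainedGenerator:
    """Fitted generator network plus its loss traces and config echo."""

    network: _MLP
    config: GANConfig
    d_loss: list[float] = field(default_factory=list)
    g_loss: list[float] = field(default_factory=list)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce(p: np.ndarray, target: float) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    if target == 1.0:
        return float(-np.mean(np.log(p)))
    return float(-np.mean(np.log(1.0 - p)))


def gan_train(minority_features: np.ndarray, config: GANConfig) -> TrainedGenerator:
    """Train the GAN on the minority-class feature rows.

    One epoch is one shuffled pass of batch-size minibatches over the real
    rows; per minibatch the discriminator is updated once on real (target 1)
    versus freshly generated (target 0) rows, then the generator is updated
    once through the frozen discriminator with target 1.  Dropout is active
    only in the network currently being updated.  Aborts with
    :class:`GanTrainingError` if a loss goes non-finite.
    """
    real = np.asarray(minority_features, dtype=float)
    if real.ndim != 2 or real.shape[0] == 0:
        raise ValueError("minority_features must be a non-empty 2-D array")
    if real.shape[1] != config.out_dim:
        raise ValueError(
            f"feature width {real.shape[1]} != config.out_dim {config.out_dim}"
        )
    rng = np.random.default_rng(config.seed)
    gen = _MLP(
        [config.noise_dim, *config.hidden, config.out_dim],
        config.leaky_alpha, config.dropout, rng, sigmoid_out=False,
    )
    disc = _MLP(
        [config.out_dim, *config.hidden, 1],
        config.leaky_alpha, config.dropout, rng, sigmoid_out=True,
    )
    n = real.shape[0]
    d_trace: list[float] = []
    g_trace: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        d_losses: list[float] = []
        g_losses: list[float] = []
        for start in range(0, n, config.batch_size):
            batch = real[order[start : start + config.batch_size]]
            m = batch.shape[0]

            # --- discriminator step: real -> 1, generated -> 0
            noise = rng.standard_normal((m, config.noise_dim))
            fake = gen.forward(noise, train=False)
            logits_real = disc.forward(batch, train=True, rng=rng)
            p_real = _sigmoid(logits_real)
            gw_r, gb_r, _ = disc.backward((p_real - 1.0) / m)
            logits_fake = disc.forward(fake, train=True, rng=rng)
            p_fake = _sigmoid(logits_fake)
            gw_f, gb_f, _ = disc.backward(p_fake / m)
            disc.adam_step(
                [a + b for a, b in zip(gw_r, gw_f)],
                [a + b for a, b in zip(gb_r, gb_f)],
                config.learning_rate, config.adam_beta1, config.adam_beta2,
            )
            d_losses.append(0.5 * (_bce(p_real, 1.0) + _bce(p_fake, 0.0)))

            # --- generator step through the frozen discriminator, target 1
            noise = rng.standard_normal((m, config.noise_dim))
            fake = gen.forward(noise, train=True, rng=rng)
            logits = disc.forward(fake, train=False)
            p = _sigmoid(logits)
            _, _, grad_fake = disc.backward((p - 1.0) / m)
            gw, gb, _ = gen.backward(grad_fake)
            gen.adam_step(
                gw, gb, config.learning_rate, config.adam_beta1, config.adam_beta2
            )
            g_losses.append(_bce(p, 1.0))
        d_epoch = float(np.mean(d_losses))
        g_epoch = float(np.mean(g_losses))
        if not (np.isfinite(d_epoch) and np.isfinite(g_epoch)):
            raise GanTrainingError(
                f"non-finite loss at epoch {epoch + 1}: d={d_epoch}, g={g_epoch}"
            )
        d_trace.append(d_epoch)
        g_trace.append(g_epoch)
    return TrainedGenerator(network=gen, config=config, d_loss=d_trace, g_loss=g_trace)


def gan_sample(
    generator: TrainedGenerator, n: int, seed: int | None = None
) -> np.ndarray:
    """Draw ``n`` synthetic rows: clip to [0, 1], round to 3 decimals.

    The clipping and rounding match the post-processing applied to keep
    synthetic rows on the scale and printed precision of the real PseAAC
    table.  Deterministic given ``seed`` (defaults to the training seed).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    config = generator.config
    rng = np.random.default_rng(config.seed if seed is None else seed)
    noise = rng.standard_normal((n, config.noise_dim))
    raw = generator.network.forward(noise, train=False)
    return np.round(np.clip(raw, 0.0, 1.0), 3)
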