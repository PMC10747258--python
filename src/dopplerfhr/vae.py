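"""Fully convolutional variational autoencoder for integrated-spectrum segments.

The quality model learns, without labels, what a *typical* 1.2 s cardiac
integrated-spectrum segment looks like.  An encoder of five strided
convolutional blocks (conv → batch-norm → ELU, kernel 16, stride 2)
compresses a 1024-sample segment to a 40-channel × 32-sample map, and two
dense heads produce the mean and (log-)variance of a 32-dimensional Gaussian
latent code.  A mirrored transposed-convolution decoder reconstructs the
segment from a reparameterized sample ``z = mu + sigma * eps``.

The training objective is the per-sample mean squared reconstruction error
plus the Kullback–Leibler divergence of ``N(mu, sigma^2)`` from ``N(0, I)``:

    loss = (1/L) * sum_l (x_l - xhat_l)^2
           + (1/2) * sum_i (mu_i^2 + sigma_i^2 - log sigma_i^2 - 1)

minimized with Adam over mini-batches of 64.
"""

from __future__ import annotations

import numpy as np

from .nn import Adam, BatchNorm1d, Conv1d, ConvTranspose1d, Dense, Elu, Layer

__all__ = ["ConvVae1d", "kld_gaussian", "recon_error", "vae_forward"]


def kld_gaussian(mu: np.ndarray, sigma2: np.ndarray) -> float:
    """KL divergence of ``N(mu, diag(sigma2))`` from ``N(0, I)``.

    Each summand ``(mu_i^2 + s_i - log s_i - 1)/2`` is nonnegative, so the
    divergence is zero exactly at ``mu = 0, sigma2 = 1``.
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    return float(0.5 * np.sum(mu**2 + sigma2 - np.log(sigma2) - 1.0))


def recon_error(x: np.ndarray, xhat: np.ndarray) -> float:
    """Mean squared reconstruction error over the segment length."""
    x = np.asarray(x, dtype=float)
    return float(np.mean((x - np.asarray(xhat, dtype=float)) ** 2))


class ConvVae1d:
    """Strided 1-D convolutional VAE (scikit-learn style estimator).

    Parameters
    ----------
    latent_dim : int
        Dimension of the Gaussian latent code.
    channels : tuple of int
        Encoder channel plan; one conv block (stride ``stride``) per entry,
        mirrored in the decoder.  The default compresses 1024 -> 32 samples
        at 40 channels.
    kernel, stride : int
        Shared by every (transposed) convolution.
    input_len : int
        Segment length; must be divisible by ``stride ** len(channels)``.
    epochs, batch_size, lr : training schedule (Adam).
    seed : int
        Seeds initialization, shuffling and latent sampling.

    Attributes
    ----------
    loss_log_ : list of float
        Mean total loss per epoch.
    n_features_in_ : int
    """

    def __init__(
        self,
        latent_dim: int = 32,
        channels: tuple[int, ...] = (8, 16, 24, 32, 40),
        kernel: int = 16,
        stride: int = 2,
        input_len: int = 1024,
        epochs: int = 100,
        batch_size: int = 64,
        lr: float = 1e-3,
        seed: int = 0,
    ):
        self.latent_dim = latent_dim
        self.channels = channels
        self.kernel = kernel
        self.stride = stride
        self.input_len = input_len
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    # -- scikit-learn plumbing -------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "latent_dim channels kernel stride input_len "
                "epochs batch_size lr seed"
            ).split()
        }

    def set_params(self, **params) -> "ConvVae1d":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- network construction --------------------------------------------
    def _build(self, rng: np.random.Generator) -> None:
        k, s = self.kernel, self.stride
        pad = (k - s) // 2  # halves/doubles the length exactly
        if self.input_len % (s ** len(self.channels)) != 0:
            raise ValueError("input_len must be divisible by stride**n_layers")
        self._l_last = self.input_len // (s ** len(self.channels))
        self._flat = self.channels[-1] * self._l_last

        self._enc: list[Layer] = []
        c_prev = 1
        for c in self.channels:
            self._enc += [Conv1d(c_prev, c, k, s, pad, rng), BatchNorm1d(c), Elu()]
            c_prev = c
        self._fc_mu = Dense(self._flat, self.latent_dim, rng)
        self._fc_logvar = Dense(self._flat, self.latent_dim, rng)
        self._fc_dec = Dense(self.latent_dim, self._flat, rng)
        self._dec_elu = Elu()

        self._dec: list[Layer] = []
        chain = list(self.channels[::-1]) + [1]
        for i, (c_in, c_out) in enumerate(zip(chain[:-1], chain[1:])):
            self._dec.append(ConvTranspose1d(c_in, c_out, k, s, pad, rng))
            if i < len(chain) - 2:  # final layer stays linear
                self._dec += [BatchNorm1d(c_out), Elu()]

        self._all_layers = (
            self._enc
            + [self._fc_mu, self._fc_logvar, self._fc_dec, self._dec_elu]
            + self._dec
        )

    # -- forward / backward ----------------------------------------------
    def _forward(
        self, x: np.ndarray, eps: np.ndarray | None, train: bool
    ) -> dict[str, np.ndarray]:
        b = x.shape[0]
        h = x[:, None, :]
        for lay in self._enc:
            h = lay.forward(h, train)
        h = h.reshape(b, self._flat)
        mu = self._fc_mu.forward(h, train)
        logvar = np.clip(self._fc_logvar.forward(h, train), -15.0, 15.0)
        std = np.exp(0.5 * logvar)
        if eps is None:
            eps = np.zeros_like(mu)
        z = mu + std * eps
        g = self._dec_elu.forward(self._fc_dec.forward(z, train), train)
        g = g.reshape(b, self.channels[-1], self._l_last)
        for lay in self._dec:
            g = lay.forward(g, train)
        xhat = g[:, 0, :]
        recon = np.mean((x - xhat) ** 2, axis=1)
        kld = 0.5 * np.sum(mu**2 + np.exp(logvar) - logvar - 1.0, axis=1)
        return {
            "mu": mu, "logvar": logvar, "std": std, "eps": eps, "z": z,
            "xhat": xhat, "recon": recon, "kld": kld,
        }

    def _backward(self, x: np.ndarray, out: dict[str, np.ndarray]) -> None:
        b, l = x.shape
        dxhat = (2.0 / (l * b)) * (out["xhat"] - x)
        dg = dxhat[:, None, :]
        for lay in reversed(self._dec):
            dg = lay.backward(dg)
        dg = dg.reshape(b, self._flat)
        dz = self._fc_dec.backward(self._dec_elu.backward(dg))
        dmu = dz + out["mu"] / b
        dlogvar = dz * out["eps"] * 0.5 * out["std"] + 0.5 * (np.exp(out["logvar"]) - 1.0) / b
        dlogvar[np.abs(out["logvar"]) >= 15.0] = 0.0  # clipped region
        dh = self._fc_mu.backward(dmu) + self._fc_logvar.backward(dlogvar)
        dh = dh.reshape(b, self.channels[-1], self._l_last)
        for lay in reversed(self._enc):
            dh = lay.backward(dh)

    # -- public API -------------------------------------------------------
    def fit(self, X: np.ndarray, y=None) -> "ConvVae1d":
        """Train on segments ``X`` of shape ``(n_samples, input_len)``."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(f"X must be (n, {self.input_len})")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        opt = Adam(self._all_layers, lr=self.lr)
        n = X.shape[0]
        self.loss_log_: list[float] = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                xb = X[order[start : start + self.batch_size]]
                eps = rng.standard_normal((xb.shape[0], self.latent_dim))
                out = self._forward(xb, eps, train=True)
                losses.append(float(np.mean(out["recon"] + out["kld"])))
                self._backward(xb, out)
                opt.step()
            self.loss_log_.append(float(np.mean(losses)))
        self.n_features_in_ = self.input_len
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "_all_layers"):
            raise RuntimeError("model is not fitted")

    def transform(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Latent means ``mu_z`` for each segment (evaluation mode)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        mus = [
            self._forward(X[i : i + batch_size], None, train=False)["mu"]
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(mus, axis=0)

    def forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None, train: bool = False
    ) -> dict[str, np.ndarray]:
        """Full pass returning mu, sigma^2, z, xhat and loss terms."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        eps = rng.standard_normal((X.shape[0], self.latent_dim)) if rng is not None else None
        out = self._forward(X, eps, train)
        out["sigma2"] = np.exp(out["logvar"])
        out["loss"] = out["recon"] + out["kld"]
        return out

    # -- persistence ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        self._check_fitted()
        state: dict[str, np.ndarray] = {}
        for i, lay in enumerate(self._all_layers):
            for k, v in lay.params.items():
                state[f"layer{i}_{k}"] = v
            if isinstance(lay, BatchNorm1d):
                state[f"layer{i}_running_mean"] = lay.running_mean
                state[f"layer{i}_running_var"] = lay.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> "ConvVae1d":
        if not hasattr(self, "_all_layers"):
            self._build(np.random.default_rng(self.seed))
        for i, lay in enumerate(self._all_layers):
            for k in lay.params:
                lay.params[k][...] = state[f"layer{i}_{k}"]
            if isinstance(lay, BatchNorm1d):
                lay.running_mean[...] = state[f"layer{i}_running_mean"]
                lay.running_var[...] = state[f"layer{i}_running_var"]
        self.n_features_in_ = self.input_len
        return self


def vae_forward(
    x: np.ndarray, model: ConvVae1d, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Single-segment forward pass; thin wrapper over :meth:`ConvVae1d.forward`."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != model.input_len:
        raise ValueError(f"x must be a length-{model.input_len} vector")
    out = model.forward(x[None, :], rng=rng)
    return {k: v[0] for k, v in out.items()}
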