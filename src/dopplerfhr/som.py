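"""Self-organizing map for latent-code outlier scoring.

A rectangular grid of prototype vectors is trained by competitive learning:
per iteration one sample is drawn, its best-matching unit (BMU) found by
Euclidean distance, and all prototypes move toward the sample with a
Gaussian neighborhood weight centered on the BMU; learning rate and
neighborhood width decay asymptotically.  The quantization error (QE) of a
vector — its distance to the BMU — is small for vectors resembling the bulk
of the training data and large for outliers, which is what makes the map a
label-free quality detector.
"""

from __future__ import annotations

import numpy as np


class SelfOrganizingMap:
    """Competitive-learning SOM (scikit-learn style estimator).

    Parameters
    ----------
    grid : (int, int)
        Output-layer shape; default 30 x 30 neurons.
    n_iter : int
        Random-sample training iterations (default 15,000).
    learning_rate : float
        Initial update step; decays as ``lr / (1 + t / (n_iter / 2))``.
    sigma : float, optional
        Initial Gaussian neighborhood width; defaults to half the larger
        grid dimension, decaying like the learning rate.
    seed : int
        Seeds prototype initialization and sample order.

    Attributes
    ----------
    weights_ : ndarray of shape (grid[0] * grid[1], n_features)
    """

    def __init__(
        self,
        grid: tuple[int, int] = (30, 30),
        n_iter: int = 15000,
        learning_rate: float = 0.5,
        sigma: float | None = None,
        seed: int = 0,
    ):
        self.grid = grid
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.sigma = sigma
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in ("grid", "n_iter", "learning_rate", "sigma", "seed")}

    def set_params(self, **params) -> "SelfOrganizingMap":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "SelfOrganizingMap":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a nonempty (n_samples, n_features) array")
        rng = np.random.default_rng(self.seed)
        gy, gx = self.grid
        n_neurons = gy * gx
        self.n_features_in_ = X.shape[1]

        # prototype init from random training vectors
        init_idx = rng.choice(X.shape[0], size=n_neurons, replace=X.shape[0] < n_neurons)
        w = X[init_idx].copy()

        # squared grid distances between neuron positions, precomputed
        pos = np.stack(np.unravel_index(np.arange(n_neurons), (gy, gx)), axis=1).astype(float)
        grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)

        sigma0 = self.sigma if self.sigma is not None else max(gy, gx) / 2.0
        half_life = self.n_iter / 2.0
        for t in range(self.n_iter):
            decay = 1.0 + t / half_life
            lr = self.learning_rate / decay
            sig = max(sigma0 / decay, 1e-3)
            x = X[rng.integers(X.shape[0])]
            bmu = int(np.argmin(((w - x) ** 2).sum(axis=1)))
            h = np.exp(-grid_d2[bmu] / (2.0 * sig * sig))
            w += (lr * h)[:, None] * (x - w)

        self.weights_ = w
        return self

    def quantization_error(self, X: np.ndarray) -> np.ndarray:
        """Euclidean distance from each row of ``X`` to its winning neuron."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("SOM is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.weights_.shape[1]:
            raise ValueError("feature dimension mismatch with trained prototypes")
        d2 = ((X[:, None, :] - self.weights_[None, :, :]) ** 2).sum(-1)
        return np.sqrt(d2.min(axis=1))


def quantization_error(v: np.ndarray, som: SelfOrganizingMap) -> float:
    """QE of a single vector; thin wrapper over the estimator method."""
    return float(som.quantization_error(np.asarray(v, dtype=float)[None, :])[0])
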