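"""Small adaptive MCMC building blocks shared by the Bayesian fitters.

All hierarchical models in this package are sampled with
Metropolis-within-Gibbs: scalar parameters get random-walk updates with
Robbins-Monro step-size adaptation during warmup, and fixed-effect
vectors get a joint Gaussian proposal whose covariance is learned from
the warmup history. Diagnostics (R-hat, ESS) are computed with arviz on
the stored chains.
"""

from __future__ import annotations

import numpy as np

TARGET_ACC_SCALAR = 0.44   # optimal-ish for 1-d random walk
TARGET_ACC_BLOCK = 0.25    # optimal-ish for multivariate random walk


class ScalarStep:
    """Adaptive scalar random-walk step size (log-scale Robbins-Monro)."""

    __slots__ = ("log_s", "target", "_i")

    def __init__(self, init: float = 0.1, target: float = TARGET_ACC_SCALAR):
        self.log_s = np.log(init)
        self.target = target
        self._i = 0

    @property
    def s(self) -> float:
        return float(np.exp(self.log_s))

    def adapt(self, accepted: float) -> None:
        self._i += 1
        self.log_s += (accepted - self.target) / np.sqrt(self._i)
        self.log_s = float(np.clip(self.log_s, -12.0, 4.0))


class BlockStep:
    """Adaptive multivariate Gaussian proposal for a parameter block.

    Keeps a running mean/covariance of visited states; after a burn-in
    of `warm_cov` updates the proposal uses the empirical covariance
    scaled by 2.38^2/d times an adapted scalar multiplier.
    """

    def __init__(self, dim: int, init_scale: float = 0.05,
                 target: float = TARGET_ACC_BLOCK, warm_cov: int = 200):
        self.dim = dim
        self.scale = ScalarStep(init_scale, target)
        self.warm_cov = warm_cov
        self._n = 0
        self._mean = np.zeros(dim)
        self._m2 = np.zeros((dim, dim))
        self._chol: np.ndarray | None = None

    def update_cov(self, x: np.ndarray) -> None:
        self._n += 1
        d = x - self._mean
        self._mean += d / self._n
        self._m2 += np.outer(d, x - self._mean)
        if self._n >= self.warm_cov and self._n % 50 == 0:
            cov = self._m2 / (self._n - 1)
            cov = cov * (2.38 ** 2 / self.dim) + 1e-8 * np.eye(self.dim)
            try:
                self._chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                self._chol = None

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal(self.dim)
        if self._chol is not None:
            return x + self.scale.s * (self._chol @ z)
        return x + self.scale.s * z


def mh_accept(log_ratio: float, rng: np.random.Generator) -> bool:
    return bool(np.log(rng.random()) < log_ratio)


def half_normal_logpdf(x: np.ndarray | float, scale: float) -> np.ndarray | float:
    """log density of |N(0, scale^2)| for x >= 0 (−inf below 0)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x < 0, -np.inf,
                   0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2)
    return out if out.ndim else float(out)


def normal_logpdf(x, mu, sd):
    z = (np.asarray(x, dtype=float) - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * np.log(2.0 * np.pi)


def sample_group_location(theta: np.ndarray, sigma: float, prior_mu: float,
                          prior_sd: float, rng: np.random.Generator) -> float:
    """Conjugate Gibbs draw of a Normal population location.

    theta_i ~ N(mu, sigma^2), mu ~ N(prior_mu, prior_sd^2).
    """
    n = theta.size
    prec = n / sigma ** 2 + 1.0 / prior_sd ** 2
    mean = (theta.sum() / sigma ** 2 + prior_mu / prior_sd ** 2) / prec
    return float(rng.normal(mean, 1.0 / np.sqrt(prec)))


def diagnostics(chains: np.ndarray, names: list[str] | None = None) -> dict:
    """R-hat and bulk ESS for an array shaped (chain, draw, param)."""
    import arviz as az
    import xarray as xr

    chains = np.asarray(chains)
    if chains.ndim == 2:
        chains = chains[..., None]
    p = chains.shape[-1]
    names = names or [f"p{i}" for i in range(p)]
    ds = xr.Dataset({name: (("chain", "draw"), chains[..., i])
                     for i, name in enumerate(names)})
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    return {
        "rhat": {k: float(rhat[k].values) for k in names},
        "ess_bulk": {k: float(ess[k].values) for k in names},
        "max_rhat": float(max(rhat[k].values for k in names)),
        "min_ess": float(min(ess[k].values for k in names)),
    }
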