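"""One-dimensional Gaussian-mixture fitting by expectation-maximization.

Used for the detection-frequency filter (two components over per-site
detection counts) and for mixture-based binning of Moran's-I values.
Written in-package because both callers assert the EM contract directly:
quantile-based initialization, convergence tolerance 1e-8 on the mean
log-likelihood, at most 500 iterations, and a per-iteration check that
the log-likelihood never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))


class DegenerateMixtureError(ValueError):
    """The data cannot support the requested mixture (e.g. single support point)."""


@dataclass
class GaussianMixture1D:
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihoods: np.ndarray  # one entry per EM iteration, non-decreasing
    converged: bool

    @property
    def n_components(self) -> int:
        return self.means.size

    def _log_joint(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[:, None]
        return (
            np.log(self.weights)[None, :]
            - 0.5 * (_LOG2PI + 2.0 * np.log(self.sds))[None, :]
            - 0.5 * ((x - self.means[None, :]) / self.sds[None, :]) ** 2
        )

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior component probabilities, shape (len(x), k)."""
        lj = self._log_joint(x)
        lj -= lj.max(axis=1, keepdims=True)
        p = np.exp(lj)
        return p / p.sum(axis=1, keepdims=True)


def fit_gaussian_mixture_1d(
    x: np.ndarray,
    k: int = 2,
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    min_sd: float = 1e-3,
    seed: int = 0,
) -> GaussianMixture1D:
    """Fit a k-component univariate Gaussian mixture by EM.

    Components are initialized at spread quantiles of the data (the
    k-means++-flavored deterministic analog for 1-D data), with equal
    weights and the pooled standard deviation.  ``seed`` only matters for
    degenerate quantile ties, where a tiny deterministic jitter separates
    the initial means.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < k:
        raise DegenerateMixtureError(f"need at least k={k} observations")
    if np.unique(x).size < 2:
        raise DegenerateMixtureError("single support point: mixture is degenerate")

    qs = (np.arange(k) + 0.5) / k
    means = np.quantile(x, qs).astype(float)
    if np.unique(means).size < k:
        rng = np.random.default_rng(seed)
        means = means + rng.normal(0.0, max(x.std(), 1.0) * 1e-3, size=k)
    sds = np.full(k, max(float(x.std()), min_sd))
    weights = np.full(k, 1.0 / k)

    model = GaussianMixture1D(means, sds, weights, np.array([]), False)
    loglik_trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        lj = model._log_joint(x)
        m = lj.max(axis=1)
        ll = float((m + np.log(np.exp(lj - m[:, None]).sum(axis=1))).mean())
        # EM guarantee: the likelihood is monotone; a real decrease means a bug
        assert ll >= prev - 1e-9, "EM log-likelihood decreased"
        loglik_trace.append(ll)
        if ll - prev < tol:
            converged = True
            break
        prev = ll
        r = model.responsibilities(x)
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        means = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, min_sd**2))
        weights = np.maximum(nk / x.size, 1e-12)
        weights = weights / weights.sum()
        model = GaussianMixture1D(means, sds, weights, np.array([]), False)

    model.log_likelihoods = np.asarray(loglik_trace)
    model.converged = converged
    return model
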