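"""Default priors for diffusion parameters.

All subject-level priors are truncated normals on the parameter's
support; hyper-SDs get half-normal priors.  These are package defaults
(broad, weakly informative on the s = 1 scale) and are fully
configurable through :class:`Priors`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .design import ModelSpec

#: default truncated-normal (mean, sd) by parameter family
DEFAULT_PRIOR_MOMENTS = {
    "v": (2.0, 3.0),
    "a": (1.5, 1.0),
    "z": (0.5, 0.2),
    "t0": (0.3, 0.2),
    "sv": (1.0, 1.0),
    "sz": (0.2, 0.2),
}

#: half-normal scale for hierarchical hyper-SD parameters
DEFAULT_HYPER_SD_SCALE = 1.0


def _log_trunc_norm(x, mu, sigma, lo, hi):
    """Elementwise log density of a truncated normal (vectorized)."""
    z = (x - mu) / sigma
    log_norm = np.log(ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma))
    return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2 * np.pi) - log_norm


@dataclass
class Priors:
    """Independent truncated-normal priors aligned with a ModelSpec."""

    mu: np.ndarray
    sigma: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    hyper_sd_scale: float = DEFAULT_HYPER_SD_SCALE

    @classmethod
    def default(cls, spec: ModelSpec, overrides: dict | None = None) -> "Priors":
        """Default priors for every free parameter of ``spec``.

        ``overrides`` maps parameter names (or family names) to
        ``(mean, sd)`` pairs.
        """
        overrides = overrides or {}
        mu = np.empty(spec.n_params)
        sigma = np.empty(spec.n_params)
        for i, (name, fam) in enumerate(zip(spec.param_names, spec.family)):
            m, s = overrides.get(name, overrides.get(fam, DEFAULT_PRIOR_MOMENTS[fam]))
            mu[i], sigma[i] = m, s
        return cls(mu=mu, sigma=sigma, lower=spec.lower.copy(), upper=spec.upper.copy())

    def logpdf(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, dtype=float)
        if np.any(theta <= self.lower) or np.any(theta >= self.upper):
            return -np.inf
        return float(np.sum(_log_trunc_norm(theta, self.mu, self.sigma, self.lower, self.upper)))

    def log_hyper_sd(self, sd: np.ndarray) -> float:
        """Half-normal log prior on hyper-SD vectors (up to its constant)."""
        sd = np.asarray(sd, dtype=float)
        if np.any(sd <= 0):
            return -np.inf
        return float(np.sum(-0.5 * (sd / self.hyper_sd_scale) ** 2))
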