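"""Parameter container for the joint phenotype/methylation/expression model.

The model ties together four observation layers for each individual *i*:

* phenotype  ``P(Y_i = y_i) = sigmoid(y_i * (beta0 + beta_e E_i + beta_m M_i
  + beta_g G_i + beta_x' X_i))`` with ``y_i in {-1, +1}``,
* methylation ``M_i = alpha0 + alpha_g G_i + eps1``,
* expression  ``E_i = gamma0 + gamma_g G_i + gamma_m M_i + eps2``,
* genotype    ``G_i ~ Binomial(2, p)`` (minor-allele count).

``eps1`` and ``eps2`` are zero-mean normal errors with variances
``sigma1_sq`` and ``sigma2_sq``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = ["APPROX_BETA", "ModelParams", "TESTABLE_EFFECTS"]

#: Scale constant of the normal-CDF approximation of the logistic function:
#: sigmoid(v) ~= Phi(v / APPROX_BETA).  Matching the variances of the logistic
#: and normal distributions gives pi / sqrt(3).
APPROX_BETA: float = float(np.pi / np.sqrt(3.0))

#: Phenotype-layer effects that the association tests may constrain to zero.
TESTABLE_EFFECTS = ("beta_g", "beta_m", "beta_e")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the three-layer model.

    ``approx_beta`` is the fixed logistic-probit scale constant; it is not an
    estimated parameter and cannot be overridden.
    """

    beta0: float
    beta_x: np.ndarray
    beta_g: float
    beta_m: float
    beta_e: float
    alpha0: float
    alpha_g: float
    gamma0: float
    gamma_g: float
    gamma_m: float
    sigma1_sq: float
    sigma2_sq: float
    p: float
    approx_beta: float = field(default=APPROX_BETA, init=False)

    def __post_init__(self) -> None:
        bx = np.atleast_1d(np.asarray(self.beta_x, dtype=float))
        if bx.ndim != 1:
            raise ValueError("beta_x must be a 1-D coefficient vector")
        object.__setattr__(self, "beta_x", bx)
        if not (self.sigma1_sq > 0 and self.sigma2_sq > 0):
            raise ValueError("error variances must be strictly positive")
        if not (0.0 < self.p < 1.0):
            raise ValueError("minor-allele frequency must lie in (0, 1)")
        for name in ("beta0", "beta_g", "beta_m", "beta_e", "alpha0",
                     "alpha_g", "gamma0", "gamma_g", "gamma_m"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def n_covariates(self) -> int:
        return self.beta_x.shape[0]

    def constrain(self, names: Iterable[str]) -> "ModelParams":
        """Return a copy with the named phenotype effects set to zero."""
        names = set(names)
        unknown = names - set(TESTABLE_EFFECTS)
        if unknown:
            raise ValueError(f"cannot constrain {sorted(unknown)}")
        return replace(self, **{name: 0.0 for name in names})

    @classmethod
    def null(cls, n_covariates: int = 0, **overrides: float) -> "ModelParams":
        """A neutral parameter vector (all effects zero, unit variances)."""
        defaults = dict(
            beta0=0.0, beta_x=np.zeros(n_covariates), beta_g=0.0, beta_m=0.0,
            beta_e=0.0, alpha0=0.0, alpha_g=0.0, gamma0=0.0, gamma_g=0.0,
            gamma_m=0.0, sigma1_sq=1.0, sigma2_sq=1.0, p=0.5,
        )
        defaults.update(overrides)
        return cls(**defaults)
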