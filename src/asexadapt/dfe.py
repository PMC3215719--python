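"""Distributions of fitness effects (DFE) for new mutations.

Both beneficial and deleterious selection coefficients are exponentially
distributed.  Beneficial effects ``s_b ~ Exponential(rate=beta1)`` are
unbounded above; deleterious effects ``s_d ~ Exponential(rate=beta2)`` are
truncated at 1.0 (and renormalized), which keeps the multiplicative fitness
factor ``1 - s_d`` non-negative.  The mean effects are ``1/beta1`` and
``1/beta2`` (the latter before truncation; at the rates used here the
truncated mass is below ``e^-10`` and the shift is negligible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DFEParams",
    "S_MAX_DELETERIOUS",
    "sample_beneficial",
    "sample_deleterious",
    "density_beneficial",
    "density_deleterious",
]

#: Upper truncation point of the deleterious DFE (fitness factor 1-s >= 0).
S_MAX_DELETERIOUS = 1.0


@dataclass(frozen=True)
class DFEParams:
    """Rate parameters of the exponential DFEs.

    Parameters
    ----------
    beta1
        Rate of the beneficial DFE; mean beneficial effect is ``1/beta1``.
    beta2
        Rate of the deleterious DFE; mean deleterious effect (before
        truncation at 1.0) is ``1/beta2``.
    """

    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        if not (self.beta1 > 0):
            raise ValueError(f"beta1 must be > 0, got {self.beta1}")
        if not (self.beta2 > 0):
            raise ValueError(f"beta2 must be > 0, got {self.beta2}")

    @property
    def mean_beneficial(self) -> float:
        return 1.0 / self.beta1

    @property
    def mean_deleterious(self) -> float:
        """Mean deleterious effect of the untruncated exponential."""
        return 1.0 / self.beta2


def sample_beneficial(
    params: DFEParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` beneficial selection coefficients from Exponential(beta1)."""
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return rng.exponential(scale=1.0 / params.beta1, size=n)


def sample_deleterious(
    params: DFEParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` deleterious coefficients from Exponential(beta2) truncated at 1.

    Uses the inverse CDF of the renormalized truncated exponential, which is
    equivalent in law to rejection resampling of draws above 1.0 (no atom at
    the truncation point).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    b = params.beta2
    u = rng.random(n)
    # F^-1(u) for F(s) = (1 - e^{-b s}) / (1 - e^{-b}) on (0, 1]
    return -np.log1p(-u * (-np.expm1(-b))) / b


def density_beneficial(s, params: DFEParams):
    """Probability density ``beta1 * exp(-beta1 * s)`` of beneficial effects."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("selection coefficient must be >= 0")
    out = params.beta1 * np.exp(-params.beta1 * s)
    return out if out.ndim else float(out)


def density_deleterious(s, params: DFEParams):
    """Density of the truncated deleterious DFE, renormalized on (0, 1]."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("selection coefficient must be >= 0")
    b = params.beta2
    norm = -np.expm1(-b)  # 1 - e^{-beta2}
    out = np.where(s <= S_MAX_DELETERIOUS, b * np.exp(-b * s) / norm, 0.0)
    return out if out.ndim else float(out)
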