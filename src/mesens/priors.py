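"""Fisher-z uncertainty distributions for literature validity coefficients.

External validation studies report a plausible range for the validity
coefficient rho_QT of a self-report instrument (e.g. 0.3-0.7 for a dietary
questionnaire measuring fruit-and-vegetable intake, 0.4-0.7 for self-reported
cigarettes smoked). Interpreting the reported limits as quantiles of an
uncertainty distribution on the Fisher-z scale gives a normal distribution
whose hyperbolic-tangent image stays inside (-1, 1) and is straightforward to
sample. The error correlation between the two instruments, for which no
literature data exist, is sampled over an admissible range instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_core import DomainError

__all__ = [
    "ValiditySpec",
    "FisherZPrior",
    "ErrorCorrSpec",
    "fisher_z",
    "inverse_fisher_z",
    "prior_from_quantiles",
    "sample_validity",
    "sample_error_correlation",
]

logger = logging.getLogger(__name__)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def fisher_z(rho):
    """Fisher-z transform, ``z = atanh(rho)``."""
    r = np.asarray(rho, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise DomainError("correlation must lie strictly inside (-1, 1)")
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def inverse_fisher_z(z):
    """Inverse Fisher-z transform, ``rho = tanh(z)``."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ValiditySpec:
    """Literature limits for a validity coefficient.

    ``lower`` and ``upper`` are the reported range endpoints, interpreted as
    the central ``ci_level`` quantiles of the uncertainty distribution (0.90
    means the limits sit at the 0.05 and 0.95 quantiles).
    """

    lower: float
    upper: float
    ci_level: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.upper < 1):
            raise DomainError("require 0 < lower <= upper < 1")
        if not (0 < self.ci_level < 1):
            raise DomainError("ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class FisherZPrior:
    """Normal distribution on the Fisher-z scale; tanh maps draws to (-1, 1)."""

    mu_z: float
    sigma_z: float

    def __post_init__(self) -> None:
        if self.sigma_z < 0:
            raise DomainError("sigma_z must be non-negative")


@dataclass(frozen=True)
class ErrorCorrSpec:
    """How the error correlation is generated.

    mode="fixed" uses ``value``; mode="admissible" draws uniformly over
    ``range`` (typically the interval between zero and the compatibility
    limit implied by the observed correlation).
    """

    mode: str = "admissible"
    value: float = 0.0
    range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "admissible"):
            raise DomainError("mode must be 'fixed' or 'admissible'")
        lo, hi = self.range
        for v in (self.value, lo, hi):
            if abs(v) > 1:
                raise DomainError("correlations must lie in [-1, 1]")
        if lo > hi:
            raise DomainError("range must be ordered (lower <= upper)")


def prior_from_quantiles(spec: ValiditySpec) -> FisherZPrior:
    """Fisher-z normal whose quantiles match the reported validity limits.

    With q the standard-normal quantile at (1 + ci_level)/2:

        mu_z    = (atanh(lower) + atanh(upper)) / 2
        sigma_z = (atanh(upper) - atanh(lower)) / (2 q)

    A degenerate spec (lower == upper) yields a point mass.
    """
    zl, zu = fisher_z(spec.lower), fisher_z(spec.upper)
    q = stats.norm.ppf(0.5 * (1.0 + spec.ci_level))
    return FisherZPrior(mu_z=0.5 * (zl + zu), sigma_z=(zu - zl) / (2.0 * q))


def sample_validity(prior: FisherZPrior, n: int, seed=None,
                    require_positive: bool = True) -> np.ndarray:
    """Draw validity coefficients as tanh of Fisher-z normal deviates.

    Validity coefficients are positive by construction of the instrument, so
    non-positive draws (possible under a wide prior) are rejected and redrawn;
    the rejection count is logged.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = _rng(seed)
    draws = np.tanh(rng.normal(prior.mu_z, prior.sigma_z, size=n))
    if require_positive:
        n_rejected = 0
        bad = draws <= 0
        while np.any(bad):
            n_rejected += int(bad.sum())
            draws[bad] = np.tanh(rng.normal(prior.mu_z, prior.sigma_z,
                                            size=int(bad.sum())))
            bad = draws <= 0
        if n_rejected:
            logger.info("rejected %d non-positive validity draws (rate %.3g)",
                        n_rejected, n_rejected / (n + n_rejected))
    return draws


def sample_error_correlation(spec: ErrorCorrSpec, n: int, seed=None) -> np.ndarray:
    """Draw error correlations: a constant vector, or uniform over the range."""
    if n < 1:
        raise DomainError("n must be >= 1")
    rng = _rng(seed)
    if spec.mode == "fixed":
        return np.full(n, spec.value, dtype=float)
    lo, hi = spec.range
    if lo == hi:  # degenerate range behaves like a fixed value
        return np.full(n, lo, dtype=float)
    return rng.uniform(lo, hi, size=n)
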