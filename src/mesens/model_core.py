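"""Deterministic algebra of the additive measurement-error model.

Two continuous exposures (in the motivating application: fruit-and-vegetable
intake and cigarette smoking) are observed through error-prone self-report
measurements

    Q_i = alpha0_i + alpha1_i * T_i + eps_i,   i = 1, 2,

with errors independent of the true exposures T_i. Classical error attenuates
the log hazard ratio of each exposure and, when the errors are correlated,
contaminates each coefficient with the other exposure's error. The bias is
summarised by the attenuation-contamination matrix

    Lambda = Sigma_T @ inv(Sigma_Q)          (no systematic bias)

whose transpose links unadjusted and true log hazard ratios,
``beta_Q = Lambda.T @ beta_T``. Everything in this module is exact, closed-form
2x2 algebra, evaluated for one set of parameter values at a time but
broadcasting over leading axes so a Monte-Carlo engine can push whole draw
vectors through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainError",
    "DegenerateCovarianceError",
    "SingularAdjustmentError",
    "InfeasibilityError",
    "ErrorModelParams",
    "CovariancePair",
    "AttenuationMatrix",
    "true_intake_variance",
    "error_variance",
    "true_covariance",
    "attenuation_contamination_matrix",
    "lambda_determinant",
    "adjust_loghr",
    "univariate_adjust",
    "error_correlation_limits",
]

#: relative determinant tolerance separating singular draws from float noise,
#: applied to the product of the diagonal magnitudes of Lambda
DET_TOL = 1e-10


class DomainError(ValueError):
    """A parameter lies outside its mathematical domain."""


class DegenerateCovarianceError(DomainError):
    """A covariance matrix is singular or not positive definite."""


class SingularAdjustmentError(ArithmeticError):
    """Lambda is (numerically) singular; the draw must be rejected.

    Deliberately not a :class:`DomainError`: a singular draw is a property of
    a particular Monte-Carlo iterate, not of the user-supplied configuration.
    """


class InfeasibilityError(DomainError):
    """The requested error structure cannot carry the observed covariance."""


@dataclass(frozen=True)
class ErrorModelParams:
    """Systematic-bias terms of the additive error model.

    alpha0 : constant (additive) bias per exposure, in exposure units.
    alpha1 : proportional scaling bias per exposure, unitless, > 0.
    """

    alpha0: tuple[float, float] = (0.0, 0.0)
    alpha1: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.alpha0)):
            raise DomainError("alpha0 must be finite")
        if not all(a > 0 and np.isfinite(a) for a in self.alpha1):
            raise DomainError("alpha1 components must be strictly positive")


def _as_pd_2x2(mat, name: str) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    if m.shape[-2:] != (2, 2):
        raise DomainError(f"{name} must be 2x2, got shape {m.shape}")
    if not np.allclose(m, np.swapaxes(m, -1, -2), rtol=0, atol=1e-10):
        raise DomainError(f"{name} must be symmetric")
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    if np.any(m[..., 0, 0] <= 0) or np.any(det <= 0):
        raise DegenerateCovarianceError(f"{name} is not positive definite")
    return m


@dataclass(frozen=True)
class CovariancePair:
    """Observed-measurement and true-exposure covariance matrices.

    Both are symmetric positive definite 2x2 matrices in exposure units
    squared. With no proportional scaling bias the true variances cannot
    exceed the observed ones.
    """

    sigma_q: np.ndarray
    sigma_t: np.ndarray
    params: ErrorModelParams = field(default_factory=ErrorModelParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_q", _as_pd_2x2(self.sigma_q, "sigma_q"))
        object.__setattr__(self, "sigma_t", _as_pd_2x2(self.sigma_t, "sigma_t"))
        if self.params.alpha1 == (1.0, 1.0):
            for i in range(2):
                if self.sigma_t[i, i] > self.sigma_q[i, i] * (1 + 1e-12):
                    raise DomainError(
                        "true variance exceeds observed variance with alpha1=1"
                    )


@dataclass(frozen=True)
class AttenuationMatrix:
    """A validated 2x2 attenuation-contamination matrix.

    Diagonal entries attenuate each coefficient; off-diagonal entries carry
    one exposure's error into the other's coefficient. Must be invertible
    (absolute determinant above ``det_tol`` times the product of the diagonal
    magnitudes).
    """

    lam: np.ndarray
    det_tol: float = DET_TOL

    def __post_init__(self) -> None:
        m = np.asarray(self.lam, dtype=float)
        if m.shape != (2, 2) or not np.all(np.isfinite(m)):
            raise DomainError("lam must be a finite 2x2 matrix")
        object.__setattr__(self, "lam", m)
        det = float(lambda_determinant(m))
        scale = max(abs(m[0, 0] * m[1, 1]), 1e-300)
        if abs(det) <= self.det_tol * scale:
            raise SingularAdjustmentError("Lambda is numerically singular")


def _check_positive(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise DomainError(f"{name} must be finite and strictly positive")
    return arr


def _check_validity(rho, name: str) -> np.ndarray:
    arr = np.asarray(rho, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise DomainError(f"{name} must lie in (0, 1]")
    return arr


def true_intake_variance(rho_qt, sigma_q, alpha1=1.0):
    """Variance of the true exposure implied by a validity coefficient.

    The validity coefficient rho_QT = corr(Q, T) = alpha1 * sigma_T / sigma_Q
    inverts to ``sigma_T^2 = (rho_QT * sigma_Q / alpha1)^2``.

    Parameters are broadcast; scalars in, scalar out.
    """
    rho = _check_validity(rho_qt, "rho_qt")
    sq = _check_positive(sigma_q, "sigma_q")
    a1 = _check_positive(alpha1, "alpha1")
    out = (rho * sq / a1) ** 2
    return out if out.ndim else float(out)


def error_variance(sigma_q2, rho_qt):
    """Random-error variance ``sigma_Q^2 * (1 - rho_QT^2)``.

    Complements :func:`true_intake_variance` (at alpha1 = 1): the two shares
    reconstitute the observed variance exactly.
    """
    sq2 = _check_positive(sigma_q2, "sigma_q2")
    rho = _check_validity(rho_qt, "rho_qt")
    out = sq2 * (1.0 - rho**2)
    return out if out.ndim else float(out)


def true_covariance(sigma_q1q2, rho_eps, sigma_q1, sigma_q2, rho1, rho2):
    """Covariance of the true exposures from the observed-covariance split.

    The observed covariance decomposes into a true-exposure part and an
    error part; subtracting the error covariance implied by the error
    correlation ``rho_eps`` and the two error SDs gives

        sigma_T1T2 = sigma_Q1Q2
                     - rho_eps * sigma_Q1 * sigma_Q2
                       * sqrt((1 - rho1^2) * (1 - rho2^2)).
    """
    s12 = np.asarray(sigma_q1q2, dtype=float)
    re = np.asarray(rho_eps, dtype=float)
    if np.any(np.abs(re) > 1):
        raise DomainError("rho_eps must lie in [-1, 1]")
    s1 = _check_positive(sigma_q1, "sigma_q1")
    s2 = _check_positive(sigma_q2, "sigma_q2")
    r1 = _check_validity(rho1, "rho1")
    r2 = _check_validity(rho2, "rho2")
    out = s12 - re * s1 * s2 * np.sqrt((1.0 - r1**2) * (1.0 - r2**2))
    return out if out.ndim else float(out)


def lambda_determinant(lam) -> np.ndarray:
    """Determinant of (stacked) 2x2 matrices."""
    m = np.asarray(lam, dtype=float)
    return m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]


def _inv_2x2(m: np.ndarray, det: np.ndarray) -> np.ndarray:
    inv = np.empty_like(m)
    inv[..., 0, 0] = m[..., 1, 1]
    inv[..., 1, 1] = m[..., 0, 0]
    inv[..., 0, 1] = -m[..., 0, 1]
    inv[..., 1, 0] = -m[..., 1, 0]
    return inv / det[..., None, None]


def attenuation_contamination_matrix(cov: CovariancePair | None = None, *,
                                     sigma_t=None, sigma_q=None,
                                     alpha1=(1.0, 1.0)) -> np.ndarray:
    """Attenuation-contamination matrix ``Lambda = Sigma_TQ @ inv(Sigma_Q)``.

    Without proportional scaling bias (alpha1 = 1) this is the classical
    ``Sigma_T @ inv(Sigma_Q)``: diagonal entries are attenuation factors,
    off-diagonal entries contamination factors. With scaling bias the
    cross-covariance generalises to ``Sigma_TQ[i, j] = alpha1_j * Sigma_T[i, j]``
    (from cov(T_i, Q_j) = alpha1_j * cov(T_i, T_j)); the default keeps
    alpha1 = (1, 1).

    Accepts either a validated :class:`CovariancePair` or raw stacked
    ``sigma_t`` / ``sigma_q`` arrays of shape (..., 2, 2) for vectorised use
    (raw arrays are checked only for positive determinant).
    """
    if cov is not None:
        st, sq = cov.sigma_t, cov.sigma_q
        alpha1 = cov.params.alpha1
    else:
        st = np.asarray(sigma_t, dtype=float)
        sq = np.asarray(sigma_q, dtype=float)
        det_q = lambda_determinant(sq)
        if np.any(det_q <= 0) or np.any(sq[..., 0, 0] <= 0):
            raise DegenerateCovarianceError("sigma_q is not positive definite")
    a1 = np.asarray(alpha1, dtype=float)
    stq = st * a1[..., None, :]  # scales column j by alpha1_j
    det_q = lambda_determinant(sq)
    return stq @ _inv_2x2(sq, det_q)


def adjust_loghr(beta_q, lam, det_tol: float = DET_TOL):
    """Adjusted log hazard ratios ``beta_T = inv(Lambda.T) @ beta_Q``.

    Solves the 2x2 system in closed form; broadcasts over leading axes.
    Raises :class:`SingularAdjustmentError` when ``|det Lambda|`` falls below
    ``det_tol`` times the product of the diagonal magnitudes (the draw should
    be rejected, not the run aborted).
    """
    b = np.asarray(beta_q, dtype=float)
    if isinstance(lam, AttenuationMatrix):
        lam = lam.lam
    m = np.asarray(lam, dtype=float)
    if b.shape[-1] != 2 or m.shape[-2:] != (2, 2):
        raise DomainError("beta_q must be length-2 and lam 2x2")
    if np.any(~np.isfinite(b)) or np.any(~np.isfinite(m)):
        raise DomainError("beta_q and lam must be finite")
    det = lambda_determinant(m)
    scale = np.abs(m[..., 0, 0] * m[..., 1, 1])
    if np.any(np.abs(det) <= det_tol * np.maximum(scale, 1e-300)):
        raise SingularAdjustmentError("Lambda is numerically singular")
    # inv(Lambda.T) = inv(Lambda).T ; closed form for 2x2
    b1 = (m[..., 1, 1] * b[..., 0] - m[..., 1, 0] * b[..., 1]) / det
    b2 = (-m[..., 0, 1] * b[..., 0] + m[..., 0, 0] * b[..., 1]) / det
    out = np.stack([b1, b2], axis=-1)
    return out if out.ndim > 1 else out


def univariate_adjust(beta_q1, attenuation):
    """Single-exposure correction: divide by the attenuation factor.

    ``attenuation = var(T)/var(Q)`` in (0, 1]; equals rho_QT^2 when alpha1=1.
    Ignores contamination from the other exposure, so it matches the
    multivariate adjustment exactly only when Lambda is diagonal.
    """
    lam = np.asarray(attenuation, dtype=float)
    if np.any(~np.isfinite(lam)) or np.any(lam <= 0) or np.any(lam > 1):
        raise DomainError("attenuation must lie in (0, 1]")
    out = np.asarray(beta_q1, dtype=float) / lam
    return out if out.ndim else float(out)


def error_correlation_limits(rho_q1q2, rho1, rho2,
                             clamp_warnings: list | None = None):
    """Admissible error-correlation interval given the observed correlation.

    One endpoint is zero (all of the observed covariance attributed to the
    true exposures); the other is the error correlation that would carry the
    whole observed covariance on its own, i.e. zero true-exposure correlation:

        limit = rho_Q1Q2 / sqrt((1 - rho1^2) * (1 - rho2^2))

    clamped to [-1, 1]. Returned ordered (lower, upper). If ``clamp_warnings``
    is a list, a message is appended whenever clamping was required.
    """
    rq = np.asarray(rho_q1q2, dtype=float)
    if np.any(np.abs(rq) >= 1):
        raise DomainError("rho_q1q2 must lie strictly inside (-1, 1)")
    r1 = np.asarray(rho1, dtype=float)
    r2 = np.asarray(rho2, dtype=float)
    for name, r in (("rho1", r1), ("rho2", r2)):
        if np.any(r <= 0) or np.any(r > 1):
            raise DomainError(f"{name} must lie in (0, 1]")
    err_share = (1.0 - r1**2) * (1.0 - r2**2)
    if np.any((err_share == 0) & (rq != 0)):
        raise InfeasibilityError(
            "perfect validity leaves no error variance to carry a nonzero "
            "observed correlation"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        limit = np.where(err_share > 0, rq / np.sqrt(err_share), 0.0)
    clipped = np.clip(limit, -1.0, 1.0)
    if clamp_warnings is not None and np.any(clipped != limit):
        clamp_warnings.append(
            "error-correlation limit exceeded [-1, 1] and was clamped"
        )
    lower = np.minimum(clipped, 0.0)
    upper = np.maximum(clipped, 0.0)
    if lower.ndim == 0:
        return float(lower), float(upper)
    return lower, upper
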