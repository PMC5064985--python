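"""Monte-Carlo engine combining data posteriors with external validity priors.

Per iteration the engine pairs one posterior draw of the unadjusted log
hazard ratios beta_Q and of the measurement covariance Sigma_Q with one draw
of each validity coefficient (Fisher-z priors) and of the error correlation,
rebuilds the true-exposure covariance Sigma_T and the attenuation-
contamination matrix Lambda, and emits the multivariate-adjusted
``inv(Lambda.T) @ beta_Q``, the univariate comparator ``beta_Qi / rho_i^2``
and the unadjusted draw itself. Draws implying a non-positive-definite
Sigma_T, a true-exposure correlation outside [-1, 1], or a numerically
singular Lambda are rejected and redrawn, and the rejection rate reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from . import model_core as mc
from .bayes import BayesianCoxPH, chain_diagnostics, sample_covariance_posterior
from .priors import (ErrorCorrSpec, FisherZPrior, ValiditySpec,
                     prior_from_quantiles, sample_validity)

__all__ = [
    "IncompatiblePriorsError",
    "summarize_draws",
    "adjust_draws",
    "variance_error_share",
    "MeasurementErrorCoxAdjuster",
    "run_adjustment",
]

METHODS = ("multivariate", "univariate", "unadjusted")
COEFS = ("exposure1", "exposure2")


class IncompatiblePriorsError(RuntimeError):
    """Most draws are infeasible; the priors contradict the observed data."""


def summarize_draws(draws) -> dict:
    """Posterior summary: mean, sd, median, 0.05/0.95 quantiles and mode.

    Quantiles use linear interpolation. The mode is the abscissa of the
    maximum of a Gaussian kernel density estimate (Silverman bandwidth)
    evaluated on a 512-point grid spanning the draw range; a (near-)constant
    sample short-circuits to the common value.
    """
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise mc.DomainError("need at least 100 draws to summarize")
    out = {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "median": float(np.median(x)),
        "q05": float(np.quantile(x, 0.05)),
        "q95": float(np.quantile(x, 0.95)),
    }
    if np.ptp(x) < 1e-14 * max(1.0, abs(out["mean"])):
        out["mode"] = out["mean"]
        out["sd"] = 0.0 if np.ptp(x) == 0 else out["sd"]
        return out
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    out["mode"] = float(grid[np.argmax(kde(grid))])
    return out


def adjust_draws(beta_q, sigma_q, rho1, rho2, rho_eps, det_tol: float = mc.DET_TOL):
    """Vectorised per-draw measurement-error adjustment.

    Parameters are aligned arrays: ``beta_q`` (m, 2), ``sigma_q`` (m, 2, 2),
    ``rho1``/``rho2``/``rho_eps`` (m,). Returns a dict with

    - ``beta_multivariate`` (m, 2): ``inv(Lambda.T) @ beta_Q`` per draw,
    - ``beta_univariate`` (m, 2): ``beta_Qi / rho_i^2``,
    - ``rho_t`` (m,): implied true-exposure correlation,
    - ``valid`` (m,): feasibility mask (PD Sigma_T, |rho_T| <= 1,
      non-singular Lambda); adjusted entries are NaN where invalid.
    """
    beta_q = np.asarray(beta_q, dtype=float)
    sigma_q = np.asarray(sigma_q, dtype=float)
    rho1 = np.asarray(rho1, dtype=float)
    rho2 = np.asarray(rho2, dtype=float)
    rho_eps = np.asarray(rho_eps, dtype=float)

    sq11, sq22, sq12 = sigma_q[:, 0, 0], sigma_q[:, 1, 1], sigma_q[:, 0, 1]
    st11 = rho1**2 * sq11
    st22 = rho2**2 * sq22
    err_cov_unit = np.sqrt((1.0 - rho1**2) * (1.0 - rho2**2))
    st12 = sq12 - rho_eps * np.sqrt(sq11 * sq22) * err_cov_unit

    with np.errstate(invalid="ignore", divide="ignore"):
        rho_t = st12 / np.sqrt(st11 * st22)
    det_t = st11 * st22 - st12**2
    valid = (st11 > 0) & (st22 > 0) & (det_t > 0) & (np.abs(rho_t) <= 1)

    sigma_t = np.empty_like(sigma_q)
    sigma_t[:, 0, 0] = st11
    sigma_t[:, 1, 1] = st22
    sigma_t[:, 0, 1] = sigma_t[:, 1, 0] = st12
    lam = mc.attenuation_contamination_matrix(sigma_t=sigma_t, sigma_q=sigma_q)
    det_lam = mc.lambda_determinant(lam)
    diag_scale = np.abs(lam[:, 0, 0] * lam[:, 1, 1])
    valid &= np.abs(det_lam) > det_tol * np.maximum(diag_scale, 1e-300)

    with np.errstate(invalid="ignore", divide="ignore"):
        b1 = (lam[:, 1, 1] * beta_q[:, 0] - lam[:, 1, 0] * beta_q[:, 1]) / det_lam
        b2 = (-lam[:, 0, 1] * beta_q[:, 0] + lam[:, 0, 0] * beta_q[:, 1]) / det_lam
        beta_multi = np.stack([b1, b2], axis=-1)
        beta_uni = beta_q / np.stack([rho1**2, rho2**2], axis=-1)
    beta_multi[~valid] = np.nan
    return {"beta_multivariate": beta_multi, "beta_univariate": beta_uni,
            "rho_t": rho_t, "valid": valid}


def variance_error_share(prior: FisherZPrior, n: int = 100_000, seed=None) -> float:
    """Mean fraction of observed-measurement variance attributed to error.

    Monte-Carlo mean of (1 - rho^2) over validity draws from ``prior``; the
    complement is the share attributable to between-person variation in true
    exposure.
    """
    if n < 10_000:
        raise mc.DomainError("n must be >= 10_000 for a stable estimate")
    rho = sample_validity(prior, n, seed)
    return float(np.mean(1.0 - rho**2))


def _resolve_validity_prior(spec) -> FisherZPrior | float:
    """A (lower, upper[, ci]) tuple, scalar or spec -> prior (or exact 1.0)."""
    if isinstance(spec, FisherZPrior):
        return spec
    if isinstance(spec, ValiditySpec):
        return prior_from_quantiles(spec)
    if np.isscalar(spec):
        v = float(spec)
        if v == 1.0:
            return 1.0  # perfect validity; atanh(1) is not representable
        return FisherZPrior(mu_z=float(np.arctanh(v)), sigma_z=0.0)
    lo, hi = float(spec[0]), float(spec[1])
    if lo == hi:
        return _resolve_validity_prior(lo)
    ci = float(spec[2]) if len(spec) > 2 else 0.90
    return prior_from_quantiles(ValiditySpec(lo, hi, ci))


class MeasurementErrorCoxAdjuster(BaseEstimator):
    """Adjust Cox log hazard ratios for correlated error in two exposures.

    Combines (i) posterior draws of the unadjusted log hazard ratios from a
    Bayesian Cox model fitted to the error-prone measurements, (ii) posterior
    draws of the measurement covariance Sigma_Q, and (iii) validity
    coefficients drawn from Fisher-z priors built from literature-reported
    ranges, into the distribution of adjusted log hazard ratios
    ``inv(Lambda.T) @ beta_Q``. Also reports the univariate (attenuation-
    factor-only) and unadjusted comparators.

    Parameters
    ----------
    validity1, validity2 : tuple (lower, upper) or float
        Literature range for each exposure's validity coefficient (a scalar
        gives a point mass; 1.0 means measured without error). Defaults are
        the published ranges 0.3-0.7 (dietary questionnaire) and 0.4-0.7
        (self-reported smoking).
    ci_level : float
        Central mass the range endpoints represent (0.90: limits are the
        0.05/0.95 quantiles).
    error_corr : {"admissible", "fixed"}
        "fixed" uses ``error_corr_value``; "admissible" draws uniformly, per
        iteration, between 0 and the compatibility limit implied by the
        posterior-mean observed correlation and that iteration's validities.
    n_samples, burn_in, tuning, prior_sd_beta, iw_scale, iw_df
        Sampler settings; see :class:`~mesens.bayes.McmcConfig`.
    max_redraws : int
        Redraw attempts per infeasible iteration before it is dropped.
    random_state : int or None
        Master seed; three independent child streams drive the Cox chain,
        the covariance draws and the validity/error-correlation draws.

    Attributes
    ----------
    beta_q_draws_ : (n_samples, 2) unadjusted log-hazard-ratio draws.
    sigma_q_draws_ : (n_samples, 2, 2) covariance draws.
    observed_corr_ : posterior-mean observed correlation of the measurements.
    draws_ : dict of retained aligned draw arrays (adjusted betas, validities,
        error correlations, implied true-exposure correlation).
    summary_ : DataFrame indexed by (method, coefficient) with columns
        mean, sd, median, q05, q95, mode.
    rejection_rate_ : fraction of combination attempts rejected as infeasible.
    diagnostics_ : dict with Metropolis acceptance rate and per-coefficient
        effective sample sizes.
    """

    def __init__(self, validity1=(0.3, 0.7), validity2=(0.4, 0.7),
                 ci_level: float = 0.90, error_corr: str = "admissible",
                 error_corr_value: float = 0.0, n_samples: int = 50_000,
                 burn_in: int = 5_000, tuning: int = 5_000,
                 prior_sd_beta: float = 1_000.0, iw_scale=None,
                 iw_df: float = 2.0, det_tol: float = mc.DET_TOL,
                 max_redraws: int = 100, random_state=None):
        self.validity1 = validity1
        self.validity2 = validity2
        self.ci_level = ci_level
        self.error_corr = error_corr
        self.error_corr_value = error_corr_value
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.tuning = tuning
        self.prior_sd_beta = prior_sd_beta
        self.iw_scale = iw_scale
        self.iw_df = iw_df
        self.det_tol = det_tol
        self.max_redraws = max_redraws
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        """Run both samplers and the combination step.

        X : (n, 2) error-prone measurements (exposure 1, exposure 2).
        y : (n, 2) array-like of [time, event], DataFrame with ``time`` and
            ``event`` columns, or structured array with those fields.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise mc.DomainError("X must be an n x 2 measurement table")
        ss = np.random.SeedSequence(self.random_state)
        self._seed_cox, self._seed_cov, self._seed_combine = ss.spawn(3)

        cox = BayesianCoxPH(n_samples=self.n_samples, burn_in=self.burn_in,
                            tuning=self.tuning, prior_sd_beta=self.prior_sd_beta,
                            random_state=np.random.default_rng(self._seed_cox))
        cox.fit(X, y)
        self.beta_q_draws_ = cox.coef_draws_
        self.sigma_q_draws_ = sample_covariance_posterior(
            X, self.n_samples, iw_scale=self.iw_scale, iw_df=self.iw_df,
            seed=np.random.default_rng(self._seed_cov))
        sq_mean = self.sigma_q_draws_.mean(axis=0)
        self.observed_corr_ = float(
            sq_mean[0, 1] / np.sqrt(sq_mean[0, 0] * sq_mean[1, 1]))

        p1 = self._prior1()
        p2 = self._prior2()
        espec = self._error_spec()
        self.draws_, self.rejection_rate_ = self._combine(p1, p2, espec)
        self.summary_ = self._summary_table(self.draws_)
        self.diagnostics_ = {
            "cox_acceptance_rate": cox.acceptance_rate_,
            "ess_beta_q1": chain_diagnostics(self.beta_q_draws_[:, 0])["ess"],
            "ess_beta_q2": chain_diagnostics(self.beta_q_draws_[:, 1])["ess"],
            "rejection_rate": self.rejection_rate_,
        }
        return self

    def _prior1(self):
        return _resolve_validity_prior(self._with_ci(self.validity1))

    def _prior2(self):
        return _resolve_validity_prior(self._with_ci(self.validity2))

    def _with_ci(self, spec):
        if np.isscalar(spec) or isinstance(spec, (FisherZPrior, ValiditySpec)):
            return spec
        lo, hi = spec[0], spec[1]
        return (lo, hi, self.ci_level)

    def _error_spec(self) -> ErrorCorrSpec:
        if self.error_corr == "fixed":
            return ErrorCorrSpec(mode="fixed", value=self.error_corr_value)
        return ErrorCorrSpec(mode="admissible")

    # ----------------------------------------------------------- combination
    def _sample_rho(self, prior, m: int, rng) -> np.ndarray:
        if isinstance(prior, float):  # exact 1.0 (perfect validity)
            return np.ones(m)
        return sample_validity(prior, m, rng)

    def _sample_rho_eps(self, spec: ErrorCorrSpec, rho1, rho2, rng) -> np.ndarray:
        if spec.mode == "fixed":
            return np.full(rho1.shape, spec.value)
        # per-draw admissible interval between 0 and the compatibility limit
        err_share = (1.0 - rho1**2) * (1.0 - rho2**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            limit = np.where(err_share > 0,
                             self.observed_corr_ / np.sqrt(err_share), 0.0)
        limit = np.clip(limit, -1.0, 1.0)
        lo, hi = np.minimum(limit, 0.0), np.maximum(limit, 0.0)
        return rng.uniform(lo, hi)

    def _combine(self, prior1, prior2, espec: ErrorCorrSpec):
        """Pair the data chains with validity/error draws; reject-and-redraw."""
        m = self.n_samples
        rng = np.random.default_rng(self._seed_combine)
        rho1 = self._sample_rho(prior1, m, rng)
        rho2 = self._sample_rho(prior2, m, rng)
        rho_eps = self._sample_rho_eps(espec, rho1, rho2, rng)

        res = adjust_draws(self.beta_q_draws_, self.sigma_q_draws_,
                           rho1, rho2, rho_eps, det_tol=self.det_tol)
        n_rejected = int((~res["valid"]).sum())
        attempts = m
        for _ in range(self.max_redraws):
            bad = ~res["valid"]
            k = int(bad.sum())
            if k == 0:
                break
            rho1[bad] = self._sample_rho(prior1, k, rng)
            rho2[bad] = self._sample_rho(prior2, k, rng)
            rho_eps[bad] = self._sample_rho_eps(espec, rho1[bad], rho2[bad], rng)
            res_bad = adjust_draws(self.beta_q_draws_[bad],
                                   self.sigma_q_draws_[bad],
                                   rho1[bad], rho2[bad], rho_eps[bad],
                                   det_tol=self.det_tol)
            for key in ("beta_multivariate", "beta_univariate", "rho_t"):
                res[key][bad] = res_bad[key]
            res["valid"][bad] = res_bad["valid"]
            attempts += k
            n_rejected += int((~res_bad["valid"]).sum())

        rejection_rate = n_rejected / attempts
        if rejection_rate > 0.5:
            raise IncompatiblePriorsError(
                f"{rejection_rate:.0%} of draws were infeasible; the validity "
                "priors and error-correlation assumption are incompatible "
                "with the observed covariance")
        keep = res["valid"]
        draws = {
            "beta_multivariate": res["beta_multivariate"][keep],
            "beta_univariate": res["beta_univariate"][keep],
            "beta_unadjusted": self.beta_q_draws_[keep],
            "rho1": rho1[keep], "rho2": rho2[keep],
            "rho_eps": rho_eps[keep], "rho_t": res["rho_t"][keep],
        }
        return draws, rejection_rate

    def _summary_table(self, draws) -> pd.DataFrame:
        rows = {}
        arrays = {"multivariate": draws["beta_multivariate"],
                  "univariate": draws["beta_univariate"],
                  "unadjusted": draws["beta_unadjusted"]}
        for method in METHODS:
            for j, coef in enumerate(COEFS):
                rows[(method, coef)] = summarize_draws(arrays[method][:, j])
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index = pd.MultiIndex.from_tuples(table.index,
                                                names=["method", "coefficient"])
        return table[["mean", "sd", "median", "q05", "q95", "mode"]]

    def _check_fitted(self):
        if not hasattr(self, "beta_q_draws_"):
            raise RuntimeError("call fit() before running sensitivity grids")

    # ------------------------------------------------------------- grids
    def sensitivity_validity_grid(self, grid) -> pd.DataFrame:
        """Re-run the combination with both validities fixed at grid points.

        ``grid`` is an iterable of (rho1, rho2) pairs in (0, 1]. The (1, 1)
        cell reproduces the unadjusted estimates (no error to correct). Data
        chains are reused; each cell uses common random numbers so that cells
        differ only through the grid coordinates.
        """
        self._check_fitted()
        records = []
        for v1, v2 in grid:
            draws, rej = self._combine(_resolve_validity_prior(float(v1)),
                                       _resolve_validity_prior(float(v2)),
                                       self._error_spec())
            for j, coef in enumerate(COEFS):
                rec = {"rho1": v1, "rho2": v2, "coefficient": coef,
                       "rejection_rate": rej,
                       "rho_t_mean": float(np.mean(draws["rho_t"]))}
                rec.update(summarize_draws(draws["beta_multivariate"][:, j]))
                records.append(rec)
        return pd.DataFrame.from_records(records)

    def sensitivity_error_corr_grid(self, values) -> pd.DataFrame:
        """Combination with the error correlation fixed at each grid value.

        Validity priors stay at their configured (literature) settings; each
        cell also reports the mean implied true-exposure correlation over the
        retained draws. Cells whose rejection rate exceeds 0.5 are flagged by
        the underlying hard error being converted into a flagged NaN row.
        """
        self._check_fitted()
        records = []
        for v in values:
            spec = ErrorCorrSpec(mode="fixed", value=float(v))
            try:
                draws, rej = self._combine(self._prior1(), self._prior2(), spec)
            except IncompatiblePriorsError:
                for coef in COEFS:
                    records.append({"rho_eps": v, "coefficient": coef,
                                    "rejection_rate": np.nan, "flagged": True})
                continue
            for j, coef in enumerate(COEFS):
                rec = {"rho_eps": v, "coefficient": coef,
                       "rejection_rate": rej, "flagged": rej > 0.5,
                       "rho_t_mean": float(np.mean(draws["rho_t"]))}
                rec.update(summarize_draws(draws["beta_multivariate"][:, j]))
                records.append(rec)
        return pd.DataFrame.from_records(records)

    def sensitivity_ci_grid(self, levels=(0.80, 0.90, 0.95, 0.99)) -> pd.DataFrame:
        """Vary the central mass assigned to the same validity limits.

        A lower level spreads the same literature range over a wider Fisher-z
        normal, so posterior spread of the adjusted estimates grows as the
        level falls. The configured ``ci_level`` cell reproduces the default
        fit exactly (common random numbers).
        """
        self._check_fitted()
        records = []
        for level in levels:
            if not (0 < level < 1):
                raise mc.DomainError("ci levels must lie in (0, 1)")
            p1 = _resolve_validity_prior(self._with_level(self.validity1, level))
            p2 = _resolve_validity_prior(self._with_level(self.validity2, level))
            draws, rej = self._combine(p1, p2, self._error_spec())
            for j, coef in enumerate(COEFS):
                rec = {"ci_level": level, "coefficient": coef,
                       "rejection_rate": rej}
                rec.update(summarize_draws(draws["beta_multivariate"][:, j]))
                records.append(rec)
        return pd.DataFrame.from_records(records)

    @staticmethod
    def _with_level(spec, level):
        if np.isscalar(spec):
            return spec
        return (spec[0], spec[1], level)


def run_adjustment(data: pd.DataFrame, config: dict | None = None,
                   **overrides) -> MeasurementErrorCoxAdjuster:
    """Fit a :class:`MeasurementErrorCoxAdjuster` from a cohort table.

    ``data`` must carry columns time, event, q1, q2 (see
    :func:`mesens.io.read_cohort`). ``config`` maps estimator parameter names
    to values; keyword overrides win.
    """
    params = dict(config or {})
    params.update(overrides)
    est = MeasurementErrorCoxAdjuster(**params)
    X = data[["q1", "q2"]].to_numpy()
    y = data[["time", "event"]].to_numpy()
    return est.fit(X, y)
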