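"""Closed-form algebra of the measurement-error model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesens import model_core as mc

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

corr = st.floats(-0.95, 0.95)
validity = st.floats(0.05, 0.999)
sd = st.floats(0.1, 10.0)


@pytest.mark.parametrize("rho,sigma,alpha1,expected", [
    (0.5, 2.0, 1.0, 1.0),
    (1.0, 3.0, 1.0, 9.0),
    (0.7, 1.0, 1.0, 0.49),
    (0.5, 2.0, 2.0, 0.25),
])
def test_true_intake_variance(rho, sigma, alpha1, expected):
    assert mc.true_intake_variance(rho, sigma, alpha1) == pytest.approx(expected)


@pytest.mark.parametrize("sq2,rho,expected", [
    (4.0, 0.5, 3.0), (1.0, 1.0, 0.0), (2.5, 0.7, 1.275),
])
def test_error_variance(sq2, rho, expected):
    assert mc.error_variance(sq2, rho) == pytest.approx(expected)


@pytest.mark.parametrize("bad_call", [
    lambda: mc.true_intake_variance(0.0, 1.0),
    lambda: mc.true_intake_variance(1.2, 1.0),
    lambda: mc.true_intake_variance(0.5, -1.0),
    lambda: mc.true_intake_variance(0.5, 1.0, 0.0),
    lambda: mc.error_variance(-1.0, 0.5),
    lambda: mc.univariate_adjust(0.1, 0.0),
    lambda: mc.univariate_adjust(0.1, 1.5),
])
def test_domain_errors(bad_call):
    with pytest.raises(mc.DomainError):
        bad_call()


@pytest.mark.parametrize("s12,re,s1,s2,r1,r2,expected", [
    (-0.07, 0.0, 1, 1, 0.5, 0.5, -0.07),
    (-0.07, -0.07 / 0.75, 1, 1, 0.5, 0.5, 0.0),
    (0.2, 0.1, 2, 1, 0.6, 0.8, 0.104),
])
def test_true_covariance_examples(s12, re, s1, s2, r1, r2, expected):
    assert mc.true_covariance(s12, re, s1, s2, r1, r2) == pytest.approx(expected, abs=1e-9)


@given(s12=corr, re=corr, s1=sd, s2=sd, r1=validity, r2=validity)
def test_covariance_conservation(s12, re, s1, s2, r1, r2):
    """Adding the error covariance back recovers the observed covariance."""
    st12 = mc.true_covariance(s12, re, s1, s2, r1, r2)
    err_cov = re * np.sqrt(mc.error_variance(s1**2, r1) * mc.error_variance(s2**2, r2))
    assert st12 + err_cov == pytest.approx(s12, abs=1e-12)


def test_attenuation_matrix_identity_and_diagonal():
    sq = np.array([[1.0, -0.07], [-0.07, 1.0]])
    lam = mc.attenuation_contamination_matrix(mc.CovariancePair(sq, sq))
    assert np.allclose(lam, np.eye(2), atol=1e-12)
    lam = mc.attenuation_contamination_matrix(
        mc.CovariancePair(np.eye(2), np.diag([0.25, 0.25])))
    assert np.allclose(lam, np.diag([0.25, 0.25]), atol=1e-12)


def test_attenuation_matrix_worked_example():
    st_ = np.array([[0.25, -0.07], [-0.07, 0.25]])
    sq = np.array([[1.0, -0.07], [-0.07, 1.0]])
    lam = mc.attenuation_contamination_matrix(mc.CovariancePair(sq, st_))
    assert lam == pytest.approx(
        np.array([[0.24631, -0.05276], [-0.05276, 0.24631]]), abs=5e-6)


def test_adjustment_worked_examples():
    beta = np.array([-0.042, 0.046])
    assert mc.adjust_loghr(beta, np.eye(2)) == pytest.approx(beta)
    assert mc.adjust_loghr(beta, np.diag([0.25, 0.25])) == pytest.approx(
        [-0.168, 0.184])
    lam = np.array([[0.24631, -0.05276], [-0.05276, 0.24631]])
    assert mc.adjust_loghr(beta, lam) == pytest.approx([-0.1368, 0.1575], abs=5e-5)


def test_adjustment_round_trip_and_oracle(rng):
    """1,000 random PD covariance pairs: closed form matches a generic solve
    and Lambda.T @ beta_T returns beta_Q."""
    m = 1000
    a = rng.uniform(0.2, 2.0, size=(m, 2))
    r_t = rng.uniform(-0.9, 0.9, size=m)
    shrink = rng.uniform(0.05, 1.0, size=(m, 2))
    for i in range(m):
        sq = np.array([[a[i, 0] ** 2, r_t[i] * a[i, 0] * a[i, 1]],
                       [r_t[i] * a[i, 0] * a[i, 1], a[i, 1] ** 2]])
        st_ = np.diag(np.sqrt(shrink[i])) @ sq @ np.diag(np.sqrt(shrink[i]))
        lam = mc.attenuation_contamination_matrix(sigma_t=st_, sigma_q=sq)
        assert np.allclose(lam, st_ @ np.linalg.inv(sq), atol=1e-10)
        beta_q = rng.normal(size=2)
        beta_t = mc.adjust_loghr(beta_q, lam)
        assert np.allclose(beta_t, np.linalg.solve(lam.T, beta_q), atol=1e-10)
        assert np.allclose(lam.T @ beta_t, beta_q, atol=1e-12)


def test_singular_lambda_rejected():
    lam = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-12]])
    with pytest.raises(mc.SingularAdjustmentError):
        mc.adjust_loghr([0.1, 0.1], lam)
    with pytest.raises(mc.SingularAdjustmentError):
        mc.AttenuationMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]))


def test_non_pd_sigma_q_rejected():
    with pytest.raises(mc.DegenerateCovarianceError):
        mc.attenuation_contamination_matrix(
            sigma_t=np.eye(2), sigma_q=np.array([[1.0, 1.0], [1.0, 1.0]]))


@pytest.mark.parametrize("beta,att,expected", [
    (-0.042, 0.25, -0.168), (0.046, 1.0, 0.046), (-0.042, 0.49, -0.042 / 0.49),
])
def test_univariate_adjust(beta, att, expected):
    assert mc.univariate_adjust(beta, att) == pytest.approx(expected)


def test_univariate_matches_multivariate_when_diagonal():
    sq = np.diag([2.0, 3.0])
    st_ = np.diag([2.0 * 0.5**2, 3.0 * 0.8**2])
    lam = mc.attenuation_contamination_matrix(sigma_t=st_, sigma_q=sq)
    beta_q = np.array([-0.3, 0.2])
    multi = mc.adjust_loghr(beta_q, lam)
    uni = [mc.univariate_adjust(beta_q[0], 0.25), mc.univariate_adjust(beta_q[1], 0.64)]
    assert np.allclose(multi, uni, atol=1e-12)


@given(r1=st.floats(0.2, 0.95))
def test_monotone_attenuation_in_validity(r1):
    """In the diagonal case |adjusted beta1| strictly decreases as rho1 rises."""
    beta = -0.042
    higher = mc.univariate_adjust(beta, min(r1 + 0.04, 1.0) ** 2)
    lower = mc.univariate_adjust(beta, r1**2)
    assert abs(higher) < abs(lower)


@pytest.mark.parametrize("rq,r1,r2,expected", [
    (-0.07, 0.5, 0.5, (-0.09333333, 0.0)),
    (0.0, 0.6, 0.6, (0.0, 0.0)),
    (0.2, 0.6, 0.8, (0.0, 0.41666667)),
])
def test_error_correlation_limits(rq, r1, r2, expected):
    lo, hi = mc.error_correlation_limits(rq, r1, r2)
    assert (lo, hi) == pytest.approx(expected, abs=1e-6)


def test_error_correlation_limit_clamped_and_infeasible():
    warnings_log = []
    lo, hi = mc.error_correlation_limits(0.9, 0.9, 0.9, clamp_warnings=warnings_log)
    assert hi == 1.0 and warnings_log
    with pytest.raises(mc.InfeasibilityError):
        mc.error_correlation_limits(0.3, 1.0, 0.5)


def test_alpha1_generalization_against_joint_normal_oracle(rng):
    """Lambda with scaling bias matches the empirical regression-calibration
    matrix cov(T, Q) @ inv(cov(Q)) of a simulated joint-normal population."""
    n = 400_000
    alpha1 = np.array([1.3, 0.7])
    st_ = np.array([[1.0, 0.3], [0.3, 2.0]])
    T = rng.multivariate_normal([0, 0], st_, size=n)
    se = np.array([[0.8, -0.1], [-0.1, 0.5]])
    eps = rng.multivariate_normal([0, 0], se, size=n)
    Q = alpha1 * T + eps
    sq = alpha1[:, None] * st_ * alpha1[None, :] + se
    lam = mc.attenuation_contamination_matrix(sigma_t=st_, sigma_q=sq, alpha1=alpha1)
    emp_tq = np.cov(np.hstack([T, Q]), rowvar=False)[:2, 2:]
    lam_emp = emp_tq @ np.linalg.inv(np.cov(Q, rowvar=False))
    assert np.allclose(lam, lam_emp, atol=0.01)
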