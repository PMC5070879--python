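"""Maximum likelihood estimation of the constrained dual tensor model.

The nine free parameters are mapped to an unconstrained R^9 so that a
quasi-Newton optimizer can run without box or simplex constraints:

* diffusivities through an exponential map (strictly positive image);
* the two volume fractions through a stick-breaking construction onto
  the open simplex {f1 > 0, f2 > 0, f1 + f2 < 1};
* the four angles are untransformed.

S0 is not optimized; it is fixed to the mean of the b=0 measurements.
The likelihood is multimodal in orientation, so the fit is multi-start:
the data-driven initialization plus restarts that rotate alpha3 by
{pi/4, pi/2} and jitter shape and fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .likelihood import rician_log_pdf, rician_score_nu
from .model import AcquisitionScheme, DTMParams, signal_and_jacobian

__all__ = [
    "to_unconstrained",
    "from_unconstrained",
    "init_theta",
    "fit_mle",
    "MLEResult",
]

_DIFF_SLICE = slice(0, 3)
_ANGLE_SLICE = slice(3, 7)


def to_unconstrained(params: DTMParams) -> np.ndarray:
    """Map a valid parameter set to the unconstrained 9-vector."""
    theta = params.free_vector
    v = np.empty(9)
    v[_DIFF_SLICE] = np.log(theta[_DIFF_SLICE])
    v[_ANGLE_SLICE] = theta[_ANGLE_SLICE]
    f1, f2 = theta[7], theta[8]
    f1 = np.clip(f1, 1e-12, 1 - 1e-12)
    t2 = np.clip(f2 / (1.0 - f1), 1e-12, 1 - 1e-12)
    v[7] = logit(f1)
    v[8] = logit(t2)
    return v


def _fractions_from_unconstrained(v8: float, v9: float):
    t1 = expit(v8)
    t2 = expit(v9)
    return t1, (1.0 - t1) * t2


def from_unconstrained(v: np.ndarray, S0: float, sigma: float) -> DTMParams:
    """Inverse of `to_unconstrained`; total map, always yields valid params."""
    v = np.asarray(v, dtype=float)
    theta = np.empty(9)
    theta[_DIFF_SLICE] = np.exp(v[_DIFF_SLICE])
    theta[_ANGLE_SLICE] = v[_ANGLE_SLICE]
    theta[7], theta[8] = _fractions_from_unconstrained(v[7], v[8])
    return DTMParams.from_free_vector(theta, S0=S0, sigma=sigma)


def _free_theta_from_unconstrained(v: np.ndarray) -> np.ndarray:
    v = np.atleast_2d(v)
    theta = np.empty_like(v)
    theta[:, _DIFF_SLICE] = np.exp(v[:, _DIFF_SLICE])
    theta[:, _ANGLE_SLICE] = v[:, _ANGLE_SLICE]
    t1 = expit(v[:, 7])
    t2 = expit(v[:, 8])
    theta[:, 7] = t1
    theta[:, 8] = (1.0 - t1) * t2
    return theta


def _transform_jacobian_diag(v: np.ndarray):
    """Chain-rule factors d(theta)/d(v); fraction block is 2x2 triangular."""
    t1 = expit(v[7])
    t2 = expit(v[8])
    d = np.ones(9)
    d[_DIFF_SLICE] = np.exp(v[_DIFF_SLICE])
    # df1/dv8, df2/dv8, df2/dv9  (df1/dv9 = 0)
    df1_dv8 = t1 * (1.0 - t1)
    df2_dv8 = -df1_dv8 * t2
    df2_dv9 = (1.0 - t1) * t2 * (1.0 - t2)
    return d, df1_dv8, df2_dv8, df2_dv9


def init_theta(
    signal: np.ndarray, scheme: AcquisitionScheme, sigma: float
) -> DTMParams:
    """Data-driven starting point from a log-linear single tensor fit.

    Fits ln(S/S0) = -b g^T D g by least squares, then duplicates the
    fitted tensor into two compartments split by alpha4 = 0.5 rad with
    f1 = f2 = 0.4.
    """
    s = np.asarray(signal, dtype=float)
    if s.shape != (scheme.n_measurements,):
        raise ValueError("signal length does not match scheme")
    if not np.any(s > 0):
        raise ValueError("signal is identically zero")
    b0 = scheme.b0_mask
    S0 = float(np.mean(s[b0])) if np.any(b0) else float(np.max(s))
    if S0 <= 0:
        raise ValueError("non-positive b0 signal")

    dwi = ~b0
    g = scheme.directions[dwi]
    b = scheme.b_values[dwi]
    y = np.log(np.clip(s[dwi], 1e-10 * S0, None) / S0)
    X = -b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    D = np.array(
        [
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ]
    )
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    lam_par = max(float(evals[0]), 1e-5)
    lam_perp = max(float(np.mean(evals[1:])), 1e-5)
    lam_perp = min(lam_perp, 0.95 * lam_par)

    # Principal axis (x, y, z) -> alpha2 = asin(z), alpha3 = atan2(-y, x),
    # matching the first row of Rx(a1) Ry(a2) Rz(a3).
    v1 = evecs[:, 0]
    z = np.clip(v1[2], -1.0, 1.0)
    alpha2 = float(np.arcsin(z))
    alpha3 = float(np.arctan2(-v1[1], v1[0]))

    return DTMParams(
        lambda_par=lam_par,
        lambda_perp1=lam_perp,
        lambda_perp2=lam_perp,
        alpha1=0.0,
        alpha2=alpha2,
        alpha3=alpha3,
        alpha4=0.5,
        f1=0.4,
        f2=0.4,
        S0=S0,
        sigma=sigma,
    )


@dataclass
class MLEResult:
    params: DTMParams
    log_likelihood: float
    converged: bool
    n_restarts: int


def _neg_loglik_and_grad(v, signal, scheme, S0, sigma):
    theta = _free_theta_from_unconstrained(v[None, :])
    nu, J = signal_and_jacobian(theta, scheme.b_values, scheme.directions, S0)
    nu = nu[0]
    J = J[0]
    ll = float(np.sum(rician_log_pdf(signal, nu, sigma)))
    score = rician_score_nu(signal, nu, sigma)  # (Ng,)
    g_theta = J.T @ score  # (9,)
    d, df1_dv8, df2_dv8, df2_dv9 = _transform_jacobian_diag(v)
    g_v = g_theta * d
    g_v[7] = g_theta[7] * df1_dv8 + g_theta[8] * df2_dv8
    g_v[8] = g_theta[8] * df2_dv9
    return -ll, -g_v


def fit_mle(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    sigma: float,
    init: DTMParams | None = None,
    n_restarts: int = 5,
    seed: int | None = 0,
    maxiter: int = 400,
) -> MLEResult:
    """Multi-start quasi-Newton maximum likelihood fit of one voxel.

    Returns the best local maximizer found; ``converged=False`` flags
    that no restart reported optimizer convergence (the best point is
    still returned, never silently dropped).
    """
    s = np.asarray(signal, dtype=float)
    if init is None:
        init = init_theta(s, scheme, sigma)
    S0 = init.S0
    rng = np.random.default_rng(seed)

    v0 = to_unconstrained(init)
    starts = [v0]
    for off in (np.pi / 4, np.pi / 2):
        v = v0.copy()
        v[5] += off
        starts.append(v)
    while len(starts) < max(1, n_restarts):
        v = v0.copy()
        v[3:7] += rng.normal(scale=0.3, size=4)
        v[7:9] += rng.normal(scale=0.5, size=2)
        v[0:3] += rng.normal(scale=0.2, size=3)
        starts.append(v)

    best_v, best_nll, any_ok = None, np.inf, False
    for v_start in starts[: max(1, n_restarts)]:
        res = minimize(
            _neg_loglik_and_grad,
            v_start,
            args=(s, scheme, S0, sigma),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        any_ok = any_ok or bool(res.success)
        if res.fun < best_nll:
            best_nll, best_v = res.fun, res.x

    if not any_ok:
        warnings.warn(
            "MLE optimizer did not report convergence on any restart; "
            "returning the best point found",
            RuntimeWarning,
            stacklevel=2,
        )
    params = from_unconstrained(best_v, S0=S0, sigma=sigma)
    return MLEResult(
        params=params,
        log_likelihood=-best_nll,
        converged=any_ok,
        n_restarts=max(1, n_restarts),
    )
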