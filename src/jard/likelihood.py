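"""Rician measurement model and joint log-likelihood.

Magnitude MR images carry Rician noise: the measured intensity s given
a noise-free model intensity nu and noise level sigma has density

    p(s | nu, sigma) = s / sigma^2 * exp(-(s^2 + nu^2) / (2 sigma^2))
                       * I0(s nu / sigma^2),

with I0 the zeroth-order modified Bessel function of the first kind.
Measurements across gradient directions are independent, so the voxel
log-likelihood is the sum of per-measurement log-densities.  All Bessel
evaluations use the exponentially scaled I0 so the log-density is
overflow-free at arbitrarily high SNR.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e, i1e

from .model import AcquisitionScheme, DTMParams, predict_signal, signal_and_jacobian

__all__ = [
    "rician_log_pdf",
    "log_likelihood",
    "log_likelihood_batch",
    "rician_score_nu",
]

#: Sentinel for log(0): measured intensity exactly zero has zero Rician
#: density, but optimizers and MH ratios need a finite number.
LOG_ZERO = -1e30


def rician_log_pdf(s_meas, s_model, sigma):
    """Log of the Rician density, elementwise on broadcastable arrays."""
    s = np.asarray(s_meas, dtype=float)
    nu = np.asarray(s_model, dtype=float)
    sig = np.asarray(sigma, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive")
    if np.any(s < 0) or np.any(nu < 0):
        raise ValueError("intensities must be non-negative")
    x = s * nu / sig**2
    # log I0(x) = x + log(i0e(x))
    with np.errstate(divide="ignore"):
        out = (
            np.log(s)
            - 2.0 * np.log(sig)
            - (s**2 + nu**2) / (2.0 * sig**2)
            + x
            + np.log(i0e(x))
        )
    return np.where(np.isneginf(out), LOG_ZERO, out)


def log_likelihood(
    signal: np.ndarray, params: DTMParams, scheme: AcquisitionScheme
) -> float:
    """Joint Rician log-likelihood of one voxel's measurements."""
    s = np.asarray(signal, dtype=float)
    if s.shape != (scheme.n_measurements,):
        raise ValueError(
            f"signal length {s.shape} does not match scheme Ng={scheme.n_measurements}"
        )
    nu = predict_signal(params, scheme)
    return float(np.sum(rician_log_pdf(s, nu, params.sigma)))


def log_likelihood_batch(
    signal: np.ndarray,
    theta: np.ndarray,
    scheme: AcquisitionScheme,
    S0: float,
    sigma: float,
) -> np.ndarray:
    """Log-likelihood of one signal under a batch of free-parameter vectors.

    ``theta`` is (n, 9); returns (n,).  Used by the sampler, where the
    same voxel signal is evaluated at thousands of parameter proposals.
    """
    nu, _ = signal_and_jacobian(
        theta, scheme.b_values, scheme.directions, S0, want_jacobian=False
    )
    lp = rician_log_pdf(signal[None, :], nu, sigma)
    return lp.sum(axis=1)


def rician_score_nu(s_meas, s_model, sigma):
    """d/d(nu) of the Rician log-density (elementwise).

    Equal to s/sigma^2 * I1/I0(s nu / sigma^2) - nu/sigma^2; feeds the
    analytic likelihood gradient and the MLE optimizer.
    """
    s = np.asarray(s_meas, dtype=float)
    nu = np.asarray(s_model, dtype=float)
    x = s * nu / sigma**2
    ratio = np.where(x > 0, i1e(x) / i0e(x), 0.0)
    return s * ratio / sigma**2 - nu / sigma**2
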