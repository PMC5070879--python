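"""Fisher information of Rician measurements and the ARD prior.

The expected information that one Rice-distributed measurement carries
about its noise-free intensity nu is Z(nu/sigma) / sigma^2, where the
dimensionless factor Z is the expectation of the squared score of the
Rice log-density.  Z(0) = 0 (a vanished compartment is unidentifiable)
and Z -> 1 in the Gaussian limit nu/sigma -> infinity.  Z is computed
once by numerical integration on a dense SNR grid and interpolated by a
cubic spline.

For the dual tensor model the 9x9 Fisher matrix is

    I(theta) = J^T diag(Z(S_j/sigma)/sigma^2) J,

with J the analytic Jacobian of the signal model.  The working prior is
p(theta) = det I(theta)^(-1/2): configurations that the acquisition
cannot support (a near-zero volume fraction, two coinciding tensors)
drive det I toward zero and the prior probability up, which is the
automatic-relevance-determination mechanism that collapses unsupported
compartments.  The classical Jeffreys prior det^(+1/2) and the Behrens
fraction prior f^-1 (1-f)^-1 are available for comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import i0e, i1e

from .model import AcquisitionScheme, DTMParams, signal_and_jacobian

__all__ = [
    "rician_information_factor",
    "fisher_information",
    "fisher_information_batch",
    "log_prior",
    "log_prior_batch",
    "behrens_log_prior",
    "crlb_sd",
]

_V_MAX = 100.0
_JITTER = 1e-10

#: Natural parameter scales used to non-dimensionalize the Fisher matrix
#: before regularizing: diffusivities live at 1e-3 mm^2/s, angles and
#: fractions at order one.  Without this, the regularizer would be set
#: by the diffusivity rows (~1e6 times larger in squared units) and
#: would flood the small eigenvalues carrying the relevance signal.
_PARAM_SCALES = np.array([1e-3, 1e-3, 1e-3, 1, 1, 1, 1, 1, 1])


def _rice_score_sq_expectation(v, n_nodes: int = 600):
    """E[(d log p / d nu)^2] for Rice(nu=v, sigma=1), by quadrature.

    Vectorized over v; the integration window tracks the density's
    support (essentially [v - 12, v + 12] intersected with s >= 0).
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    lo = np.maximum(0.0, v - 12.0)
    hi = v + 12.0
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    half = 0.5 * (hi - lo)
    s = half[:, None] * x[None, :] + 0.5 * (hi + lo)[:, None]
    wts = half[:, None] * w[None, :]
    xarg = s * v[:, None]
    pdf = s * np.exp(-0.5 * (s - v[:, None]) ** 2) * i0e(xarg)
    ratio = np.where(xarg > 0, i1e(xarg) / i0e(xarg), 0.0)
    score = s * ratio - v[:, None]
    return np.sum(wts * score**2 * pdf, axis=1)


class _ZTable:
    """Lazily built interpolation table of the Rice information factor Z(v).

    A cubic spline through quadrature values is densified onto a fine
    (non-uniform: finer below v=2 where Z ~ v^2) grid evaluated with
    `np.interp`, keeping the relative interpolation error below 1e-4
    while staying cheap inside the sampler's inner loop.
    """

    def __init__(self, v_max: float = _V_MAX, n_grid: int = 2001) -> None:
        self.v_max = v_max
        self.n_grid = n_grid
        self._fine_x: np.ndarray | None = None
        self._fine_y: np.ndarray | None = None

    def _build(self) -> None:
        # Z ~ v^2 near the origin, so the quadrature grid is densified
        # there to keep the relative spline error small
        grid = np.unique(
            np.concatenate(
                [
                    [0.0],
                    np.geomspace(1e-3, 2.0, 600),
                    np.linspace(2.0, self.v_max, self.n_grid),
                ]
            )
        )
        z = _rice_score_sq_expectation(grid)
        z[0] = 0.0
        spline = CubicSpline(grid, z)
        fine = np.unique(
            np.concatenate(
                [
                    np.arange(0.0, 0.1, 5e-5),
                    np.arange(0.1, 2.0, 4e-4),
                    np.arange(2.0, self.v_max, 5e-3),
                    [self.v_max],
                ]
            )
        )
        self._fine_x = fine
        self._fine_y = np.clip(spline(fine), 0.0, None)

    def __call__(self, v):
        if self._fine_x is None:
            self._build()
        v = np.asarray(v, dtype=float)
        out = np.interp(np.clip(v, 0.0, self.v_max), self._fine_x, self._fine_y)
        # series limit Z = v^2 + O(v^4) beats interpolation below v ~ 0.01
        return np.where(v < 1e-2, v**2, out)


_Z = _ZTable()


def rician_information_factor(snr_point, exact: bool = True):
    """Dimensionless information factor Z(v), v = s_model/sigma.

    With ``exact=False`` returns the Gaussian-noise approximation Z = 1
    for all v > 0.
    """
    v = np.asarray(snr_point, dtype=float)
    if np.any(v < 0):
        raise ValueError("snr_point must be non-negative")
    if not exact:
        return np.ones_like(v)
    return _Z(v)


def fisher_from_jacobian(
    nu: np.ndarray, J: np.ndarray, sigma: float, exact: bool = True
) -> np.ndarray:
    """Fisher matrices J^T diag(Z(nu/sigma)/sigma^2) J from precomputed pieces.

    ``nu`` is (n, Ng) model signal, ``J`` its (n, Ng, 9) Jacobian.
    """
    if exact:
        w = rician_information_factor(nu / sigma) / sigma**2
    else:
        w = np.full_like(nu, 1.0 / sigma**2)
    info = np.swapaxes(J, 1, 2) @ (J * w[..., None])
    return 0.5 * (info + np.swapaxes(info, 1, 2))


def fisher_information_batch(
    theta: np.ndarray,
    scheme: AcquisitionScheme,
    S0: float,
    sigma: float,
    exact: bool = True,
) -> np.ndarray:
    """Batched 9x9 Fisher matrices for (n, 9) free-parameter vectors."""
    nu, J = signal_and_jacobian(theta, scheme.b_values, scheme.directions, S0)
    return fisher_from_jacobian(nu, J, sigma, exact=exact)


def fisher_information(
    params: DTMParams,
    scheme: AcquisitionScheme,
    sigma: float | None = None,
    exact: bool = True,
) -> np.ndarray:
    """Expected information matrix of the 9 free parameters for one voxel."""
    sig = params.sigma if sigma is None else sigma
    return fisher_information_batch(
        params.free_vector[None, :], scheme, params.S0, sig, exact=exact
    )[0]


def _logdet_regularized(info: np.ndarray) -> np.ndarray:
    """Regularized log det of the Fisher matrix, batched over leading axis.

    The matrix is first non-dimensionalized with `_PARAM_SCALES` (which
    shifts log det by a constant, irrelevant in MH ratios), then given a
    jitter of 1e-10 times the mean scaled diagonal so the log det stays
    finite on structurally singular configurations (the alpha1 null
    direction, coinciding tensors, vanished fractions).
    """
    s = np.outer(_PARAM_SCALES, _PARAM_SCALES)
    scaled = info * s
    diag_mean = np.einsum("...aa->...", scaled) / scaled.shape[-1]
    diag_mean = np.maximum(diag_mean, np.finfo(float).tiny)
    eye = np.eye(scaled.shape[-1])
    reg = scaled + (_JITTER * diag_mean)[..., None, None] * eye
    sign, logdet = np.linalg.slogdet(reg)
    # jitter keeps reg PD in exact arithmetic; guard rounding anyway
    return np.where(sign > 0, logdet, -np.inf)


def log_prior_batch(
    theta: np.ndarray,
    scheme: AcquisitionScheme,
    S0: float,
    sigma: float,
    kind: str = "fisher",
    exact: bool = True,
) -> np.ndarray:
    """Log prior density (unnormalized) for a batch of parameter vectors.

    kind:
      * ``"fisher"``   -- det I^(-1/2), the working ARD prior;
      * ``"jeffreys"`` -- det I^(+1/2), the classical Jeffreys form;
      * ``"behrens"``  -- product of f^-1 (1-f)^-1 over both fractions;
      * ``"flat"``     -- 0.
    """
    theta = np.atleast_2d(theta)
    if kind == "flat":
        return np.zeros(theta.shape[0])
    if kind == "behrens":
        return behrens_log_prior(theta[:, 7]) + behrens_log_prior(theta[:, 8])
    info = fisher_information_batch(theta, scheme, S0, sigma, exact=exact)
    logdet = _logdet_regularized(info)
    if kind == "fisher":
        return -0.5 * logdet
    if kind == "jeffreys":
        return 0.5 * logdet
    raise ValueError(f"unknown prior kind: {kind!r}")


def log_prior_from_jacobian(
    nu: np.ndarray,
    J: np.ndarray,
    sigma: float,
    kind: str = "fisher",
    exact: bool = True,
) -> np.ndarray:
    """Fisher-determinant log prior reusing a precomputed signal Jacobian."""
    logdet = _logdet_regularized(fisher_from_jacobian(nu, J, sigma, exact=exact))
    if kind == "fisher":
        return -0.5 * logdet
    if kind == "jeffreys":
        return 0.5 * logdet
    raise ValueError(f"unknown prior kind: {kind!r}")


def log_prior(
    params: DTMParams,
    scheme: AcquisitionScheme,
    sigma: float | None = None,
    kind: str = "fisher",
    exact: bool = True,
) -> float:
    sig = params.sigma if sigma is None else sigma
    return float(
        log_prior_batch(
            params.free_vector[None, :], scheme, params.S0, sig, kind=kind,
            exact=exact,
        )[0]
    )


def behrens_log_prior(f):
    """log of the Behrens ARD fraction prior f^-1 (1-f)^-1."""
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.log(f) - np.log1p(-f)
    return np.where((f <= 0) | (f >= 1), np.inf, out)


def crlb_sd(
    params: DTMParams,
    scheme: AcquisitionScheme,
    sigma: float | None = None,
    null_cutoff: float = 1e-10,
) -> np.ndarray:
    """Cramer-Rao lower bounds: per-parameter SD floor sqrt(diag I^-1).

    The Fisher matrix of the axially symmetric model always has a null
    direction (alpha1 rotates each tensor about structure the symmetric
    model cannot see), so the inverse is taken on the identifiable
    subspace: the matrix is rescaled to unit diagonal, eigen-decomposed,
    and eigenvalues below ``null_cutoff`` times the largest are treated
    as zero information.  Parameters lying in the null space -- no
    information at all -- get NaN (degenerate-parameter flag); the rest
    get finite bounds.
    """
    info = fisher_information(params, scheme, sigma)
    # fixed unit normalization (diffusivities in 1e-3 mm^2/s, angles and
    # fractions order one); raw entries differ by the squared units,
    # which alone puts the raw condition number near 1e12
    scales = np.array([1e-3, 1e-3, 1e-3, 1, 1, 1, 1, 1, 1])
    scaled = info * np.outer(scales, scales)
    evals, evecs = np.linalg.eigh(scaled)
    evals = np.clip(evals, 0.0, None)
    keep = evals > null_cutoff * evals.max()
    if not np.any(keep):
        return np.full(9, np.nan)
    # variance in scaled coordinates: sum_k V_ik^2 / e_k over kept modes
    var_scaled = (evecs[:, keep] ** 2 / evals[keep]).sum(axis=1)
    # parameters with appreciable null-space weight have unbounded CRLB
    null_weight = (evecs[:, ~keep] ** 2).sum(axis=1)
    sd = np.sqrt(var_scaled) * scales
    sd[null_weight > 1e-2] = np.nan
    return sd
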