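"""Constrained dual tensor model of the diffusion-weighted MR signal.

A voxel's signal is modelled as a mixture of two rank-2 anisotropic
diffusion tensors plus an isotropic free-water compartment,

    S(theta, j) = S0 * sum_i  f_i * exp(-b_j g_j^T D_i g_j),
    i in {1, 2, iso},   f_1 + f_2 + f_iso = 1,

with the constraints that both tensors share the axial diffusivity
lambda_par, each tensor is axially symmetric (lambda_perp on both minor
axes), and D_iso is fixed to the free-water diffusivity at body
temperature (3.0e-3 mm^2/s).  Tensor orientations are parameterized by
four angles: Rx(alpha1) Ry(alpha2) orient the plane containing both
principal axes, and Rz(alpha3 +/- alpha4/2) are the in-plane rotations
of the two principal eigenvectors, so alpha4 is the crossing angle.

The nine free parameters exposed to estimators are, in order,

    [lambda_par, lambda_perp1, lambda_perp2,
     alpha1, alpha2, alpha3, alpha4, f1, f2]

with diffusivities in mm^2/s, angles in rad, fractions dimensionless.
S0 (unweighted amplitude) and sigma (Rician noise SD) are known,
fixed quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FREE_PARAM_NAMES",
    "D_ISO_FREE_WATER",
    "AcquisitionScheme",
    "DTMParams",
    "TensorTriplet",
    "build_rotation",
    "build_tensors",
    "predict_signal",
    "fractional_anisotropy",
    "signal_and_jacobian",
]

#: Free-water diffusivity at 37 degrees C, mm^2/s.
D_ISO_FREE_WATER = 3.0e-3

FREE_PARAM_NAMES = (
    "lambda_par",
    "lambda_perp1",
    "lambda_perp2",
    "alpha1",
    "alpha2",
    "alpha3",
    "alpha4",
    "f1",
    "f2",
)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell diffusion acquisition: b-values and unit gradient directions.

    Parameters
    ----------
    b_values : (Ng,) array
        Diffusion weightings in s/mm^2; entries equal to zero mark b=0
        measurements whose direction is ignored.
    directions : (Ng, 3) array
        Unit gradient directions (rows).
    """

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.ascontiguousarray(np.atleast_1d(self.b_values), dtype=float)
        g = np.ascontiguousarray(np.atleast_2d(self.directions), dtype=float)
        if g.shape != (b.size, 3):
            raise ValueError(
                f"directions shape {g.shape} does not match {b.size} b-values"
            )
        if np.any(b < 0) or not np.all(np.isfinite(b)):
            raise ValueError("b-values must be finite and non-negative")
        dwi = b > 0
        norms = np.linalg.norm(g[dwi], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("non-b0 gradient directions must have unit norm")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    @property
    def n_measurements(self) -> int:
        return int(self.b_values.size)

    @property
    def Ng(self) -> int:
        """Measurement count, by its conventional name."""
        return self.n_measurements

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    def concatenate(self, other: "AcquisitionScheme") -> "AcquisitionScheme":
        return AcquisitionScheme(
            np.concatenate([self.b_values, other.b_values]),
            np.vstack([self.directions, other.directions]),
        )


@dataclass
class DTMParams:
    """Parameters of the constrained dual tensor model for one voxel.

    The nine free parameters plus the fixed amplitude ``S0``, noise level
    ``sigma`` and isotropic diffusivity ``D_iso``.  ``f_iso`` is derived,
    ``1 - f1 - f2``.  The estimated model shares the axial diffusivity and
    is axially symmetric; ``lambda_par2`` and ``lambda_perp1b``/
    ``lambda_perp2b`` relax those constraints for *simulation-only*
    ground truths (the reference generating values use a second axial
    diffusivity of 1.40e-3 and unequal perpendicular pairs).
    """

    lambda_par: float
    lambda_perp1: float
    lambda_perp2: float
    alpha1: float
    alpha2: float
    alpha3: float
    alpha4: float
    f1: float
    f2: float
    S0: float = 250.0
    sigma: float = 10.0
    D_iso: float = D_ISO_FREE_WATER
    lambda_par2: float | None = None
    lambda_perp1b: float | None = None
    lambda_perp2b: float | None = None

    def __post_init__(self) -> None:
        if self.lambda_par2 is None:
            self.lambda_par2 = self.lambda_par
        if self.lambda_perp1b is None:
            self.lambda_perp1b = self.lambda_perp1
        if self.lambda_perp2b is None:
            self.lambda_perp2b = self.lambda_perp2
        self.validate()

    def validate(self) -> None:
        for name in ("lambda_par", "lambda_par2", "lambda_perp1",
                     "lambda_perp2", "lambda_perp1b", "lambda_perp2b"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        for name in ("alpha1", "alpha2", "alpha3", "alpha4"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.f1 < 0 or self.f2 < 0 or self.f1 + self.f2 > 1 + 1e-12:
            raise ValueError(
                f"fractions must satisfy f1, f2 >= 0 and f1 + f2 <= 1 "
                f"(got f1={self.f1}, f2={self.f2})"
            )
        if self.S0 <= 0 or self.sigma < 0:
            raise ValueError("S0 must be positive and sigma non-negative")
        if abs(self.D_iso - D_ISO_FREE_WATER) > 1e-15:
            raise ValueError("D_iso is fixed to the free-water value 3.0e-3 mm^2/s")

    @property
    def f_iso(self) -> float:
        return 1.0 - self.f1 - self.f2

    @property
    def free_vector(self) -> np.ndarray:
        """The 9 free parameters in estimator order."""
        return np.array([getattr(self, n) for n in FREE_PARAM_NAMES], dtype=float)

    @classmethod
    def from_free_vector(
        cls, theta: np.ndarray, S0: float, sigma: float
    ) -> "DTMParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (9,):
            raise ValueError("free parameter vector must have 9 entries")
        kw = dict(zip(FREE_PARAM_NAMES, theta))
        return cls(S0=S0, sigma=sigma, **kw)

    def swap_labels(self) -> "DTMParams":
        """Exchange the two anisotropic compartments (signal-invariant)."""
        return replace(
            self,
            lambda_par=self.lambda_par2,
            lambda_par2=self.lambda_par,
            lambda_perp1=self.lambda_perp2,
            lambda_perp2=self.lambda_perp1,
            lambda_perp1b=self.lambda_perp2b,
            lambda_perp2b=self.lambda_perp1b,
            f1=self.f2,
            f2=self.f1,
            alpha4=-self.alpha4,
        )


@dataclass(frozen=True)
class TensorTriplet:
    """The two anisotropic tensors plus the isotropic diffusivity."""

    D1: np.ndarray
    D2: np.ndarray
    D_iso_scalar: float = D_ISO_FREE_WATER


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def build_rotation(
    alpha1: float, alpha2: float, alpha3: float, alpha4: float, which: int
) -> np.ndarray:
    """Rotation matrix R_i = Rx(a1) Ry(a2) Rz(a3 +/- a4/2) of tensor ``which``.

    ``which=1`` takes the ``+alpha4/2`` in-plane rotation, ``which=2``
    the ``-alpha4/2`` one, so the two principal axes diverge by alpha4.
    """
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    angles = np.array([alpha1, alpha2, alpha3, alpha4], dtype=float)
    if not np.all(np.isfinite(angles)):
        raise ValueError("rotation angles must be finite")
    sign = 1.0 if which == 1 else -1.0
    return _rx(alpha1) @ _ry(alpha2) @ _rz(alpha3 + sign * alpha4 / 2.0)


def build_tensors(params: DTMParams) -> TensorTriplet:
    """Assemble D_i = R_i^T E_i R_i from the model parameters.

    E_i places the shared axial diffusivity on the local x-axis; the
    (possibly unequal, simulation-only) perpendicular diffusivities sit
    on y and z.
    """
    params.validate()
    tensors = []
    for which, l_par, lp_a, lp_b in (
        (1, params.lambda_par, params.lambda_perp1, params.lambda_perp1b),
        (2, params.lambda_par2, params.lambda_perp2, params.lambda_perp2b),
    ):
        R = build_rotation(params.alpha1, params.alpha2, params.alpha3,
                           params.alpha4, which)
        E = np.diag([l_par, lp_a, lp_b])
        tensors.append(R.T @ E @ R)
    return TensorTriplet(tensors[0], tensors[1], params.D_iso)


def predict_signal(params: DTMParams, scheme: AcquisitionScheme) -> np.ndarray:
    """Noise-free signal S(theta, j) for every measurement of the scheme."""
    triplet = build_tensors(params)
    b = scheme.b_values
    g = scheme.directions
    q1 = np.einsum("ja,ab,jb->j", g, triplet.D1, g)
    q2 = np.einsum("ja,ab,jb->j", g, triplet.D2, g)
    s = params.S0 * (
        params.f1 * np.exp(-b * q1)
        + params.f2 * np.exp(-b * q2)
        + params.f_iso * np.exp(-b * params.D_iso)
    )
    return s


def fractional_anisotropy(eigenvalues) -> float:
    """Standard DTI fractional anisotropy of three positive eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected three eigenvalues")
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError("eigenvalues must be positive and finite")
    a, b, c = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (a - b) ** 2 + (b - c) ** 2 + (a - c) ** 2
    den = a**2 + b**2 + c**2
    return np.sqrt(0.5 * num / den)


# ---------------------------------------------------------------------------
# Vectorized signal + analytic Jacobian over batches of parameter vectors.
# These back the likelihood gradient, the Fisher matrix and the sampler,
# which evaluate the model millions of times.
# ---------------------------------------------------------------------------


def _batch_rotations(a1, a2, gamma):
    """Rx(a1) @ Ry(a2) @ Rz(gamma) and its three angle derivatives.

    All inputs are (n,) arrays; returns four (n, 3, 3) arrays:
    R, dR/da1, dR/da2, dR/dgamma.
    """
    n = a1.shape[0]
    c1, s1 = np.cos(a1), np.sin(a1)
    c2, s2 = np.cos(a2), np.sin(a2)
    c3, s3 = np.cos(gamma), np.sin(gamma)
    z = np.zeros(n)
    o = np.ones(n)

    def mat(rows):
        return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)

    Rx = mat([[o, z, z], [z, c1, -s1], [z, s1, c1]])
    dRx = mat([[z, z, z], [z, -s1, -c1], [z, c1, -s1]])
    Ry = mat([[c2, z, s2], [z, o, z], [-s2, z, c2]])
    dRy = mat([[-s2, z, c2], [z, z, z], [-c2, z, -s2]])
    Rz = mat([[c3, -s3, z], [s3, c3, z], [z, z, o]])
    dRz = mat([[-s3, -c3, z], [c3, -s3, z], [z, z, z]])

    RxRy = Rx @ Ry
    R = RxRy @ Rz
    dR1 = dRx @ Ry @ Rz
    dR2 = Rx @ dRy @ Rz
    dR3 = RxRy @ dRz
    return R, dR1, dR2, dR3


def signal_and_jacobian(
    theta: np.ndarray,
    b_values: np.ndarray,
    directions: np.ndarray,
    S0: float,
    D_iso: float = D_ISO_FREE_WATER,
    want_jacobian: bool = True,
):
    """Model signal and its Jacobian w.r.t. the 9 free parameters.

    Parameters
    ----------
    theta : (n, 9) array
        Batch of free-parameter vectors (see `FREE_PARAM_NAMES`).
    b_values : (Ng,), directions : (Ng, 3)
        Acquisition scheme.
    S0 : scalar or (n,) array
        Unweighted amplitude, shared or per-vector.

    Returns
    -------
    S : (n, Ng) array, and J : (n, Ng, 9) array if ``want_jacobian``.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    n = theta.shape[0]
    S0 = np.asarray(S0, dtype=float)
    if S0.ndim == 1:
        S0 = S0[:, None]
    elif S0.ndim > 1:
        raise ValueError("S0 must be scalar or a 1-D per-vector array")
    b = np.asarray(b_values, dtype=float)
    g = np.asarray(directions, dtype=float)
    ng = b.size

    lpar = theta[:, 0][:, None]
    lperp = (theta[:, 1], theta[:, 2])
    a1, a2, a3, a4 = theta[:, 3], theta[:, 4], theta[:, 5], theta[:, 6]
    f = (theta[:, 7][:, None], theta[:, 8][:, None])
    fiso = 1.0 - theta[:, 7] - theta[:, 8]

    A_iso = np.exp(-b * D_iso)[None, :]  # (1, Ng)
    S = fiso[:, None] * A_iso
    if want_jacobian:
        J = np.empty((n, ng, 9))

    gT = np.ascontiguousarray(g.T)  # (3, Ng)
    A = []
    for i, sign in enumerate((1.0, -1.0)):
        R, dR1, dR2, dR3 = _batch_rotations(a1, a2, a3 + sign * a4 / 2.0)
        u = R @ gT  # (n, 3, Ng)
        ux2 = u[:, 0, :] ** 2
        uperp2 = u[:, 1, :] ** 2 + u[:, 2, :] ** 2
        lp = lperp[i][:, None]
        q = lpar * ux2 + lp * uperp2
        Ai = np.exp(-b * q)
        A.append((Ai, ux2, uperp2))
        S = S + f[i] * Ai
        if want_jacobian:
            fa = f[i] * Ai * (-b)
            # dq/dangle = 2 (E u) . (dR g); E u = (lpar ux, lp uy, lp uz)
            Eu = np.empty_like(u)
            Eu[:, 0, :] = lpar * u[:, 0, :]
            Eu[:, 1, :] = lp * u[:, 1, :]
            Eu[:, 2, :] = lp * u[:, 2, :]
            for k, dR in enumerate((dR1, dR2, dR3)):
                w = dR @ gT  # (n, 3, Ng)
                dq = 2.0 * (Eu * w).sum(axis=1)
                if k < 2:
                    contrib = fa * dq
                    if i == 0:
                        J[:, :, 3 + k] = contrib
                    else:
                        J[:, :, 3 + k] += contrib
                else:
                    # gamma = alpha3 +/- alpha4/2
                    if i == 0:
                        J[:, :, 5] = fa * dq
                        J[:, :, 6] = 0.5 * fa * dq
                    else:
                        J[:, :, 5] += fa * dq
                        J[:, :, 6] += -0.5 * fa * dq
            J[:, :, 1 + i] = fa * uperp2
            J[:, :, 7 + i] = Ai - A_iso

    if want_jacobian:
        J[:, :, 0] = -b * (f[0] * A[0][0] * A[0][1] + f[1] * A[1][0] * A[1][1])
        J *= S0 if S0.ndim == 0 else S0[:, :, None]
        return S0 * S, J
    return S0 * S, None
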