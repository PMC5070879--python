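"""Synthetic multi-shell DWI generation for Monte Carlo experiments.

The default acquisition emulates a 3T HARDI protocol: 92 gradient
directions, homogeneously spread on the sphere by electrostatic
repulsion, reused on two shells (b = 1000 and 3000 s/mm^2), plus two
b = 0 measurements.  Noise is Rician, built as the magnitude of the
noise-free signal plus complex Gaussian noise, with SNR = S0/sigma = 25
by default (S0 = 250, sigma = 10).

The default crossing-fiber ground truth (two tensors sharing axial
diffusivity 1.48e-3 mm^2/s, perpendicular diffusivities 0.15/0.12 and
0.40/0.38 e-3 mm^2/s, in-plane mean orientation alpha3 = 0.8 pi, plane
angles alpha1, alpha2 redrawn uniformly per realization) deliberately
uses unequal perpendicular eigenvalues, a mild misfit with respect to
the axially symmetric estimated model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq, minimize

from .model import AcquisitionScheme, DTMParams, fractional_anisotropy, predict_signal

__all__ = [
    "TABLE_PARAMS",
    "ExperimentConfig",
    "make_scheme",
    "simulate_signal",
    "truth_for_fa",
    "default_crossing_truth",
    "single_fiber_truth",
    "export_dataset",
]

#: Canonical crossing-fiber ground-truth values (diffusivities in mm^2/s).
TABLE_PARAMS = {
    "lambda_1_par": 1.480e-3,
    "lambda_1_perp1": 0.15e-3,
    "lambda_1_perp2": 0.12e-3,
    "lambda_2_par": 1.400e-3,
    "lambda_2_perp1": 0.40e-3,
    "lambda_2_perp2": 0.38e-3,
    "alpha3": 0.8 * np.pi,
    "f_iso": 0.1,
    "D_iso": 3.0e-3,
    "S0": 250.0,
    "sigma": 10.0,
}


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _repulsion_directions(n: int, maxiter: int = 150) -> np.ndarray:
    """Quasi-uniform unit directions by Coulomb-energy minimization.

    Points are parameterized by spherical angles and refined from a
    Fibonacci-sphere start; fully deterministic.
    """
    x0 = _fibonacci_sphere(n)
    ang0 = np.column_stack([np.arccos(np.clip(x0[:, 2], -1, 1)),
                            np.arctan2(x0[:, 1], x0[:, 0])]).ravel()

    def energy(ang):
        a = ang.reshape(n, 2)
        st = np.sin(a[:, 0])
        pts = np.column_stack([st * np.cos(a[:, 1]), st * np.sin(a[:, 1]),
                               np.cos(a[:, 0])])
        diff = pts[:, None, :] - pts[None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        iu = np.triu_indices(n, k=1)
        return np.sum(1.0 / np.sqrt(d2[iu]))

    res = minimize(energy, ang0, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    a = res.x.reshape(n, 2)
    st = np.sin(a[:, 0])
    pts = np.column_stack([st * np.cos(a[:, 1]), st * np.sin(a[:, 1]),
                           np.cos(a[:, 0])])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


_SCHEME_CACHE: dict = {}


def make_scheme(
    dirs_per_shell: int = 92,
    b_shells=(1000.0, 3000.0),
    n_b0: int = 2,
) -> AcquisitionScheme:
    """Multi-shell scheme with one shared, repulsion-optimized direction set.

    b=0 measurements come first (direction set to +z, ignored), then the
    shells in the order given, each reusing the same directions.
    """
    if dirs_per_shell < 6:
        raise ValueError("need at least 6 directions per shell")
    key = int(dirs_per_shell)
    if key not in _SCHEME_CACHE:
        _SCHEME_CACHE[key] = _repulsion_directions(dirs_per_shell)
    dirs = _SCHEME_CACHE[key]
    b_values = [np.zeros(n_b0)]
    directions = [np.tile([0.0, 0.0, 1.0], (n_b0, 1))]
    for b in b_shells:
        b_values.append(np.full(dirs_per_shell, float(b)))
        directions.append(dirs)
    return AcquisitionScheme(np.concatenate(b_values), np.vstack(directions))


def simulate_signal(
    truth: DTMParams, scheme: AcquisitionScheme, sigma: float, rng
) -> np.ndarray:
    """Rician-noisy signal: |S + n1 + i n2| with n1, n2 ~ N(0, sigma^2)."""
    s = predict_signal(truth, scheme)
    if sigma == 0:
        return s
    n1 = rng.normal(scale=sigma, size=s.shape)
    n2 = rng.normal(scale=sigma, size=s.shape)
    return np.hypot(s + n1, n2)


def truth_for_fa(target_fa: float, lambda_par: float = 1.48e-3) -> np.ndarray:
    """Axially symmetric eigenvalues (lambda_par, lp, lp) with the given FA.

    Solves FA = (lambda_par - lp) / sqrt(lambda_par^2 + 2 lp^2) for the
    perpendicular diffusivity lp in (0, lambda_par).
    """
    if not 0 < target_fa < 1:
        raise ValueError("target FA must be in (0, 1)")
    # FA of (lp, l, l) ranges over (0, 1/sqrt(2)... ) check attainability:
    # as lp -> 0, FA -> 1; as lp -> lambda_par, FA -> 0.

    def f(lp):
        return fractional_anisotropy([lambda_par, lp, lp]) - target_fa

    lo, hi = 1e-12 * lambda_par, lambda_par * (1 - 1e-12)
    lp = brentq(f, lo, hi, xtol=1e-18, rtol=8.9e-16)
    return np.array([lambda_par, lp, lp])


def default_crossing_truth(
    f1: float,
    alpha4: float,
    alpha1: float = 0.0,
    alpha2: float = 0.0,
    f_iso: float = 0.1,
) -> DTMParams:
    """Crossing-fiber ground truth; f2 fills up to 1 - f1 - f_iso."""
    t = TABLE_PARAMS
    return DTMParams(
        lambda_par=t["lambda_1_par"],
        lambda_par2=t["lambda_2_par"],
        lambda_perp1=t["lambda_1_perp1"],
        lambda_perp2=t["lambda_2_perp1"],
        lambda_perp1b=t["lambda_1_perp2"],
        lambda_perp2b=t["lambda_2_perp2"],
        alpha1=alpha1,
        alpha2=alpha2,
        alpha3=t["alpha3"],
        alpha4=alpha4,
        f1=f1,
        f2=1.0 - f1 - f_iso,
        S0=t["S0"],
        sigma=t["sigma"],
    )


def single_fiber_truth(
    target_fa: float,
    f1: float = 0.9,
    alpha1: float = 0.0,
    alpha2: float = 0.0,
) -> DTMParams:
    """One axially symmetric fiber (fraction f1) plus free water (rest).

    The second compartment keeps the canonical crossing shape but has
    zero volume fraction; it exists only so tensor matching has a
    reference.
    """
    lam = truth_for_fa(target_fa)
    t = TABLE_PARAMS
    return DTMParams(
        lambda_par=lam[0],
        lambda_par2=t["lambda_2_par"],
        lambda_perp1=lam[1],
        lambda_perp2=t["lambda_2_perp1"],
        lambda_perp2b=t["lambda_2_perp2"],
        alpha1=alpha1,
        alpha2=alpha2,
        alpha3=t["alpha3"],
        alpha4=np.pi / 2,
        f1=f1,
        f2=0.0,
        S0=t["S0"],
        sigma=t["sigma"],
    )


@dataclass
class ExperimentConfig:
    """One Monte Carlo sweep: a swept truth parameter and noise settings."""

    sweep_name: str
    sweep_values: tuple
    n_realizations: int = 100
    sigma: float = 10.0
    dirs_per_shell: int = 92
    b_shells: tuple = (1000.0, 3000.0)
    n_b0: int = 2
    base_seed: int = 0
    alpha4: float = np.pi / 2
    n_mcmc: int = 5000
    n_burn_in: int = 2000
    mle_restarts: int = 5

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.sweep_name not in ("f1", "fa", "alpha4"):
            raise ValueError("sweep_name must be one of 'f1', 'fa', 'alpha4'")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Load a config from a YAML key-value file.

        Recognized keys are the dataclass fields (`sweep_name`,
        `sweep_values`, `n_realizations`, `sigma`, `dirs_per_shell`,
        `b_shells`, `n_b0`, `base_seed`, `alpha4`, `n_mcmc`,
        `n_burn_in`, `mle_restarts`); list values become tuples.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("sweep_values", "b_shells"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def scheme(self) -> AcquisitionScheme:
        return make_scheme(self.dirs_per_shell, self.b_shells, self.n_b0)

    def truth(self, sweep_value: float, alpha1: float, alpha2: float) -> DTMParams:
        if self.sweep_name == "f1":
            p = default_crossing_truth(sweep_value, self.alpha4, alpha1, alpha2)
        elif self.sweep_name == "alpha4":
            p = default_crossing_truth(0.4, sweep_value, alpha1, alpha2)
        else:
            p = single_fiber_truth(sweep_value, alpha1=alpha1, alpha2=alpha2)
        return replace(p, sigma=self.sigma)


def export_dataset(
    truths: list[DTMParams],
    scheme: AcquisitionScheme,
    signals: np.ndarray,
    out_dir,
    prefix: str = "synthetic",
) -> dict:
    """Write a simulated dataset as NIfTI + FSL bval/bvec + truth CSV.

    The volume is laid out 1 x 1 x n_voxels x Ng.  Returns the paths.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    signals = np.atleast_2d(signals)
    n_vox, ng = signals.shape
    img = nib.Nifti1Image(
        signals.reshape(1, 1, n_vox, ng).astype(np.float32), affine=np.eye(4)
    )
    dwi_path = out / f"{prefix}.nii.gz"
    nib.save(img, dwi_path)

    bval_path = out / f"{prefix}.bval"
    bvec_path = out / f"{prefix}.bvec"
    np.savetxt(bval_path, scheme.b_values[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.directions.T, fmt="%.8f")

    truth_path = out / f"{prefix}_truth.csv"
    with open(truth_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = [
            "lambda_par", "lambda_perp1", "lambda_perp2",
            "alpha1", "alpha2", "alpha3", "alpha4", "f1", "f2", "S0", "sigma",
        ]
        writer.writerow(["voxel"] + header)
        for i, p in enumerate(truths):
            writer.writerow([i] + list(p.free_vector) + [p.S0, p.sigma])
    return {
        "dwi": dwi_path,
        "bval": bval_path,
        "bvec": bvec_path,
        "truth": truth_path,
    }
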