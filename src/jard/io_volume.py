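"""NIfTI / FSL-gradient-table plumbing for whole-volume fitting.

Reads a 4-D diffusion-weighted volume with FSL-style bval/bvec text
files (row- or column-major, auto-detected) into a flat (voxel,
measurement) array plus an `AcquisitionScheme`, and writes per-voxel
parameter, volume-fraction, FA and CRLB maps back onto the input grid.
Voxel iteration order is lexicographic in index space, so seeded
per-voxel sampling is reproducible regardless of how the work is split.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .model import AcquisitionScheme, DTMParams, fractional_anisotropy
from .prior import crlb_sd

__all__ = ["VoxelDataset", "load_dataset", "write_maps", "fit_volume"]


@dataclass
class VoxelDataset:
    """Masked voxel signals plus acquisition and grid metadata."""

    signals: np.ndarray  # (n_voxels, Ng), masked voxels only
    scheme: AcquisitionScheme
    mask: np.ndarray  # 3-D bool
    affine: np.ndarray
    shape: tuple

    def __post_init__(self) -> None:
        if self.signals.shape[1] != self.scheme.n_measurements:
            raise ValueError("signal measurement axis does not match scheme")
        if self.signals.shape[0] != int(self.mask.sum()):
            raise ValueError("signal voxel count does not match mask")

    @property
    def voxel_indices(self) -> np.ndarray:
        """Masked voxel coordinates in deterministic lexicographic order."""
        return np.argwhere(self.mask)


def _read_table(path) -> np.ndarray:
    try:
        rows = [
            [float(x) for x in line.split()]
            for line in Path(path).read_text().splitlines()
            if line.strip()
        ]
    except ValueError as exc:
        raise ValueError(f"malformed numeric entry in {path}: {exc}") from exc
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged rows in {path}")
    return np.asarray(rows)


def load_dataset(dwi_path, bval_path, bvec_path, mask_path=None) -> VoxelDataset:
    """Load a 4-D NIfTI volume with its gradient table.

    bvecs may be 3 x Ng or Ng x 3; non-unit non-zero directions are
    normalized with a warning if they deviate by more than 1e-3.
    """
    img = nib.load(str(dwi_path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"{dwi_path}: expected 4-D volume, got {data.ndim}-D")
    ng = data.shape[3]

    bvals = _read_table(bval_path).ravel()
    if bvals.size != ng:
        raise ValueError(
            f"{bval_path}: {bvals.size} b-values but volume has {ng} measurements"
        )
    bvecs = _read_table(bvec_path)
    if bvecs.shape == (3, ng):
        bvecs = bvecs.T
    elif bvecs.shape != (ng, 3):
        raise ValueError(
            f"{bvec_path}: shape {bvecs.shape} matches neither 3x{ng} nor {ng}x3"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dwi = bvals > 0
    bad = dwi & (np.abs(norms - 1.0) > 1e-3)
    if np.any(bad):
        import warnings

        warnings.warn(
            f"{int(bad.sum())} non-unit gradient directions (max deviation "
            f"{np.abs(norms[bad] - 1).max():.2e}); normalizing",
            RuntimeWarning,
            stacklevel=2,
        )
    safe = np.where(norms > 0, norms, 1.0)
    bvecs = bvecs / safe[:, None]
    bvecs[~dwi] = [0.0, 0.0, 1.0]  # placeholder; ignored at b=0

    scheme = AcquisitionScheme(bvals, bvecs)
    if mask_path is not None:
        mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask grid does not match DWI grid")
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    signals = data[mask]
    return VoxelDataset(
        signals=signals,
        scheme=scheme,
        mask=mask,
        affine=img.affine,
        shape=data.shape[:3],
    )


_MAP_FIELDS = (
    "f1", "f2", "f_iso", "fa1", "fa2",
    "lambda_par", "lambda_perp1", "lambda_perp2",
)


def write_maps(estimates, template: VoxelDataset, out_dir, crlb=None) -> dict:
    """Write per-voxel estimates as NIfTI maps on the template grid.

    ``estimates`` is a sequence of `DTMParams`, one per masked voxel in
    the template's lexicographic order.  Unmasked voxels are NaN.
    Optionally ``crlb`` is an (n_voxels, 9) array of CRLB SDs written as
    one map per parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = int(template.mask.sum())
    if len(estimates) != n:
        raise ValueError(f"{len(estimates)} estimates for {n} masked voxels")

    def blank():
        return np.full(template.shape, np.nan, dtype=np.float32)

    maps = {name: blank() for name in _MAP_FIELDS}
    idx = template.voxel_indices
    for (i, j, k), p in zip(idx, estimates):
        vals = {
            "f1": p.f1,
            "f2": p.f2,
            "f_iso": p.f_iso,
            "fa1": fractional_anisotropy(
                [p.lambda_par, p.lambda_perp1, p.lambda_perp1]
            ),
            "fa2": fractional_anisotropy(
                [p.lambda_par, p.lambda_perp2, p.lambda_perp2]
            ),
            "lambda_par": p.lambda_par,
            "lambda_perp1": p.lambda_perp1,
            "lambda_perp2": p.lambda_perp2,
        }
        for name, v in vals.items():
            maps[name][i, j, k] = v
    if crlb is not None:
        crlb = np.asarray(crlb)
        from .model import FREE_PARAM_NAMES

        for col, pname in enumerate(FREE_PARAM_NAMES):
            m = blank()
            for (i, j, k), v in zip(idx, crlb[:, col]):
                m[i, j, k] = v
            maps[f"crlb_sd_{pname}"] = m

    paths = {}
    for name, arr in maps.items():
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr, template.affine), p)
        paths[name] = p
    return paths


def fit_volume(
    dataset: VoxelDataset,
    sigma: float,
    n_samples: int = 5000,
    n_burn_in: int = 2000,
    base_seed: int = 0,
    method: str = "jard",
    with_crlb: bool = False,
    progress: bool = False,
):
    """Fit every masked voxel; returns (estimates, crlb or None).

    Voxel k uses seed ``base_seed + k`` for its chain, so results do not
    depend on how voxels are batched.
    """
    from .mcmc import run_jard_batch
    from .mle import fit_mle

    estimates = []
    inits = []
    iterator = range(dataset.signals.shape[0])
    if progress:
        from tqdm import tqdm  # type: ignore

        iterator = tqdm(iterator, desc="MLE")
    for k in iterator:
        res = fit_mle(
            dataset.signals[k], dataset.scheme, sigma, seed=base_seed + k
        )
        inits.append(res.params)
    if method == "mle":
        estimates = inits
    else:
        theta = np.array([p.free_vector for p in inits])
        est, _ = run_jard_batch(
            dataset.signals,
            dataset.scheme,
            sigma,
            theta,
            S0=float(np.mean([p.S0 for p in inits])),
            n_samples=n_samples,
            n_burn_in=n_burn_in,
            seed=base_seed,
        )
        estimates = [
            DTMParams.from_free_vector(e, S0=inits[i].S0, sigma=sigma)
            for i, e in enumerate(est)
        ]
    crlb = None
    if with_crlb:
        crlb = np.array(
            [crlb_sd(p, dataset.scheme, sigma) for p in estimates]
        )
    return estimates, crlb
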