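"""Whole-volume plumbing: simulate a small NIfTI dataset, fit it, write maps.

Exports a 6-voxel synthetic acquisition as NIfTI + FSL bval/bvec files,
reads it back through the volume loader, fits every voxel (MLE followed
by the ARD posterior mean) and writes volume-fraction / FA / diffusivity
maps plus per-parameter Cramer-Rao bounds.
"""

import tempfile
from pathlib import Path

import numpy as np

from jard.io_volume import fit_volume, load_dataset, write_maps
from jard.synthetic import (
    default_crossing_truth,
    export_dataset,
    make_scheme,
    simulate_signal,
)

workdir = Path(tempfile.mkdtemp(prefix="dtm_example_"))
scheme = make_scheme()
rng = np.random.default_rng(0)
truths, signals = [], []
for _ in range(6):
    t = default_crossing_truth(f1=0.45, alpha4=np.pi / 2, alpha1=rng.uniform(0, np.pi))
    truths.append(t)
    signals.append(simulate_signal(t, scheme, t.sigma, rng))
paths = export_dataset(truths, scheme, np.array(signals), workdir)
print("exported:", ", ".join(p.name for p in paths.values()))

dataset = load_dataset(paths["dwi"], paths["bval"], paths["bvec"])
estimates, crlb = fit_volume(
    dataset, sigma=10.0, n_samples=1500, n_burn_in=600, with_crlb=True
)
maps = write_maps(estimates, dataset, workdir / "maps", crlb=crlb)
print(f"wrote {len(maps)} NIfTI maps to {workdir / 'maps'}")
for i, p in enumerate(estimates[:3]):
    print(
        f"voxel {i}: f = ({p.f1:.2f}, {p.f2:.2f}, {p.f_iso:.2f}) "
        f"truth (0.45, 0.45, 0.10); CRLB SD of f1 = {crlb[i][7]:.3f}"
    )

# Both fractions should sit near 0.45: a genuine 90-degree crossing is
# well supported by this acquisition, so the prior leaves it alone.
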