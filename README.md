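# jard — dual-tensor diffusion MRI with a data-acquisition-adaptive ARD prior

`jard` estimates the parameters of a constrained **dual tensor model**
(DTM) of the diffusion-weighted MR signal in every voxel: two rank-2
anisotropic tensors for crossing fiber bundles plus an isotropic
free-water compartment,

```
S(θ, j) = S0 · Σ_{i ∈ {1,2,iso}} f_i · exp(−b_j g_jᵀ D_i g_j),
f1 + f2 + f_iso = 1,
```

with shared axial diffusivity λ∥, axially symmetric tensors
(λ_{i,⊥}), D_iso fixed to free water (3.0×10⁻³ mm²/s) and orientations
parameterized as R_i = Rx(α1)·Ry(α2)·Rz(α3 ± α4/2), so α4 is the
crossing angle.  Nine parameters are free:
θ = (λ∥, λ1⊥, λ2⊥, α1…α4, f1, f2).

Fitting a dual tensor to a voxel that contains only **one** fiber is a
classic overfitting trap: maximum likelihood happily invents a second
compartment with a sizable volume fraction.  `jard` solves this with
**automatic relevance determination**: after a Rician maximum-likelihood
fit (used as initialization), a Metropolis–Hastings sampler draws from
the posterior

```
p(θ | S̃) ∝ p(S̃ | θ) · det I(θ)^(−1/2),
```

where `I(θ)` is the Fisher information matrix of the Rician measurement
model for the actual acquisition (gradient scheme, b-values, SNR).  The
determinant collapses whenever the data cannot support both tensors —
a vanishing fraction, or two coinciding compartments — so the prior
probability rises there and the posterior mean pushes the unsupported
volume fraction to zero.  Because `I(θ)` is built from the acquisition
itself, the prior automatically adapts: fewer directions or a lower SNR
make it collapse compartments sooner.

Intended users: diffusion-MRI methods researchers who need per-voxel
diffusion *shape* estimates (volume fractions, per-compartment FA,
diffusivities) that degrade gracefully from crossing-fiber to
single-fiber anatomy, plus a simulator for validating estimators under
controlled conditions.

## Worked example

```python
import numpy as np
from jard import fit_mle, make_scheme, run_jard, simulate_signal
from jard.synthetic import default_crossing_truth

scheme = make_scheme()          # 92 dirs × b={1000,3000} s/mm² + 2 b0
rng = np.random.default_rng(14)
a1, a2 = rng.uniform(0, np.pi, 2)
truth = default_crossing_truth(f1=0.0, alpha4=np.pi/4,    # true f1 = 0:
                               alpha1=a1, alpha2=a2)      # one fiber only
signal = simulate_signal(truth, scheme, truth.sigma, rng) # SNR 25

mle = fit_mle(signal, scheme, sigma=truth.sigma, seed=0)
chain, ard = run_jard(signal, scheme, truth.sigma, mle.params, seed=0)
```

prints (`examples/02_single_voxel_fit.py`):

```
truth: f = (0.00, 0.90), one fiber + free water
MLE : f = (0.44, 0.56), log-likelihood = -673.5
ARD : f = (0.04, 0.94), acceptance rate = 0.13
ARD dominant-tensor FA = 0.67 (true 0.67)
```

The voxel contains one fiber, yet the maximum-likelihood fit splits the
anisotropic volume almost evenly between two tensors — a fictitious
crossing.  The ARD posterior mean collapses the unsupported compartment
to f ≈ 0.04 and concentrates the volume (and the correct FA of 0.67) in
the real fiber.  More narrative scripts live in `examples/`: the signal
model, the prior landscape, a small Monte Carlo comparison, and NIfTI
volume-fitting round trips.

A thin CLI wraps the same functions for shell use:

```bash
jard simulate --n-voxels 10 --f1 0.3 --out-dir data/
jard fit-jard data/synthetic.nii.gz data/synthetic.bval data/synthetic.bvec \
     --sigma 10 --out-dir maps/
jard experiment vf-sweep --fast --out-dir sweep/
```

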