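"""Metropolis-Hastings sampling of the dual tensor posterior.

The posterior is the Rician likelihood times the Fisher-determinant ARD
prior (both evaluated in log space).  Proposals are an isotropic
Gaussian random walk on the 9 natural parameters with fixed,
per-parameter step sizes: 1e-5 mm^2/s for the three diffusivities,
1e-2 rad for the four angles and 1e-2 for the two fractions.  Proposals
leaving the parameter domain (non-positive diffusivities, fractions
outside the eps-interior of the simplex) have zero posterior and are
always rejected; the kernel stays symmetric so detailed balance holds.

The point estimate is the arithmetic mean of the chain states inside
the retention window (repeats after rejections included).  By default
the window is measured in accepted transitions -- burn-in ends after
n_burn_in acceptances and the window closes at n_samples acceptances --
with a proposal-counting mode available (see `run_jard_batch`).  Every
step consumes nine normals and one uniform from the voxel's generator,
whether or not the uniform is needed for the accept decision, so the
sequential and the vectorized multi-voxel samplers are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import rician_log_pdf
from .model import AcquisitionScheme, DTMParams, signal_and_jacobian
from .prior import log_prior_batch, log_prior_from_jacobian

__all__ = [
    "DEFAULT_STEP_SIZES",
    "PosteriorChain",
    "propose",
    "metropolis_hastings",
    "run_jard",
    "run_jard_batch",
    "posterior_summary",
]

#: Fixed random-walk step sizes for
#: [lambda_par, lambda_perp1, lambda_perp2, alpha1..4, f1, f2].
DEFAULT_STEP_SIZES = np.array(
    [1e-5, 1e-5, 1e-5, 1e-2, 1e-2, 1e-2, 1e-2, 1e-2, 1e-2]
)

#: Fractions are kept this far inside the simplex so likelihood and
#: prior stay finite.
FRACTION_EPS = 1e-6


@dataclass
class PosteriorChain:
    """MCMC output for one voxel: states theta_1..theta_N plus bookkeeping."""

    states: np.ndarray  # (N, 9)
    accepted: np.ndarray  # (N,) bool
    n_burn_in: int
    seed: int | None
    log_posterior: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        if self.n_burn_in >= len(self.states):
            raise ValueError("burn-in must be shorter than the chain")

    @property
    def n_samples(self) -> int:
        return len(self.states)

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    def posterior_mean(self, unique_accepted: bool = False) -> np.ndarray:
        """Mean of post-burn-in states (default), or of unique accepted states."""
        tail = self.states[self.n_burn_in :]
        if unique_accepted:
            keep = self.accepted[self.n_burn_in :]
            if not np.any(keep):
                return tail[-1].copy()
            return tail[keep].mean(axis=0)
        return tail.mean(axis=0)


def in_domain(theta: np.ndarray, eps: float = FRACTION_EPS) -> np.ndarray:
    """Validity mask of (n, 9) proposals under the positivity/simplex rules."""
    theta = np.atleast_2d(theta)
    f1, f2 = theta[:, 7], theta[:, 8]
    return (
        (theta[:, 0] > 0)
        & (theta[:, 1] > 0)
        & (theta[:, 2] > 0)
        & (f1 >= eps)
        & (f2 >= eps)
        & (f1 + f2 <= 1.0 - eps)
    )


def propose(theta_t: np.ndarray, step_sizes: np.ndarray, rng) -> np.ndarray:
    """Symmetric Gaussian random-walk proposal theta_t + Delta * N(0,1)."""
    step = np.asarray(step_sizes, dtype=float)
    if np.any(step < 0):
        raise ValueError("step sizes must be non-negative")
    return np.asarray(theta_t, dtype=float) + step * rng.standard_normal(
        np.shape(theta_t)
    )


def metropolis_hastings(
    log_post,
    x0: np.ndarray,
    step_sizes: np.ndarray,
    n_samples: int,
    rng,
    valid=None,
):
    """Generic random-walk Metropolis sampler (single chain).

    ``log_post`` maps a state vector to its unnormalized log posterior;
    ``valid`` (optional) is a domain predicate; invalid proposals are
    rejected outright.  Returns (states, accepted, log_post_trace).
    """
    x = np.array(x0, dtype=float)
    d = x.size
    lp = float(log_post(x))
    if not np.isfinite(lp):
        raise ValueError("log posterior is not finite at the initial state")
    states = np.empty((n_samples, d))
    accepted = np.zeros(n_samples, dtype=bool)
    trace = np.empty(n_samples)
    step = np.asarray(step_sizes, dtype=float)
    for t in range(n_samples):
        prop = x + step * rng.standard_normal(d)
        u = rng.uniform()
        ok = True if valid is None else bool(valid(prop))
        if ok:
            lp_prop = float(log_post(prop))
            # alpha >= 1 accepts; else accept iff u <= alpha
            if lp_prop >= lp or u <= np.exp(lp_prop - lp):
                x, lp = prop, lp_prop
                accepted[t] = True
        states[t] = x
        trace[t] = lp
    return states, accepted, trace


def run_jard_batch(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    sigma: float,
    theta_inits: np.ndarray,
    S0: float,
    n_samples: int = 5000,
    n_burn_in: int = 2000,
    step_sizes: np.ndarray | None = None,
    seed: int = 0,
    prior: str = "fisher",
    exact_information: bool = True,
    keep_chains: bool = False,
    count: str = "accepted",
    max_steps: int | None = None,
):
    """Vectorized JARD sampling of many voxels that share one scheme.

    ``signals`` is (n_voxels, Ng), ``theta_inits`` (n_voxels, 9).  Voxel
    k uses its own generator seeded ``seed + k``, so results match
    per-voxel sequential runs and are independent of batching.

    ``count`` controls how chain length is measured: with
    ``"accepted"`` (default) the burn-in ends after ``n_burn_in``
    accepted transitions and the retention window closes at
    ``n_samples`` accepted transitions, the estimate being the mean of
    all states inside the window; with ``"proposals"`` the window is
    simply steps ``n_burn_in..n_samples-1``.  Chains stop early once
    their window closes; ``max_steps`` (default ``4 * n_samples``)
    bounds the total proposals for chains whose acceptance stalls.

    Returns (estimates (n_voxels, 9), acceptance_rates (n_voxels,)) and,
    if ``keep_chains``, the per-step states, accept flags and log
    posterior up to the last step any chain was active.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    theta = np.array(np.atleast_2d(theta_inits), dtype=float)
    n_vox = signals.shape[0]
    if theta.shape != (n_vox, 9):
        raise ValueError("theta_inits must be (n_voxels, 9)")
    if count not in ("accepted", "proposals"):
        raise ValueError("count must be 'accepted' or 'proposals'")
    if n_burn_in >= n_samples:
        raise ValueError("burn-in must be shorter than the chain")
    step = DEFAULT_STEP_SIZES if step_sizes is None else np.asarray(step_sizes)
    if max_steps is None:
        max_steps = n_samples if count == "proposals" else 4 * n_samples

    # clamp initial fractions into the sampling domain
    theta[:, 7:9] = np.clip(theta[:, 7:9], FRACTION_EPS, None)
    over = theta[:, 7] + theta[:, 8] > 1.0 - FRACTION_EPS
    theta[over, 7:9] *= (1.0 - FRACTION_EPS) / theta[over, 7:9].sum(
        axis=1, keepdims=True
    )

    rngs = [np.random.default_rng(seed + k) for k in range(n_vox)]
    fisher_prior = prior in ("fisher", "jeffreys")

    def logpost(th):
        nu, J = signal_and_jacobian(
            th, scheme.b_values, scheme.directions, S0,
            want_jacobian=fisher_prior,
        )
        ll = rician_log_pdf(signals, np.clip(nu, 0.0, None), sigma).sum(axis=1)
        if fisher_prior:
            pr = log_prior_from_jacobian(
                nu, J, sigma, kind=prior, exact=exact_information
            )
        else:
            pr = log_prior_batch(th, scheme, S0, sigma, kind=prior)
        return ll + pr

    lp = logpost(theta)
    if not np.all(np.isfinite(lp)):
        raise ValueError("log posterior not finite at an initial state")

    running_sum = np.zeros((n_vox, 9))
    n_kept = np.zeros(n_vox)
    tail_sum = np.zeros((n_vox, 9))  # fallback for stalled chains
    tail_kept = 0
    accept_count = np.zeros(n_vox, dtype=int)
    steps_taken = np.zeros(n_vox, dtype=int)
    active = np.ones(n_vox, dtype=bool)
    if keep_chains:
        chains, accepted_rec, lp_rec = [], [], []

    normals = np.empty((n_vox, 9))
    uniforms = np.empty(n_vox)
    for t in range(max_steps):
        if not np.any(active):
            break
        for k in np.flatnonzero(active):
            normals[k] = rngs[k].standard_normal(9)
            uniforms[k] = rngs[k].uniform()
        prop = np.where(active[:, None], theta + step * normals, theta)
        ok = in_domain(prop) & active
        safe = np.where(ok[:, None], prop, theta)
        lp_prop = logpost(safe)
        with np.errstate(over="ignore"):
            accept = ok & (
                (lp_prop >= lp) | (uniforms <= np.exp(np.minimum(lp_prop - lp, 0)))
            )
        theta[accept] = prop[accept]
        lp[accept] = lp_prop[accept]
        accept_count += accept
        steps_taken += active
        if keep_chains:
            chains.append(theta.copy())
            accepted_rec.append(accept.copy())
            lp_rec.append(lp.copy())
        if count == "proposals":
            in_window = active & (t >= n_burn_in)
            active &= t + 1 < n_samples
        else:
            in_window = active & (accept_count > n_burn_in)
            active &= accept_count < n_samples
        running_sum[in_window] += theta[in_window]
        n_kept += in_window
        if t >= max_steps // 2:
            tail_sum += theta
            tail_kept += 1

    # chains whose retention window never opened (acceptance stalled at a
    # sticky mode before n_burn_in acceptances) fall back to the mean
    # over the second half of their run
    stalled = n_kept == 0
    if np.any(stalled) and tail_kept > 0:
        running_sum[stalled] = tail_sum[stalled]
        n_kept[stalled] = tail_kept
    elif np.any(stalled):
        running_sum[stalled] = theta[stalled]
        n_kept[stalled] = 1
    estimates = running_sum / n_kept[:, None]
    rates = accept_count / np.maximum(steps_taken, 1)
    if keep_chains:
        return (
            estimates,
            rates,
            np.swapaxes(np.array(chains), 0, 1),
            np.swapaxes(np.array(accepted_rec), 0, 1),
            np.swapaxes(np.array(lp_rec), 0, 1),
        )
    return estimates, rates


def run_jard(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    sigma: float,
    theta_init: DTMParams,
    n_samples: int = 5000,
    n_burn_in: int = 2000,
    step_sizes: np.ndarray | None = None,
    seed: int = 0,
    prior: str = "fisher",
    exact_information: bool = True,
    unique_accepted_mean: bool = False,
    count: str = "accepted",
    max_steps: int | None = None,
):
    """Posterior-mean (ARD) estimate for one voxel.

    Initialization is normally the MLE fit.  Returns the `PosteriorChain`
    and the estimate as a `DTMParams`.
    """
    signal = np.asarray(signal, dtype=float)
    est, rates, chains, accepted, lp_rec = run_jard_batch(
        signal[None, :],
        scheme,
        sigma,
        theta_init.free_vector[None, :],
        S0=theta_init.S0,
        n_samples=n_samples,
        n_burn_in=n_burn_in,
        step_sizes=step_sizes,
        seed=seed,
        prior=prior,
        exact_information=exact_information,
        keep_chains=True,
        count=count,
        max_steps=max_steps,
    )
    if count == "accepted":
        # chain index at which the burn-in window (counted in accepted
        # transitions) ended
        reached = np.flatnonzero(np.cumsum(accepted[0]) > n_burn_in)
        nb_idx = int(reached[0]) if reached.size else len(chains[0]) - 1
    else:
        nb_idx = n_burn_in
    chain = PosteriorChain(
        states=chains[0],
        accepted=accepted[0],
        n_burn_in=nb_idx,
        seed=seed,
        log_posterior=lp_rec[0],
    )
    mean = (
        chain.posterior_mean(unique_accepted=True)
        if unique_accepted_mean
        else est[0]
    )
    params = DTMParams.from_free_vector(mean, S0=theta_init.S0, sigma=sigma)
    return chain, params


def posterior_summary(chain: PosteriorChain) -> dict:
    """Per-parameter posterior mean and SD plus the acceptance rate."""
    tail = chain.states[chain.n_burn_in :]
    return {
        "mean": tail.mean(axis=0),
        "sd": tail.std(axis=0, ddof=0),
        "acceptance_rate": chain.acceptance_rate,
        "n_burn_in": chain.n_burn_in,
        "n_samples": chain.n_samples,
    }
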