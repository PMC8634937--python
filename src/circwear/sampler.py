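"""Affine-invariant ensemble MCMC with the Goodman-Weare stretch move.

An ensemble of walkers explores the target; each walker proposes a move
along the line through itself and a randomly chosen walker of the
complementary half-ensemble, with stretch factor z drawn with density
proportional to 1/sqrt(z) on [1/a, a] and acceptance probability
min(1, z^(d-1) * p(proposal)/p(current)).  The update alternates between
the two half-ensembles so complementary walkers are fixed within a half
step, which keeps the chain valid under vectorized evaluation.

The sampler is fully deterministic given a seed, and the log target is
always called on a (walkers, dim) matrix so likelihoods can vectorize.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gw_ensemble_sample"]


def _draw_z(rng: np.random.Generator, n: int, a: float) -> np.ndarray:
    # inverse-CDF sample of g(z) ∝ 1/sqrt(z) on [1/a, a]
    u = rng.random(n)
    return ((u * (a - 1.0) + 1.0) ** 2) / a


def gw_ensemble_sample(log_target, init: np.ndarray, n_total_evals: int,
                       stretch_a: float = 2.0, seed: int = 0,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Run the stretch-move sampler.

    Parameters
    ----------
    log_target
        Callable mapping a (k, dim) array to a length-k array of log
        densities (may be -inf).
    init
        (n_walkers, dim) starting ensemble; n_walkers must be at least
        2*dim and even, and the walkers must not be all identical.
    n_total_evals
        Total number of target evaluations; one step evaluates every
        walker once, so the chain runs n_total_evals // n_walkers steps.
    stretch_a
        Stretch scale a > 1 (2 is the standard choice).
    seed
        Seed for the private random generator; fixes the run exactly.

    Returns
    -------
    chain : (n_steps, n_walkers, dim) array of walker positions.
    logp : (n_steps, n_walkers) array of log densities.
    """
    init = np.array(init, dtype=float)
    n_walkers, dim = init.shape
    if n_walkers < 2 * dim:
        raise ValueError(f"need at least {2 * dim} walkers for dim {dim}")
    if n_walkers % 2:
        raise ValueError("n_walkers must be even")
    if np.allclose(init, init[0]):
        raise ValueError("initial walkers must not be all identical")
    if stretch_a <= 1:
        raise ValueError("stretch_a must exceed 1")
    n_steps = n_total_evals // n_walkers
    if n_steps < 1:
        raise ValueError("n_total_evals smaller than one full step")

    rng = np.random.Generator(np.random.PCG64(seed))
    pos = init.copy()
    logp = np.asarray(log_target(pos), dtype=float)
    if not np.any(np.isfinite(logp)):
        raise ValueError("log target non-finite at every initial walker")
    # walkers starting at -inf are nudged toward the best walker until finite
    bad = ~np.isfinite(logp)
    tries = 0
    while np.any(bad):
        best = pos[np.argmax(logp)]
        pos[bad] = 0.5 * (pos[bad] + best) + 1e-8 * rng.standard_normal(
            (int(bad.sum()), dim))
        logp[bad] = log_target(pos[bad])
        bad = ~np.isfinite(logp)
        tries += 1
        if tries > 100:
            raise ValueError("could not find finite starting density for all walkers")

    half = n_walkers // 2
    chain = np.empty((n_steps, n_walkers, dim))
    chain_logp = np.empty((n_steps, n_walkers))
    idx = (np.arange(half), np.arange(half, n_walkers))
    for step in range(n_steps):
        for h in (0, 1):
            S = idx[h]
            C = idx[1 - h]
            z = _draw_z(rng, half, stretch_a)
            partners = C[rng.integers(0, half, size=half)]
            prop = pos[partners] + z[:, None] * (pos[S] - pos[partners])
            logp_prop = np.asarray(log_target(prop), dtype=float)
            log_ratio = (dim - 1) * np.log(z) + logp_prop - logp[S]
            accept = np.log(rng.random(half)) < log_ratio
            pos[S[accept]] = prop[accept]
            logp[S[accept]] = logp_prop[accept]
        chain[step] = pos
        chain_logp[step] = logp
    return chain, chain_logp
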