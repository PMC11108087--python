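"""Componentwise adaptive random-walk Metropolis kernel (numba-compiled).

The target is log posterior = multinomial log-likelihood kernel
(sum_I n_I log psi_I) plus independent Normal(0, sigma^2) priors on the
log parameters.  Each parameter j contributes a fixed 64-vector
``cols[j]`` to the unnormalized log weights u (nucleotide multiplicities
for the betas, category indicators for the Phis), so a componentwise
proposal updates u in O(64) and only the log-normalizer is recomputed.

All randomness is pre-drawn outside the kernel, which makes traces
bit-reproducible for a fixed seed and keeps the kernel purely numeric.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _logsumexp64(u):
    m = u[0]
    for i in range(1, u.shape[0]):
        if u[i] > m:
            m = u[i]
    s = 0.0
    for i in range(u.shape[0]):
        s += np.exp(u[i] - m)
    return m + np.log(s)


@njit(cache=True)
def run_chain(
    cols,          # (p, 64) float64: d(log weight)/d(theta_j) per codon
    counts,        # (64,) float64 codon counts
    theta0,        # (p,) initial log-parameters
    n_iter,        # total iterations (sweeps)
    n_burn,        # burn-in sweeps (adaptation active, samples discarded)
    thin,          # keep every thin-th post-burn-in sweep
    prior_sigma,   # prior SD on log parameters
    target_accept, # adaptation target acceptance rate
    step0,         # initial proposal SD
    normals,       # (n_iter, p) standard normal draws
    uniforms,      # (n_iter, p) uniform(0,1) draws
):
    p, m = cols.shape
    n_total = 0.0
    for i in range(m):
        n_total += counts[i]
    # counts . cols[j], so the data term of a proposal is O(1)
    cc = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(m):
            s += counts[i] * cols[j, i]
        cc[j] = s

    theta = theta0.copy()
    u = np.zeros(m)
    for j in range(p):
        for i in range(m):
            u[i] += theta[j] * cols[j, i]
    data_dot = 0.0
    for i in range(m):
        data_dot += counts[i] * u[i]
    log_z = _logsumexp64(u)
    loglik = data_dot - n_total * log_z

    inv2s2 = 1.0 / (2.0 * prior_sigma * prior_sigma)
    steps = np.full(p, step0)
    n_keep = (n_iter - n_burn + thin - 1) // thin
    samples = np.empty((n_keep, p))
    logpost = np.empty(n_keep)
    accepted = np.zeros(p)
    kept = 0
    u_prop = np.empty(m)

    for t in range(n_iter):
        for j in range(p):
            d = steps[j] * normals[t, j]
            for i in range(m):
                u_prop[i] = u[i] + d * cols[j, i]
            log_z_prop = _logsumexp64(u_prop)
            data_dot_prop = data_dot + d * cc[j]
            loglik_prop = data_dot_prop - n_total * log_z_prop
            tj = theta[j]
            dlp = (loglik_prop - loglik) - ((tj + d) * (tj + d) - tj * tj) * inv2s2
            if np.log(uniforms[t, j]) < dlp:
                theta[j] = tj + d
                for i in range(m):
                    u[i] = u_prop[i]
                data_dot = data_dot_prop
                log_z = log_z_prop
                loglik = loglik_prop
                accepted[j] += 1.0
            if t < n_burn:
                # Robbins-Monro on log step size toward the target rate;
                # frozen after burn-in to preserve detailed balance.
                alpha = np.exp(dlp) if dlp < 0.0 else 1.0
                gamma = 1.0 / np.sqrt(t + 1.0)
                steps[j] *= np.exp(gamma * (alpha - target_accept))
        if t >= n_burn and (t - n_burn) % thin == 0:
            prior = 0.0
            for j in range(p):
                prior -= theta[j] * theta[j] * inv2s2
            for j in range(p):
                samples[kept, j] = theta[j]
            logpost[kept] = loglik + prior
            kept += 1

    return samples, logpost, accepted / n_iter, steps
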