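"""Bayesian estimation of mutational and fitness coefficients from codon counts.

The likelihood is multinomial over a species' pooled genome-wide codon
counts, with cell probabilities given by the model's stationary
distribution.  Priors are independent Normal(0, sigma^2) on the log
parameters (sigma = 2 by default), proper and weakly informative around
the reference values beta = Phi = 1.  Sampling uses componentwise
adaptive random-walk Metropolis on the log scale (see ``_sampler``),
with adaptation frozen after burn-in.

A hard identifiability guard refuses mappings with more than 53 fitness
categories, where simulation studies find the coefficient set no longer
identifiable from 64 codon frequencies; it can be overridden explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from . import _sampler
from .genetic_code import CODONS, FitnessMapping, amino_acid_mapping
from .model import (
    COMPOSITION,
    ModelParameters,
    category_indicator,
    log_stationary_from_arrays,
)

#: Beyond this many fitness categories the model is treated as unidentifiable.
IDENTIFIABILITY_CAP = 53


class IdentifiabilityError(ValueError):
    """Raised when a mapping exceeds the identifiability guard."""


@dataclass(frozen=True)
class CodonCounts:
    """Observed counts over the 64 codons for one species (or pooled genome)."""

    counts: np.ndarray
    species_id: str = "species"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (64,):
            raise ValueError("counts must be a length-64 vector")
        if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        if counts.sum() <= 0:
            raise ValueError("total codon count must be positive")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.total

    @classmethod
    def from_dict(cls, counts: Mapping[str, int], species_id: str = "species"):
        vec = np.array([counts.get(c, 0) for c in CODONS])
        return cls(counts=vec, species_id=species_id)

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CODONS), name=self.species_id)


def log_likelihood(counts: CodonCounts, params: ModelParameters) -> float:
    """Multinomial log-likelihood kernel sum_I n_I log psi_I.

    The combinatorial constant is omitted; it cancels in posterior and
    DIC comparisons (``multinomial_log_constant`` restores it for
    absolute values such as BIC).  A zero psi with positive count yields
    -inf rather than an exception.
    """
    log_psi = log_stationary_from_arrays(
        np.log(params.beta_array()), np.log(params.phi_by_codon())
    )
    with np.errstate(invalid="ignore"):
        value = float(np.dot(counts.counts, log_psi))
    return value if np.isfinite(value) else -math.inf


def multinomial_log_constant(counts: CodonCounts) -> float:
    """log of the multinomial coefficient n! / prod n_I!."""
    return float(gammaln(counts.total + 1) - gammaln(counts.counts + 1).sum())


def log_prior(params: ModelParameters, sigma: float = 2.0) -> float:
    """Independent Normal(0, sigma^2) log density on each free log parameter."""
    if sigma <= 0:
        raise ValueError("prior sigma must be positive")
    x = params.free_log_vector()
    return float(
        -0.5 * np.sum(x**2) / sigma**2
        - x.size * (0.5 * math.log(2 * math.pi) + math.log(sigma))
    )


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler configuration; defaults suit a 25-parameter amino-acid fit."""

    n_iter: int = 50_000
    burn_in_fraction: float = 0.5
    thin: int = 10
    n_chains: int = 2
    prior_sigma: float = 2.0
    target_accept: float = 0.44
    initial_step: float = 0.1
    init_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter < 10 or not 0 < self.burn_in_fraction < 1:
            raise ValueError("invalid MCMC settings")

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_in_fraction)


@dataclass(frozen=True)
class PosteriorTrace:
    """Post-burn-in, thinned MCMC samples of the free log parameters.

    ``samples`` has shape (n_chains, n_samples, n_parameters); parameter
    order is beta_T, beta_C, beta_G then the free Phi categories in
    mapping order.
    """

    samples: np.ndarray
    log_posterior: np.ndarray
    param_names: Tuple[str, ...]
    mapping: FitnessMapping
    seed: int
    settings: MCMCSettings
    acceptance: np.ndarray

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    def pooled(self) -> np.ndarray:
        """(n_chains * n_samples, p) matrix pooling all chains."""
        return self.samples.reshape(-1, self.samples.shape[-1])

    def posterior_mean_log(self) -> np.ndarray:
        return self.pooled().mean(axis=0)

    def posterior_mean_params(self) -> ModelParameters:
        """ModelParameters at the posterior mean of the log parameters."""
        return ModelParameters.from_free_log_vector(
            self.mapping, self.posterior_mean_log()
        )

    def map_sample(self) -> np.ndarray:
        """The retained sample with the highest (unnormalized) log posterior."""
        flat = self.log_posterior.reshape(-1)
        return self.pooled()[int(np.argmax(flat))]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for c in range(self.n_chains):
            frame = pd.DataFrame(self.samples[c], columns=list(self.param_names))
            frame.insert(0, "chain", c)
            frame["log_posterior"] = self.log_posterior[c]
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)


def _parameter_columns(mapping: FitnessMapping) -> np.ndarray:
    """(p, 64) per-parameter contribution to the unnormalized log weights."""
    comp = COMPOSITION  # columns A, C, G, T
    indicator = category_indicator(mapping)
    free = mapping.free_labels
    label_col = {l: j for j, l in enumerate(mapping.labels)}
    rows = [comp[:, 3], comp[:, 1], comp[:, 2]]  # beta_T, beta_C, beta_G
    rows += [indicator[:, label_col[l]] for l in free]
    return np.ascontiguousarray(np.array(rows))


def run_mcmc(
    counts: CodonCounts,
    mapping: FitnessMapping | None = None,
    settings: MCMCSettings | None = None,
    seed: int = 0,
    force: bool = False,
) -> PosteriorTrace:
    """Sample the posterior of the model parameters given codon counts.

    Identical seed, settings and data reproduce the trace bit-for-bit.
    """
    mapping = mapping or amino_acid_mapping()
    settings = settings or MCMCSettings()
    if mapping.n_categories > IDENTIFIABILITY_CAP and not force:
        raise IdentifiabilityError(
            f"mapping has {mapping.n_categories} fitness categories; more than "
            f"{IDENTIFIABILITY_CAP} is unidentifiable from 64 codon frequencies "
            "(pass force=True to override)"
        )
    cols = _parameter_columns(mapping)
    p = cols.shape[0]
    names = ModelParameters.parameter_names(mapping)
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(settings.n_chains)
    all_samples, all_logpost, all_accept = [], [], []
    for chain_ss in chain_seeds:
        rng = np.random.default_rng(chain_ss)
        theta0 = rng.normal(0.0, settings.init_jitter, size=p)
        normals = rng.standard_normal((settings.n_iter, p))
        uniforms = rng.random((settings.n_iter, p))
        samples, logpost, accept, _ = _sampler.run_chain(
            cols,
            counts.counts.astype(np.float64),
            theta0,
            settings.n_iter,
            settings.n_burn,
            settings.thin,
            settings.prior_sigma,
            settings.target_accept,
            settings.initial_step,
            normals,
            uniforms,
        )
        if not np.isfinite(logpost).all():
            raise RuntimeError("non-finite posterior encountered during sampling")
        all_samples.append(samples)
        all_logpost.append(logpost)
        all_accept.append(accept)
    return PosteriorTrace(
        samples=np.array(all_samples),
        log_posterior=np.array(all_logpost),
        param_names=names,
        mapping=mapping,
        seed=seed,
        settings=settings,
        acceptance=np.array(all_accept),
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-R-hat for one parameter, chains of shape (m, n).

    Each chain is split in half before comparing means.  Values below 1
    (a small-sample artifact of the variance estimator) are clipped to 1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    half = chains.shape[1] // 2
    if half < 2:
        raise ValueError("chains too short to split")
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    w = split.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    b = half * split.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(max(var_plus / w, 1.0)))


def effective_sample_size(chains: np.ndarray) -> float:
    """Multi-chain effective sample size for one parameter.

    Combined-chain autocorrelations with Geyer's initial positive
    monotone sequence truncation.
    """
    chains = np.asarray(chains, dtype=float)
    m, n = chains.shape
    w = chains.var(axis=1, ddof=1).mean()
    if w == 0:
        return float(m * n)
    b = n * chains.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * w + b / n
    # mean autocovariance across chains via FFT
    acov = np.zeros(n)
    for c in range(m):
        x = chains[c] - chains[c].mean()
        f = np.fft.rfft(x, 2 * n)
        ac = np.fft.irfft(f * np.conjugate(f))[:n].real / n
        acov += ac / m
    rho = 1.0 - (w - acov) / var_plus
    # Geyer: sum consecutive pairs while positive, enforce monotone decrease
    tau = 1.0
    prev = math.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        tau += 2.0 * pair
        prev = pair
        t += 2
    return float(m * n / tau)


def convergence_diagnostics(trace: PosteriorTrace) -> pd.DataFrame:
    """Per-parameter split-R-hat and effective sample size."""
    if trace.n_chains < 2:
        raise ValueError("convergence diagnostics require at least two chains")
    rows = []
    for j, name in enumerate(trace.param_names):
        chains = trace.samples[:, :, j]
        rows.append(
            {
                "parameter": name,
                "rhat": split_rhat(chains),
                "ess": effective_sample_size(chains),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Information criteria and posterior predictive checks
# ---------------------------------------------------------------------------

def _loglik_matrix(trace: PosteriorTrace, counts: CodonCounts) -> np.ndarray:
    """Log-likelihood kernel at every retained sample (flattened chains)."""
    cols = _parameter_columns(trace.mapping)
    theta = trace.pooled()
    u = theta @ cols  # (nsamples, 64)
    return u @ counts.counts - counts.total * logsumexp(u, axis=1)


def information_criteria(
    trace: PosteriorTrace, counts: CodonCounts
) -> Tuple[float, float]:
    """(BIC, DIC) from a converged trace.

    DIC = mean deviance + p_D with the deviance D = -2 log L (kernel)
    and p_D evaluated at the posterior mean of the log parameters.  BIC
    uses the full multinomial likelihood (combinatorial constant
    included) at the maximum-posterior retained sample, with n the
    species' total codon count and k the number of free parameters.
    """
    loglik = _loglik_matrix(trace, counts)
    if loglik.size == 0:
        raise ValueError("empty trace")
    d_bar = float(np.mean(-2.0 * loglik))
    at_mean = ModelParameters.from_free_log_vector(
        trace.mapping, trace.posterior_mean_log()
    )
    d_hat = -2.0 * log_likelihood(counts, at_mean)
    p_d = d_bar - d_hat
    dic = d_bar + p_d
    k = len(trace.param_names)
    map_params = ModelParameters.from_free_log_vector(trace.mapping, trace.map_sample())
    loglik_hat = log_likelihood(counts, map_params) + multinomial_log_constant(counts)
    bic = k * math.log(counts.total) - 2.0 * loglik_hat
    return float(bic), float(dic)


def posterior_predictive_flags(
    trace: PosteriorTrace,
    counts: CodonCounts,
    n_reps: int = 500,
    seed: int = 0,
    interval: Tuple[float, float] = (0.05, 0.95),
) -> np.ndarray:
    """Flag codons whose empirical frequency falls outside the predictive interval.

    For each of ``n_reps`` posterior draws, a replicate count vector of
    the same total is simulated from the draw's stationary distribution;
    per codon, the (0.05, 0.95) quantile interval of replicate
    frequencies is formed and the codon is flagged when its empirical
    frequency lies outside it.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100 for stable quantiles")
    rng = np.random.default_rng(seed)
    pooled = trace.pooled()
    idx = rng.integers(0, pooled.shape[0], size=n_reps)
    cols = _parameter_columns(trace.mapping)
    u = pooled[idx] @ cols
    psi = np.exp(u - logsumexp(u, axis=1, keepdims=True))
    reps = np.empty((n_reps, 64))
    for r in range(n_reps):
        reps[r] = rng.multinomial(counts.total, psi[r]) / counts.total
    lo, hi = np.quantile(reps, interval, axis=0)
    emp = counts.frequencies
    return (emp < lo) | (emp > hi)


def aggregate_codon_errors(flags: Sequence[np.ndarray]) -> np.ndarray:
    """Per-codon fraction of species flagged by the posterior predictive check."""
    stack = np.asarray(list(flags), dtype=float)
    if stack.ndim != 2 or stack.shape[1] != 64:
        raise ValueError("flags must be per-species length-64 vectors")
    return stack.mean(axis=0)


# ---------------------------------------------------------------------------
# High-level fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Posterior summaries, information criteria and diagnostics of one fit."""

    species_id: str
    trace: PosteriorTrace
    summary: pd.DataFrame  # parameter, mean_log, sd_log, mean, sd, rhat, ess
    bic: float
    dic: float

    @property
    def mapping(self) -> FitnessMapping:
        return self.trace.mapping

    @property
    def max_rhat(self) -> float:
        return float(self.summary["rhat"].max())

    def posterior_mean(self, name: str) -> float:
        """Posterior mean of one coefficient on the natural scale."""
        row = self.summary.loc[self.summary["parameter"] == name]
        if row.empty:
            raise KeyError(name)
        return float(row["mean"].iloc[0])

    def phi_posterior_means(self) -> Dict[str, float]:
        """Natural-scale posterior mean Phi per free category label."""
        return {
            l: self.posterior_mean(f"phi_{l}") for l in self.mapping.free_labels
        }

    def estimates(self) -> ModelParameters:
        """ModelParameters at the posterior mean of the log parameters."""
        return self.trace.posterior_mean_params()


def fit(
    counts: CodonCounts,
    mapping: FitnessMapping | None = None,
    settings: MCMCSettings | None = None,
    seed: int = 0,
    force: bool = False,
) -> FitResult:
    """Run MCMC and package posterior summaries with BIC/DIC and diagnostics."""
    trace = run_mcmc(counts, mapping, settings, seed=seed, force=force)
    diag = convergence_diagnostics(trace)
    pooled = trace.pooled()
    natural = np.exp(pooled)
    summary = pd.DataFrame(
        {
            "parameter": list(trace.param_names),
            "mean_log": pooled.mean(axis=0),
            "sd_log": pooled.std(axis=0, ddof=1),
            "mean": natural.mean(axis=0),
            "sd": natural.std(axis=0, ddof=1),
        }
    ).merge(diag, on="parameter")
    bic, dic = information_criteria(trace, counts)
    return FitResult(
        species_id=counts.species_id,
        trace=trace,
        summary=summary,
        bic=bic,
        dic=dic,
    )
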