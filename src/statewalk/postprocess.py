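"""Posterior summaries: relabeling, mean densities, mean vectors, state probabilities.

Mixture posteriors are invariant under permutation of the state labels, so a
well-mixing chain swaps state identities ("label switching").  Before any
summary is computed, the chain is relabeled with Stephens' batch
Kullback-Leibler algorithm: per kept sample the classification-probability
matrix is permuted to agree as closely as possible with the running average,
iterating to a fixed point.  With at most three states all permutations are
enumerated exactly.

Summaries follow the posterior-mean-density convention: the reported rate and
angle distributions are averages of the per-sample parametric densities (and
therefore integrate to one), with pointwise SD bands expressing fitting
uncertainty; circular concentration is summarised by the posterior mean of
the wrapped-Cauchy mean vector (rho cos mu, rho sin mu).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Literal

import numpy as np
from scipy.special import gamma as gamma_fn

from .fit import ChainSamples, ModelData, label_probabilities
from .preprocess import StepSeries

__all__ = [
    "PosteriorDensity",
    "MeanVectorSummary",
    "classification_matrices",
    "relabel_stephens",
    "sort_states_by_rate",
    "posterior_density",
    "posterior_weibull_mean",
    "posterior_mean_vector",
    "state_probabilities",
    "classification_accuracy",
    "per_sample_loglik",
]


@dataclass(frozen=True)
class PosteriorDensity:
    """Posterior mean density curve on a grid, with a pointwise SD band."""

    grid: np.ndarray
    mean_curve: np.ndarray
    sd_curve: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mean_curve < 0) or np.any(self.sd_curve < 0):
            raise ValueError("density and SD curves must be non-negative")


@dataclass(frozen=True)
class MeanVectorSummary:
    """Posterior mean of the wrapped-Cauchy mean vector, with a scalar SD.

    The SD is the planar root-mean-square deviation of the per-sample vectors
    around their mean — the radius of the uncertainty circle drawn around the
    arrow head.
    """

    vector: np.ndarray
    sd: float

    def __post_init__(self) -> None:
        if np.linalg.norm(self.vector) >= 1.0:
            raise ValueError("a mean vector has norm < 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _wc_pdf_grid(grid: np.ndarray, mu: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """(M, G) wrapped-Cauchy densities for M samples on a G-point angle grid."""
    mu = mu[:, None]
    rho = rho[:, None]
    return (1.0 - rho**2) / (
        2.0 * np.pi * (1.0 + rho**2 - 2.0 * rho * np.cos(grid[None, :] - mu))
    )


def _weibull_pdf_grid(grid: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(M, G) Weibull densities for M samples on a G-point rate grid (grid > 0)."""
    a = a[:, None]
    b = b[:, None]
    x = grid[None, :] / b
    return (a / b) * x ** (a - 1.0) * np.exp(-(x**a))


def classification_matrices(chain: ChainSamples, steps: StepSeries) -> np.ndarray:
    """(M, T, N) per-sample classification probabilities P(z_t = j | theta^(m))."""
    data = ModelData(steps)
    if data.n != chain.n_entries:
        raise ValueError("step series does not match the chain's data size")
    M, N = chain.n_samples, chain.n_states
    P = np.empty((M, data.n, N))
    for m in range(M):
        state = {
            "a": chain.a[m], "b": chain.b[m], "mu": chain.mu[m],
            "rho": chain.rho[m], "w": chain.w[m],
        }
        P[m] = label_probabilities(state, data)
    return P


def _apply_permutations(chain: ChainSamples, perms: np.ndarray) -> ChainSamples:
    """Return a copy of ``chain`` with per-sample state permutations applied.

    ``perms[m]`` lists, for each new state index ``j``, the old state index it
    takes its parameters from; labels are mapped through the inverse
    permutation so parameters and labels stay attached to the same points.
    """
    M, N = chain.n_samples, chain.n_states
    rows = np.arange(M)[:, None]
    new = {
        k: getattr(chain, k)[rows, perms]
        for k in ("a", "b", "mu", "rho", "w")
    }
    inv = np.empty_like(perms)
    inv[rows, perms] = np.arange(N)[None, :]
    new_z = inv[rows, chain.z]
    return ChainSamples(
        a=new["a"], b=new["b"], mu=new["mu"], rho=new["rho"], w=new["w"],
        z=new_z.astype(chain.z.dtype), accept_rates=chain.accept_rates,
        config=chain.config, rho_max=chain.rho_max,
    )


def relabel_stephens(chain: ChainSamples, steps: StepSeries,
                     max_iter: int = 100, tol: float = 0.0) -> ChainSamples:
    """Resolve label switching by Stephens' batch KL relabeling.

    Iteratively: average the permuted classification matrices into ``Q``, then
    per sample pick the permutation minimising KL(Q || P^(m) permuted),
    enumerating all N! permutations, until the permutation assignment reaches
    a fixed point.  The per-sample likelihood is untouched because parameters,
    weights and labels are permuted together.
    """
    N = chain.n_states
    if N == 1:
        return chain
    P = classification_matrices(chain, steps)  # (M, T, N)
    M = P.shape[0]
    logP = np.log(np.clip(P, 1e-300, None))
    perms = np.array(list(permutations(range(N))))  # (K, N)
    # seed the running average from a single reference sample: the plain mean
    # of a label-switching chain is symmetric across states, which would tie
    # every permutation and stall the assignment
    Q = P[0]
    nu = np.zeros(M, dtype=int)
    for _ in range(max_iter):
        # cost[m, k] = -sum_tj Q[t, j] log P[m, t, perms[k, j]]
        cost = -np.einsum("tj,mtkj->mk", Q, logP[:, :, perms.T].swapaxes(2, 3))
        new_nu = cost.argmin(axis=1)
        if np.array_equal(new_nu, nu):
            break
        nu = new_nu
        Q = np.take_along_axis(P, perms[nu][:, None, :], axis=2).mean(axis=0)
    return _apply_permutations(chain, perms[nu])


def sort_states_by_rate(chain: ChainSamples) -> ChainSamples:
    """Canonical presentation order: state 1 is the slower state.

    Applies one global permutation so states are sorted by increasing
    posterior Weibull mean (slow area-restricted first, fast transiting last).
    """
    means = np.array(
        [posterior_weibull_mean(chain, j)[0] for j in range(chain.n_states)]
    )
    order = np.argsort(means, kind="stable")
    if np.array_equal(order, np.arange(chain.n_states)):
        return chain
    perms = np.tile(order, (chain.n_samples, 1))
    return _apply_permutations(chain, perms)


def posterior_density(chain: ChainSamples, which: Literal["rate", "angle"],
                      state: int, grid: np.ndarray) -> PosteriorDensity:
    """Posterior mean density of a state's rate or angle distribution (Eq.-style
    average of per-sample pdfs) with the pointwise SD band across samples."""
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    grid = np.asarray(grid, dtype=float)
    if which == "rate":
        curves = _weibull_pdf_grid(grid, chain.a[:, state], chain.b[:, state])
    elif which == "angle":
        curves = _wc_pdf_grid(grid, chain.mu[:, state], chain.rho[:, state])
    else:
        raise ValueError("which must be 'rate' or 'angle'")
    mean_curve = curves.mean(axis=0)
    sd_curve = curves.std(axis=0, ddof=0) if chain.n_samples > 1 else np.zeros_like(mean_curve)
    return PosteriorDensity(grid=grid, mean_curve=mean_curve, sd_curve=sd_curve)


def posterior_weibull_mean(chain: ChainSamples, state: int) -> tuple[float, float]:
    """Posterior mean (and SD across samples) of the state's Weibull mean rate
    b Gamma(1 + 1/a)."""
    means = chain.b[:, state] * gamma_fn(1.0 + 1.0 / chain.a[:, state])
    sd = float(means.std(ddof=1)) if means.size > 1 else 0.0
    return float(means.mean()), sd


def posterior_mean_vector(chain: ChainSamples, state: int) -> MeanVectorSummary:
    """Posterior mean of (rho cos mu, rho sin mu) with planar RMS deviation."""
    vx = chain.rho[:, state] * np.cos(chain.mu[:, state])
    vy = chain.rho[:, state] * np.sin(chain.mu[:, state])
    centre = np.array([vx.mean(), vy.mean()])
    sd = float(np.sqrt(np.mean((vx - centre[0]) ** 2 + (vy - centre[1]) ** 2)))
    return MeanVectorSummary(vector=centre, sd=sd)


def state_probabilities(chain: ChainSamples) -> np.ndarray:
    """(T, N) per-entry posterior state probabilities: the fraction of kept
    samples assigning each entry to each state (no discretisation)."""
    M, N = chain.n_samples, chain.n_states
    out = np.zeros((chain.n_entries, N))
    for j in range(N):
        out[:, j] = (chain.z == j).mean(axis=0)
    return out


def classification_accuracy(probs: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of points whose maximum-probability state matches the truth,
    maximised over all assignments of model states to truth labels.

    Ties in the probability vector go to the lower state index.
    """
    probs = np.asarray(probs)
    truth = np.asarray(truth)
    if probs.shape[0] != truth.shape[0]:
        raise ValueError(
            f"length mismatch: {probs.shape[0]} probability rows vs {truth.shape[0]} truth labels"
        )
    n_states = probs.shape[1]
    pred = probs.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    labels = np.unique(truth)
    if labels.size > n_states:
        raise ValueError("more truth labels than model states")
    best = 0.0
    for perm in permutations(range(n_states), labels.size):
        mapped = np.empty(truth.shape, dtype=int)
        for lab, j in zip(labels, perm):
            mapped[truth == lab] = j
        best = max(best, float(np.mean(pred == mapped)))
    return best


def per_sample_loglik(chain: ChainSamples, steps: StepSeries) -> np.ndarray:
    """Joint log-likelihood of each kept sample (labels included).

    Useful as an invariant: relabeling permutes parameters and labels together
    and must leave this vector exactly unchanged.
    """
    data = ModelData(steps)
    M = chain.n_samples
    out = np.empty(M)
    for m in range(M):
        total = 0.0
        for j in range(chain.n_states):
            mask = chain.z[m] == j
            if np.any(mask):
                total += data.state_loglik(
                    chain.a[m, j], chain.b[m, j], chain.mu[m, j], chain.rho[m, j], mask
                )
        out[m] = total
    return out
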