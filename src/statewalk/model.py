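"""Step-and-turn mixture model: densities and likelihood.

A trajectory converted to movement rates ``r`` and turning angles ``phi`` is
modelled as a mixture of ``N`` correlated random walks ("behavioural states").
Within state ``j`` the movement rate follows a Weibull distribution with shape
``a_j`` and scale ``b_j``, and the turning angle follows a wrapped Cauchy
distribution with mean direction ``mu_j`` and concentration ``rho_j``.  The
per-step likelihood factorises into the rate and angle terms, and steps are
conditionally independent given their state labels.

The log-densities here are written out explicitly rather than routed through
``scipy.stats``: they sit in the innermost MCMC loop and must vectorise over
both observations and parameter grids.  ``scipy.stats.weibull_min`` and
``scipy.stats.wrapcauchy`` act as independent oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gamma as gamma_fn

__all__ = [
    "RHO_MAX",
    "WeibullParams",
    "WrappedCauchyParams",
    "StateParams",
    "MixtureModel",
    "weibull_pdf",
    "weibull_logpdf",
    "weibull_mean",
    "wrapped_cauchy_pdf",
    "wrapped_cauchy_logpdf",
    "wrapped_cauchy_rvs",
    "mean_vector",
    "mixture_loglik",
    "wrap_angle",
]

#: Upper bound on the wrapped-Cauchy concentration.  The density degenerates to
#: a point mass as rho -> 1, so inference caps rho strictly below 1.
RHO_MAX = 0.99


def wrap_angle(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the interval (-pi, pi]."""
    out = np.mod(-np.asarray(phi) + np.pi, 2.0 * np.pi)
    out = np.pi - out
    # mod can return 2*pi-epsilon -> -pi; push the closed boundary to +pi
    out = np.where(out <= -np.pi, out + 2.0 * np.pi, out)
    if np.ndim(phi) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class WeibullParams:
    """Weibull rate distribution: shape ``a`` > 0, scale ``b`` > 0."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"Weibull shape must be positive, got {self.a}")
        if not (np.isfinite(self.b) and self.b > 0):
            raise ValueError(f"Weibull scale must be positive, got {self.b}")

    @property
    def mean(self) -> float:
        """b * Gamma(1 + 1/a), the mean movement rate of the state."""
        return weibull_mean(self.a, self.b)


@dataclass(frozen=True)
class WrappedCauchyParams:
    """Wrapped Cauchy turn distribution: mean direction ``mu``, concentration ``rho``."""

    mu: float
    rho: float
    rho_max: float = RHO_MAX

    def __post_init__(self) -> None:
        if not (-np.pi < self.mu <= np.pi):
            raise ValueError(f"mu must lie in (-pi, pi], got {self.mu}")
        if not (0.0 <= self.rho <= self.rho_max < 1.0):
            raise ValueError(
                f"rho must lie in [0, {self.rho_max}], got {self.rho}"
            )


@dataclass(frozen=True)
class StateParams:
    weibull: WeibullParams
    wc: WrappedCauchyParams


@dataclass(frozen=True)
class MixtureModel:
    """An ``N``-state step-and-turn mixture with state weights on the simplex."""

    states: Sequence[StateParams]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.states)
        if n not in (1, 2, 3):
            raise ValueError(f"number of states must be 1, 2 or 3, got {n}")
        w = self.weights
        if w is None:
            w = np.full(n, 1.0 / n)
        w = np.asarray(w, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be a length-N simplex vector")
        object.__setattr__(self, "weights", w)

    @property
    def n_states(self) -> int:
        return len(self.states)


def weibull_logpdf(r, a: float, b: float):
    """Log-density of the Weibull(shape=a, scale=b) at rate ``r`` >= 0.

    At ``r == 0`` the density is 0 for a > 1 (log-density ``-inf``), 1/b for
    a == 1 and diverges for a < 1 (``+inf``), handled consistently here.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("movement rates must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.log(r)
        out = (
            np.log(a)
            - np.log(b)
            + (a - 1.0) * (logr - np.log(b))
            - np.exp(a * (logr - np.log(b)))
        )
    if np.any(r == 0):
        if a > 1:
            zero_val = -np.inf
        elif a == 1:
            zero_val = -np.log(b)
        else:
            zero_val = np.inf
        out = np.where(r == 0, zero_val, out)
    return out if out.ndim else float(out)


def weibull_pdf(r, p: WeibullParams | None = None, *, a: float | None = None, b: float | None = None):
    """Weibull density (a/b)(r/b)^(a-1) exp(-(r/b)^a) for r >= 0."""
    if p is not None:
        a, b = p.a, p.b
    return np.exp(weibull_logpdf(r, a, b))


def weibull_mean(a: float, b: float) -> float:
    return float(b * gamma_fn(1.0 + 1.0 / a))


def wrapped_cauchy_logpdf(phi, mu: float, rho: float, rho_max: float = RHO_MAX):
    """Log-density of the wrapped Cauchy at angle ``phi`` in (-pi, pi]."""
    if not (0.0 <= rho <= rho_max):
        raise ValueError(f"rho must lie in [0, {rho_max}], got {rho}")
    phi = np.asarray(phi, dtype=float)
    num = 1.0 - rho * rho
    den = 1.0 + rho * rho - 2.0 * rho * np.cos(phi - mu)
    out = np.log(num) - np.log(2.0 * np.pi) - np.log(den)
    return out if out.ndim else float(out)


def wrapped_cauchy_pdf(phi, p: WrappedCauchyParams | None = None, *, mu: float | None = None,
                       rho: float | None = None, rho_max: float = RHO_MAX):
    """(1/2pi) (1 - rho^2) / (1 + rho^2 - 2 rho cos(phi - mu)); uniform at rho=0."""
    if p is not None:
        mu, rho, rho_max = p.mu, p.rho, p.rho_max
    return np.exp(wrapped_cauchy_logpdf(phi, mu, rho, rho_max))


def wrapped_cauchy_rvs(mu: float, rho: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample turning angles: wrap a Cauchy with scale -log(rho) around ``mu``.

    At rho = 0 the distribution is uniform on (-pi, pi].
    """
    if rho == 0.0:
        return wrap_angle(rng.uniform(-np.pi, np.pi, size))
    gamma = -np.log(rho)
    return wrap_angle(mu + gamma * rng.standard_cauchy(size))


def mean_vector(p: WrappedCauchyParams) -> np.ndarray:
    """Mean resultant vector (rho cos mu, rho sin mu); its norm equals rho."""
    return np.array([p.rho * np.cos(p.mu), p.rho * np.sin(p.mu)])


def mixture_loglik(steps, z: np.ndarray, m: MixtureModel) -> float:
    """Joint log-likelihood of a step series under given state labels.

    ``z`` holds one 0-based label per step-series entry (an entry is a grid
    slot with at least one valid observable).  Entries with a valid rate but
    no valid turning angle contribute only the Weibull factor; the likelihood
    factorises over entries and over the two observables.
    """
    z = np.asarray(z)
    n = m.n_states
    if z.shape[0] != steps.n_entries:
        raise ValueError(
            f"label vector length {z.shape[0]} != number of entries {steps.n_entries}"
        )
    if z.size and (z.min() < 0 or z.max() >= n):
        raise ValueError("state labels out of range")
    r, phi = steps.entry_r, steps.entry_phi
    total = 0.0
    for j in range(n):
        sel = z == j
        if not np.any(sel):
            continue
        st = m.states[j]
        rj = r[sel]
        ok_r = ~np.isnan(rj)
        if np.any(ok_r):
            total += float(np.sum(weibull_logpdf(rj[ok_r], st.weibull.a, st.weibull.b)))
        pj = phi[sel]
        ok_p = ~np.isnan(pj)
        if np.any(ok_p):
            total += float(
                np.sum(wrapped_cauchy_logpdf(pj[ok_p], st.wc.mu, st.wc.rho, st.wc.rho_max))
            )
    return total
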