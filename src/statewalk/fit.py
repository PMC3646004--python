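"""Metropolis-within-Gibbs sampler for the step-and-turn mixture model.

Each sweep updates, in order:

1. the per-entry state labels ``z`` from their exact full conditional
   ``P(z_t = j) ∝ w_j f_j(r_t, phi_t)`` (independent across entries given the
   parameters);
2. the mixture weights from the conjugate Dirichlet full conditional
   ``w ~ Dirichlet(1 + counts)``;
3. each state's continuous parameters by random-walk Metropolis: on the log
   scale for the Weibull shape ``a`` and scale ``b`` (Gamma priors with mean
   30 and variance 3000, i.e. shape 0.3 and rate 0.01), a wrapped walk for the
   turn mean ``mu`` (uniform prior on (-pi, pi]) and a boundary-reflected walk
   for the concentration ``rho`` (uniform prior on (0, rho_max)).

Proposal scales adapt by Robbins-Monro towards ~30% acceptance during burn-in
only, so the post-burn-in chain keeps the exact stationary distribution.  The
chain protocol follows the usual single long run: burn-in sweeps, then
``n_iter`` sweeps keeping every ``thin``-th sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as gamma_fn

from .model import RHO_MAX, wrap_angle
from .preprocess import StepSeries

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "ChainSamples",
    "ModelData",
    "init_chain",
    "update_labels",
    "update_weights",
    "update_state_params",
    "run_chain",
    "split_rhat",
]

_PARAM_NAMES = ("a", "b", "mu", "rho")


@dataclass(frozen=True)
class PriorSpec:
    """Priors: Gamma on Weibull a and b, uniform on mu and rho, Dirichlet(1) weights.

    The Gamma defaults (shape 0.3, rate 0.01) are the moment match to a vague
    prior with mean 30 and variance 3000.
    """

    gamma_shape: float = 0.3
    gamma_rate: float = 0.01
    rho_max: float = RHO_MAX

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("Gamma prior parameters must be positive")
        if not (0 < self.rho_max < 1):
            raise ValueError("rho_max must lie in (0, 1)")


@dataclass(frozen=True)
class MCMCConfig:
    n_iter: int = 100_000
    burn_in: int = 2_000
    thin: int = 10
    proposal_sd: Dict[str, float] = field(
        default_factory=lambda: {"a": 0.2, "b": 0.2, "mu": 0.4, "rho": 0.1}
    )
    adapt_during_burnin: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        missing = [k for k in _PARAM_NAMES if k not in self.proposal_sd]
        if missing:
            raise ValueError(f"proposal_sd lacks entries for {missing}")


@dataclass
class ChainSamples:
    """Thinned posterior draws of all mixture parameters and labels."""

    a: np.ndarray        # (M, N)
    b: np.ndarray        # (M, N)
    mu: np.ndarray       # (M, N)
    rho: np.ndarray      # (M, N)
    w: np.ndarray        # (M, N)
    z: np.ndarray        # (M, T), 0-based labels
    accept_rates: Dict[str, float]
    config: Dict
    rho_max: float = RHO_MAX

    @property
    def n_samples(self) -> int:
        return self.a.shape[0]

    @property
    def n_states(self) -> int:
        return self.a.shape[1]

    @property
    def n_entries(self) -> int:
        return self.z.shape[1]

    def save(self, path: str | Path) -> None:
        import json

        np.savez_compressed(
            path,
            a=self.a, b=self.b, mu=self.mu, rho=self.rho, w=self.w, z=self.z,
            rho_max=self.rho_max,
            meta=np.frombuffer(
                json.dumps({"accept_rates": self.accept_rates, "config": self.config}).encode(),
                dtype=np.uint8,
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ChainSamples":
        import json

        with np.load(path) as f:
            meta = json.loads(bytes(f["meta"]).decode())
            return cls(
                a=f["a"], b=f["b"], mu=f["mu"], rho=f["rho"], w=f["w"],
                z=f["z"], rho_max=float(f["rho_max"]),
                accept_rates=meta["accept_rates"], config=meta["config"],
            )


class ModelData:
    """Step-series view prepared for fast repeated likelihood evaluation."""

    def __init__(self, steps: StepSeries):
        r = steps.entry_r
        phi = steps.entry_phi
        self.n = r.shape[0]
        self.valid_r = ~np.isnan(r)
        self.valid_phi = ~np.isnan(phi)
        self.r = np.where(self.valid_r, r, 1.0)
        with np.errstate(divide="ignore"):
            self.log_r = np.where(self.valid_r & (self.r > 0), np.log(self.r), -np.inf)
        self.phi = np.where(self.valid_phi, phi, 0.0)

    def weibull_terms(self, a: float, b: float) -> np.ndarray:
        """Per-entry Weibull log-density (0 where r is invalid)."""
        lb = np.log(b)
        with np.errstate(over="ignore"):  # exp overflow -> -inf, a certain rejection
            out = np.log(a) - lb + (a - 1.0) * (self.log_r - lb) - np.exp(
                a * (self.log_r - lb)
            )
        return np.where(self.valid_r, out, 0.0)

    def wc_terms(self, mu: float, rho: float) -> np.ndarray:
        """Per-entry wrapped-Cauchy log-density (0 where phi is invalid)."""
        out = (
            np.log1p(-rho * rho)
            - np.log(2.0 * np.pi)
            - np.log(1.0 + rho * rho - 2.0 * rho * np.cos(self.phi - mu))
        )
        return np.where(self.valid_phi, out, 0.0)

    def state_loglik(self, a, b, mu, rho, mask: np.ndarray) -> float:
        """Log-likelihood of the entries in ``mask`` under one state's parameters."""
        mr = mask & self.valid_r
        total = 0.0
        if np.any(mr):
            lr = self.log_r[mr]
            lb = np.log(b)
            with np.errstate(over="ignore"):  # overflow -> -inf likelihood
                total += float(
                    mr.sum() * (np.log(a) - lb)
                    + (a - 1.0) * (lr.sum() - mr.sum() * lb)
                    - np.exp(a * (lr - lb)).sum()
                )
        mp = mask & self.valid_phi
        if np.any(mp):
            total += float(
                mp.sum() * (np.log1p(-rho * rho) - np.log(2.0 * np.pi))
                - np.log(1.0 + rho * rho - 2.0 * rho * np.cos(self.phi[mp] - mu)).sum()
            )
        return total


def _weibull_shape_from_cv2(cv2: float) -> float:
    """Invert the Weibull coefficient-of-variation relation for the shape."""

    def f(a: float) -> float:
        g1 = gamma_fn(1.0 + 1.0 / a)
        return gamma_fn(1.0 + 2.0 / a) / (g1 * g1) - 1.0 - cv2

    lo, hi = 0.1, 50.0
    if not np.isfinite(cv2) or cv2 <= f(hi) + 1e-12:
        return hi
    if cv2 >= f(lo) - 1e-12:
        return lo
    return float(brentq(f, lo, hi))


def init_chain(steps: StepSeries, n_states: int, prior: PriorSpec,
               rng: np.random.Generator) -> dict:
    """Deterministic-given-seed initial state.

    Weibull parameters come from method-of-moments fits to a randomized
    contiguous split of the sorted rates (so multimodal rate data yield
    distinct initial state means); mu starts at 0, rho at 0.5, weights
    uniform, labels random.
    """
    if n_states not in (1, 2, 3):
        raise ValueError("n_states must be 1, 2 or 3")
    data = ModelData(steps)
    if data.n < 5 * n_states:
        raise ValueError(
            f"too little data: {data.n} entries for a {n_states}-state model"
        )
    rates = np.sort(data.r[data.valid_r])
    # randomized near-equal contiguous blocks of the sorted rates
    fracs = rng.dirichlet(np.full(n_states, 5.0))
    cuts = np.concatenate([[0], np.round(np.cumsum(fracs) * rates.size).astype(int)])
    cuts[-1] = rates.size
    a0 = np.empty(n_states)
    b0 = np.empty(n_states)
    for j in range(n_states):
        blk = rates[cuts[j]:cuts[j + 1]]
        if blk.size < 2 or blk.mean() <= 0 or blk.std() == 0:
            a0[j], b0[j] = 1.0, max(blk.mean(), 1e-6) if blk.size else 1.0
            continue
        cv2 = float(blk.var() / blk.mean() ** 2)
        a0[j] = _weibull_shape_from_cv2(cv2)
        b0[j] = float(blk.mean() / gamma_fn(1.0 + 1.0 / a0[j]))
    return {
        "a": a0,
        "b": b0,
        "mu": np.zeros(n_states),
        "rho": np.full(n_states, 0.5),
        "w": np.full(n_states, 1.0 / n_states),
        "z": rng.integers(0, n_states, data.n),
    }


def _label_logprob_matrix(state: dict, data: ModelData) -> np.ndarray:
    """(T, N) matrix of unnormalised log full-conditional label probabilities."""
    n_states = state["a"].shape[0]
    ll = np.empty((data.n, n_states))
    for j in range(n_states):
        ll[:, j] = (
            np.log(state["w"][j])
            + data.weibull_terms(state["a"][j], state["b"][j])
            + data.wc_terms(state["mu"][j], state["rho"][j])
        )
    return ll


def label_probabilities(state: dict, data: ModelData) -> np.ndarray:
    """Normalised per-entry full-conditional state probabilities (T, N)."""
    ll = _label_logprob_matrix(state, data)
    m = ll.max(axis=1, keepdims=True)
    finite = np.isfinite(m[:, 0])
    p = np.exp(ll - np.where(np.isfinite(m), m, 0.0))
    p[~finite] = state["w"]  # all-states-zero entries fall back to the weights
    p /= p.sum(axis=1, keepdims=True)
    return p


def update_labels(state: dict, data: ModelData, rng: np.random.Generator) -> np.ndarray:
    """Draw every label from its exact full conditional, independently across entries."""
    if not all(np.all(np.isfinite(state[k])) for k in _PARAM_NAMES):
        raise ValueError("non-finite mixture parameters")
    p = label_probabilities(state, data)
    u = rng.random(data.n)
    return (p.cumsum(axis=1) < u[:, None]).sum(axis=1)


def update_weights(state: dict, rng: np.random.Generator) -> np.ndarray:
    """Conjugate draw w ~ Dirichlet(1 + label counts)."""
    n_states = state["a"].shape[0]
    counts = np.bincount(state["z"], minlength=n_states)
    return rng.dirichlet(1.0 + counts)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Fold a real number into [lo, hi] by reflection at both boundaries."""
    width = hi - lo
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def update_state_params(state: dict, data: ModelData, prior: PriorSpec,
                        rng: np.random.Generator,
                        proposal_sd: Dict[str, float],
                        accept_counter: Dict[str, list] | None = None) -> None:
    """One Metropolis sweep over (a, b, mu, rho) of every state, in place.

    Each parameter is a separate random-walk block; acceptance uses the
    likelihood of the entries currently labelled with that state times the
    parameter's prior.  With no data in a state the blocks sample the prior.
    """
    n_states = state["a"].shape[0]
    for j in range(n_states):
        mask = state["z"] == j
        a, b, mu, rho = (state[k][j] for k in _PARAM_NAMES)
        ll = data.state_loglik(a, b, mu, rho, mask)

        # --- a, b: random walk on the log scale, Gamma prior + Jacobian ----
        for name in ("a", "b"):
            cur = state[name][j]
            prop = float(np.exp(np.log(cur) + rng.normal(0.0, proposal_sd[name])))
            cand = dict(a=state["a"][j], b=state["b"][j])
            cand[name] = prop
            ll_prop = data.state_loglik(cand["a"], cand["b"], mu, rho, mask)
            # log Gamma(shape, rate) density + log-scale Jacobian
            def _lp(x: float) -> float:
                return prior.gamma_shape * np.log(x) - prior.gamma_rate * x

            log_alpha = (ll_prop - ll) + (_lp(prop) - _lp(cur))
            accepted = np.log(rng.random()) < log_alpha
            if accepted:
                state[name][j] = prop
                ll = ll_prop
            if accept_counter is not None:
                accept_counter[name].append(accepted)

        a, b = state["a"][j], state["b"][j]

        # --- mu: wrapped random walk, uniform prior --------------------------
        prop_mu = wrap_angle(mu + rng.normal(0.0, proposal_sd["mu"]))
        ll_prop = data.state_loglik(a, b, prop_mu, rho, mask)
        accepted = np.log(rng.random()) < (ll_prop - ll)
        if accepted:
            state["mu"][j] = prop_mu
            ll = ll_prop
        if accept_counter is not None:
            accept_counter["mu"].append(accepted)
        mu = state["mu"][j]

        # --- rho: reflected random walk on (0, rho_max), uniform prior ------
        prop_rho = _reflect(rho + rng.normal(0.0, proposal_sd["rho"]), 0.0, prior.rho_max)
        ll_prop = data.state_loglik(a, b, mu, prop_rho, mask)
        accepted = np.log(rng.random()) < (ll_prop - ll)
        if accepted:
            state["rho"][j] = prop_rho
        if accept_counter is not None:
            accept_counter["rho"].append(accepted)


def run_chain(steps: StepSeries, n_states: int, prior: PriorSpec = PriorSpec(),
              cfg: MCMCConfig = MCMCConfig()) -> ChainSamples:
    """Run the full Metropolis-within-Gibbs protocol on a step series.

    Burn-in sweeps (with Robbins-Monro proposal adaptation, frozen afterwards)
    are followed by ``n_iter`` sweeps of label -> weight -> parameter updates,
    keeping every ``thin``-th sweep, for ``floor(n_iter / thin)`` samples.
    """
    rng = np.random.default_rng(cfg.seed)
    data = ModelData(steps)
    state = init_chain(steps, n_states, prior, rng)
    sd = dict(cfg.proposal_sd)
    target = 0.3

    # ---- burn-in with optional adaptation ---------------------------------
    for it in range(cfg.burn_in):
        counter = {k: [] for k in _PARAM_NAMES} if cfg.adapt_during_burnin else None
        state["z"] = update_labels(state, data, rng)
        state["w"] = update_weights(state, rng)
        update_state_params(state, data, prior, rng, sd, counter)
        if counter is not None:
            gain = (it + 1.0) ** -0.6
            for k in _PARAM_NAMES:
                if counter[k]:
                    acc = float(np.mean(counter[k]))
                    sd[k] = float(np.exp(np.log(sd[k]) + gain * (acc - target)))

    # ---- sampling, adaptation frozen --------------------------------------
    M = cfg.n_iter // cfg.thin
    n_states_ = n_states
    out_a = np.empty((M, n_states_))
    out_b = np.empty((M, n_states_))
    out_mu = np.empty((M, n_states_))
    out_rho = np.empty((M, n_states_))
    out_w = np.empty((M, n_states_))
    out_z = np.empty((M, data.n), dtype=np.int8)
    counter = {k: [] for k in _PARAM_NAMES}
    kept = 0
    for it in range(1, cfg.n_iter + 1):
        state["z"] = update_labels(state, data, rng)
        state["w"] = update_weights(state, rng)
        update_state_params(state, data, prior, rng, sd, counter)
        if it % cfg.thin == 0 and kept < M:
            out_a[kept] = state["a"]
            out_b[kept] = state["b"]
            out_mu[kept] = state["mu"]
            out_rho[kept] = state["rho"]
            out_w[kept] = state["w"]
            out_z[kept] = state["z"]
            kept += 1

    accept = {k: float(np.mean(v)) if v else float("nan") for k, v in counter.items()}
    config_echo = {
        "n_states": n_states,
        "n_iter": cfg.n_iter,
        "burn_in": cfg.burn_in,
        "thin": cfg.thin,
        "seed": cfg.seed,
        "proposal_sd": {k: float(v) for k, v in sd.items()},
        "prior": {"gamma_shape": prior.gamma_shape, "gamma_rate": prior.gamma_rate,
                  "rho_max": prior.rho_max},
        "n_entries": int(data.n),
    }
    return ChainSamples(a=out_a, b=out_b, mu=out_mu, rho=out_rho, w=out_w, z=out_z,
                        accept_rates=accept, config=config_echo, rho_max=prior.rho_max)


def split_rhat(chain: ChainSamples) -> Dict[str, np.ndarray]:
    """Split-chain potential scale reduction for the continuous parameters."""
    import arviz as az

    out: Dict[str, np.ndarray] = {}
    M = chain.n_samples
    half = M // 2
    for name in _PARAM_NAMES:
        arr = getattr(chain, name)[: 2 * half]
        split = np.stack([arr[:half], arr[half:]], axis=0)  # (2, half, N)
        out[name] = np.asarray(
            [float(az.rhat(split[:, :, j])) for j in range(chain.n_states)]
        )
    return out
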