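"""Synthetic two-regime trajectories and GPS-collar-like observation.

The generator produces a planar trajectory alternating two movement regimes:

* ``straight`` — fast, directionally persistent transiting: turn increments
  drawn from a highly concentrated von Mises centred on 0;
* ``area_restricted`` — slow foraging/resting movement: turn increments from a
  broad von Mises centred on pi, producing frequent near-reversals.

Segment lengths (in points) are uniform integers on ``[seg_len_min,
seg_len_max]``; the last segment is truncated so the trajectory holds exactly
``target_points`` points.  Within a segment, successive step lengths follow a
Gaussian random walk ``d_{i+1} ~ N(d_i, step_sd^2)`` truncated to positive
values by rejection, seeded at the regime's initial step length; headings
accumulate the von Mises turn increments from a fresh uniform initial heading.

``observe_gps`` turns any trajectory into collar-like fix records with
dropouts, isotropic position noise, a 2D/3D fix flag and a log-normal PDOP
value, so the screening/subsampling stages can be exercised without field
data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import wrap_angle

__all__ = [
    "RegimeParams",
    "GeneratorConfig",
    "TrueTrajectory",
    "ObservationConfig",
    "default_generator_config",
    "collar_generator_config",
    "load_generator_config",
    "draw_segment_lengths",
    "simulate_trajectory",
    "observe_gps",
]

_REGIME_LABELS = ("straight", "area_restricted")
_REQUIRED_REGIME_KEYS = ("mu_turn", "kappa_turn", "step_sd", "step_init")


@dataclass(frozen=True)
class RegimeParams:
    """Movement parameters of one behavioural regime of the generator."""

    label: str
    mu_turn: float      # von Mises mean turn, rad in (-pi, pi]
    kappa_turn: float   # von Mises concentration, >= 0
    step_sd: float      # SD of the step-length innovation, length units
    step_init: float    # first step length of a segment of this regime

    def __post_init__(self) -> None:
        if self.label not in _REGIME_LABELS:
            raise ValueError(f"unknown regime label {self.label!r}")
        for name in _REQUIRED_REGIME_KEYS:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"regime {self.label!r}: parameter {name!r} missing or non-finite")
        if self.kappa_turn < 0:
            raise ValueError("kappa_turn must be non-negative")
        if self.step_sd <= 0 or self.step_init <= 0:
            raise ValueError("step_sd and step_init must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    regimes: tuple[RegimeParams, RegimeParams]
    seg_len_min: int = 20
    seg_len_max: int = 100
    target_points: int = 487
    seed: int = 0
    start_xy: tuple[float, float] = (0.0, 0.0)
    dt: float = 1.0  # seconds (or arbitrary units) between successive points

    def __post_init__(self) -> None:
        labels = {r.label for r in self.regimes}
        if labels != set(_REGIME_LABELS):
            raise ValueError(f"need one regime of each label, got {labels}")
        if not (1 <= self.seg_len_min <= self.seg_len_max):
            raise ValueError("need 1 <= seg_len_min <= seg_len_max")
        if self.target_points < self.seg_len_min:
            raise ValueError("target_points must be >= seg_len_min")
        s, a = self.regime("straight"), self.regime("area_restricted")
        if not s.step_init > a.step_init:
            raise ValueError(
                "straight regime must start faster than the area-restricted regime"
            )

    def regime(self, label: str) -> RegimeParams:
        for r in self.regimes:
            if r.label == label:
                return r
        raise KeyError(label)


@dataclass(frozen=True)
class TrueTrajectory:
    """Simulated positions with ground-truth regime labels."""

    xy: np.ndarray          # (n, 2)
    t: np.ndarray           # (n,), strictly increasing
    state_true: np.ndarray  # (n,) regime label strings
    step_len: np.ndarray    # (n-1,) all > 0
    heading: np.ndarray     # (n-1,) rad

    def __post_init__(self) -> None:
        n = self.xy.shape[0]
        if not (self.t.shape[0] == n and self.state_true.shape[0] == n):
            raise ValueError("xy, t and state_true must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.step_len <= 0):
            raise ValueError("step lengths must be positive")

    @property
    def n_points(self) -> int:
        return self.xy.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.xy[:, 0], "y": self.xy[:, 1], "t": self.t, "state_true": self.state_true}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ObservationConfig:
    """GPS-collar emulation: 5-min fixes, dropouts, noise and quality metadata."""

    fix_interval: float = 300.0
    dropout_prob: float = 0.05
    p_2d: float = 0.3
    pdop_lognormal_mu: float = 1.3
    pdop_lognormal_sigma: float = 0.6
    position_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.p_2d):
            if not (0.0 <= p < 1.0):
                raise ValueError("probabilities must lie in [0, 1)")
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be non-negative")


def _regimes_from_mapping(cfg: dict) -> tuple[RegimeParams, RegimeParams]:
    try:
        raw = cfg["regimes"]
    except KeyError as exc:
        raise ValueError("generator config lacks a 'regimes' section") from exc
    regimes = []
    for label in _REGIME_LABELS:
        if label not in raw:
            raise ValueError(f"generator config lacks regime {label!r}")
        entry = dict(raw[label])
        missing = [k for k in _REQUIRED_REGIME_KEYS if k not in entry]
        if missing:
            raise ValueError(f"regime {label!r} lacks parameters {missing}")
        regimes.append(RegimeParams(label=label, **{k: float(entry[k]) for k in _REQUIRED_REGIME_KEYS}))
    return tuple(regimes)  # type: ignore[return-value]


def load_generator_config(source: str | Path | io.TextIOBase, *, seed: int = 0,
                          dt: float = 1.0) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML file; validates strictly."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = yaml.safe_load(source)
    if not isinstance(cfg, dict):
        raise ValueError("generator config must be a YAML mapping")
    return GeneratorConfig(
        regimes=_regimes_from_mapping(cfg),
        seg_len_min=int(cfg.get("seg_len_min", 20)),
        seg_len_max=int(cfg.get("seg_len_max", 100)),
        target_points=int(cfg.get("target_points", 487)),
        seed=seed,
        dt=dt,
    )


def default_generator_config(seed: int = 0, dt: float = 1.0) -> GeneratorConfig:
    """Packaged default study conditions (two regimes, 487 points)."""
    text = resources.files("statewalk.data").joinpath("synthetic_default.yaml").read_text()
    return load_generator_config(io.StringIO(text), seed=seed, dt=dt)


def collar_generator_config(seed: int = 0, target_points: int = 818) -> GeneratorConfig:
    """Study conditions for GPS-collar-style experiments.

    Same two regimes as the synthetic default, but sized to one animal's
    pooled tracking volume (818 points, the per-animal average of a
    four-animal possum campaign totalling ~3272 fixes) and time-stamped at
    the 5-min (300 s) collar interval.
    """
    base = default_generator_config(seed=seed, dt=300.0)
    return replace(base, target_points=int(target_points))


def draw_segment_lengths(cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw alternating-regime segment lengths summing exactly to ``target_points``.

    Returns ``(lengths, labels)`` where labels alternate between the two
    regimes starting from a uniformly chosen one; the final segment is
    truncated so the cumulative point count equals ``cfg.target_points``.
    """
    lengths: list[int] = []
    first = int(rng.integers(0, 2))
    total = 0
    while total < cfg.target_points:
        ln = int(rng.integers(cfg.seg_len_min, cfg.seg_len_max + 1))
        if total + ln > cfg.target_points:
            ln = cfg.target_points - total
        lengths.append(ln)
        total += ln
    labels = np.array(
        [_REGIME_LABELS[(first + i) % 2] for i in range(len(lengths))], dtype=object
    )
    return np.asarray(lengths, dtype=int), labels


def _truncated_normal_step(prev: float, sd: float, rng: np.random.Generator) -> float:
    """d ~ N(prev, sd^2) truncated to d > 0 by rejection."""
    for _ in range(1000):
        d = rng.normal(prev, sd)
        if d > 0:
            return d
    raise RuntimeError("step-length rejection sampling failed (sd too large?)")


def simulate_trajectory(cfg: GeneratorConfig) -> TrueTrajectory:
    """Simulate a two-regime correlated random walk of ``target_points`` points.

    Each point carries the label of the regime that generated the step into it
    (the first point carries the first segment's label).  Timestamps are
    ``0, dt, 2 dt, ...``.
    """
    rng = np.random.default_rng(cfg.seed)
    seg_lens, seg_labels = draw_segment_lengths(cfg, rng)
    n = cfg.target_points

    xy = np.empty((n, 2))
    xy[0] = cfg.start_xy
    state = np.empty(n, dtype=object)
    step_len = np.empty(n - 1)
    heading = np.empty(n - 1)

    i = 1  # index of the next point to place
    state[0] = seg_labels[0]
    pos = np.asarray(cfg.start_xy, dtype=float)
    for ln, label in zip(seg_lens, seg_labels):
        reg = cfg.regime(label)
        # number of steps this segment contributes: its points, except the very
        # first segment whose first point is the fixed start position
        n_steps = ln if i > 1 else ln - 1
        if n_steps <= 0:
            continue
        th = rng.uniform(-np.pi, np.pi)  # fresh initial direction per segment
        d = reg.step_init
        for s in range(n_steps):
            if s > 0:
                th = wrap_angle(th + rng.vonmises(reg.mu_turn, reg.kappa_turn))
                d = _truncated_normal_step(d, reg.step_sd, rng)
            pos = pos + d * np.array([np.cos(th), np.sin(th)])
            xy[i] = pos
            state[i] = label
            step_len[i - 1] = d
            heading[i - 1] = th
            i += 1
    assert i == n, "segment bookkeeping failed"
    t = np.arange(n, dtype=float) * cfg.dt
    return TrueTrajectory(xy=xy, t=t, state_true=state, step_len=step_len, heading=heading)


def observe_gps(traj: TrueTrajectory, ocfg: ObservationConfig) -> pd.DataFrame:
    """Emulate collar observation of a trajectory: one candidate fix per
    ``fix_interval``, independent dropouts, position noise and fix-quality
    metadata.  Returns a fix table with columns ``x, y, t, dim, pdop``.
    """
    rng = np.random.default_rng(ocfg.seed)
    t = traj.t
    dt = t[1] - t[0] if len(t) > 1 else ocfg.fix_interval
    stride = ocfg.fix_interval / dt
    if not np.isclose(stride, round(stride)):
        raise ValueError("fix_interval must be a multiple of the trajectory time step")
    idx = np.arange(0, traj.n_points, int(round(stride)))
    keep = rng.random(idx.size) >= ocfg.dropout_prob
    idx = idx[keep]
    xy = traj.xy[idx] + rng.normal(0.0, ocfg.position_noise_sd, size=(idx.size, 2)) \
        if ocfg.position_noise_sd > 0 else traj.xy[idx].copy()
    dim = np.where(rng.random(idx.size) < ocfg.p_2d, "2D", "3D")
    pdop = rng.lognormal(ocfg.pdop_lognormal_mu, ocfg.pdop_lognormal_sigma, idx.size)
    return pd.DataFrame(
        {"x": xy[:, 0], "y": xy[:, 1], "t": t[idx], "dim": dim, "pdop": pdop}
    )
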