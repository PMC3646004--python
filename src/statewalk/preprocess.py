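"""Fix screening, temporal subsampling and step-series conversion.

Observed trajectories are sequences of (x, y, t) triplets, possibly with GPS
quality metadata.  Three stages prepare them for model fitting:

1. ``screen_fixes`` removes low-quality records (2D fixes with PDOP above a
   threshold), the standard screening rule for collar data.
2. ``subsample`` selects fixes lying on a regular time grid anchored at the
   first retained fix; missing grid slots stay missing — no interpolation.
3. ``to_step_series`` converts consecutive grid fixes to movement rates and
   quadrant-aware signed turning angles; a value whose required fixes are not
   all present at consecutive grid slots is excluded (stored as NaN).

A :class:`StepSeries` keeps one entry per grid slot so that rates and angles
sharing a slot stay paired for the mixture likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import wrap_angle

__all__ = [
    "ScreenConfig",
    "SubsampleSpec",
    "StepSeries",
    "screen_fixes",
    "subsample",
    "to_step_series",
    "steps_from_positions",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Quality screening rule: drop 2D fixes whose PDOP exceeds the threshold."""

    pdop_threshold: float = 5.0
    drop_2d_above_threshold: bool = True

    def __post_init__(self) -> None:
        if self.pdop_threshold <= 0:
            raise ValueError("pdop_threshold must be positive")


@dataclass(frozen=True)
class SubsampleSpec:
    """Regular-grid subsampling: keep fixes at anchor + k * target_interval.

    ``target_interval`` must be a positive multiple of ``base_interval``.
    ``tolerance`` (same units) allows jittered real timestamps to match a grid
    slot; the default 0 suits exactly spaced synthetic data.
    """

    base_interval: float
    factor: int | None = None
    target_interval: float | None = None
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.base_interval <= 0:
            raise ValueError("base_interval must be positive")
        if (self.factor is None) == (self.target_interval is None):
            raise ValueError("give exactly one of factor or target_interval")
        if self.factor is not None:
            if self.factor < 1:
                raise ValueError("factor must be >= 1")
            object.__setattr__(self, "target_interval", self.factor * self.base_interval)
        else:
            ratio = self.target_interval / self.base_interval
            if not np.isclose(ratio, round(ratio)) or ratio < 1:
                raise ValueError(
                    "target_interval must be a positive multiple of base_interval"
                )
            object.__setattr__(self, "factor", int(round(ratio)))
        if self.tolerance < 0 or self.tolerance >= self.target_interval / 2:
            raise ValueError("tolerance must lie in [0, target_interval / 2)")


@dataclass(frozen=True)
class StepSeries:
    """Movement rates and turning angles on a regular time grid.

    ``r[k]`` is the rate over grid slots (k, k+1); ``phi[k]`` is the signed
    turn at the middle fix of slots (k, k+1, k+2).  Invalid values (a required
    slot missing) are NaN.  ``t`` holds the grid-slot timestamps the entries
    anchor to, ``t_mid`` the timestamp each paired entry refers to (slot k+1).
    """

    t: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    interval: float

    def __post_init__(self) -> None:
        k = len(self.t)
        if len(self.r) != k or len(self.phi) != k:
            raise ValueError("t, r and phi must have equal length")
        with np.errstate(invalid="ignore"):
            if np.any(self.r[~np.isnan(self.r)] < 0):
                raise ValueError("movement rates must be non-negative")
            bad = self.phi[~np.isnan(self.phi)]
            if bad.size and (np.any(bad <= -np.pi) or np.any(bad > np.pi)):
                raise ValueError("turning angles must lie in (-pi, pi]")

    @property
    def t_mid(self) -> np.ndarray:
        return self.t + self.interval

    @property
    def n_r(self) -> int:
        return int(np.sum(~np.isnan(self.r)))

    @property
    def n_phi(self) -> int:
        return int(np.sum(~np.isnan(self.phi)))

    # --- model-facing view: entries with at least one valid observable -----
    @property
    def entry_mask(self) -> np.ndarray:
        return ~(np.isnan(self.r) & np.isnan(self.phi))

    @property
    def n_entries(self) -> int:
        return int(np.sum(self.entry_mask))

    @property
    def entry_r(self) -> np.ndarray:
        return self.r[self.entry_mask]

    @property
    def entry_phi(self) -> np.ndarray:
        return self.phi[self.entry_mask]

    @property
    def entry_t(self) -> np.ndarray:
        return self.t[self.entry_mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "r": self.r,
                "phi": self.phi,
                "valid_r": ~np.isnan(self.r),
                "valid_phi": ~np.isnan(self.phi),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "interval", self.interval)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StepSeries":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(float),
            r=df["r"].to_numpy(float),
            phi=df["phi"].to_numpy(float),
            interval=float(df["interval"].iloc[0]),
        )


def screen_fixes(fixes: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Drop 2D fixes with PDOP above the threshold; keep everything else in order."""
    if not cfg.drop_2d_above_threshold or fixes.empty:
        return fixes.copy()
    for col in ("dim", "pdop"):
        if col not in fixes.columns:
            raise KeyError(f"fix table lacks required column {col!r}")
    bad = (fixes["dim"] == "2D") & (fixes["pdop"] > cfg.pdop_threshold)
    return fixes.loc[~bad].copy()


def subsample(t: np.ndarray, spec: SubsampleSpec) -> np.ndarray:
    """Indices of fixes on the grid anchor + k * target_interval.

    The anchor is the first timestamp.  A grid slot with no fix within
    ``tolerance`` is simply absent; when several fixes match a slot the
    closest (earliest on ties) wins.  Returns fix indices in slot order,
    alongside nothing else — slot numbers are recoverable from timestamps.
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        return np.empty(0, dtype=int)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    anchor = t[0]
    step = spec.target_interval
    slots = np.round((t - anchor) / step).astype(int)
    resid = np.abs(t - (anchor + slots * step))
    ok = resid <= spec.tolerance + 1e-9
    picked: dict[int, int] = {}
    for i in np.nonzero(ok)[0]:
        s = slots[i]
        if s not in picked or resid[i] < resid[picked[s]]:
            picked[s] = i
    return np.array([picked[s] for s in sorted(picked)], dtype=int)


def to_step_series(xy: np.ndarray, t: np.ndarray, spec: SubsampleSpec) -> StepSeries:
    """Convert grid-selected fixes to movement rates and turning angles.

    ``xy`` and ``t`` are the *selected* fixes (output of :func:`subsample`
    applied to the full table).  A rate at slot k needs fixes at slots
    (k, k+1); an angle needs (k, k+1, k+2); others are NaN.
    """
    xy = np.asarray(xy, dtype=float)
    t = np.asarray(t, dtype=float)
    if xy.shape[0] != t.shape[0]:
        raise ValueError("positions and timestamps must have equal length")
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 selected fixes")
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate timestamps (zero time difference)")
    step = spec.target_interval
    anchor = t[0]
    slots = np.round((t - anchor) / step).astype(int)

    n_slots = slots[-1]  # entries are defined for slots 0 .. last-1
    pos_at = {int(s): xy[i] for i, s in enumerate(slots)}
    t_grid = anchor + np.arange(n_slots) * step
    r = np.full(n_slots, np.nan)
    phi = np.full(n_slots, np.nan)
    for k in range(n_slots):
        if k in pos_at and (k + 1) in pos_at:
            d = pos_at[k + 1] - pos_at[k]
            r[k] = float(np.hypot(d[0], d[1])) / step
            if (k + 2) in pos_at:
                e = pos_at[k + 2] - pos_at[k + 1]
                # signed angle between successive displacement vectors via the
                # quadrant-aware arctangent, in (-pi, pi]
                cross = d[0] * e[1] - d[1] * e[0]
                dot = d[0] * e[0] + d[1] * e[1]
                phi[k] = wrap_angle(float(np.arctan2(cross, dot)))
    return StepSeries(t=t_grid, r=r, phi=phi, interval=float(step))


def steps_from_positions(xy: np.ndarray, t: np.ndarray, spec: SubsampleSpec) -> StepSeries:
    """Subsample a full fix sequence and convert it, in one call."""
    idx = subsample(t, spec)
    return to_step_series(np.asarray(xy)[idx], np.asarray(t)[idx], spec)
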