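"""Presentation of posterior summaries.

Three display styles:

* per-state rate and angle posterior mean densities with +/-1 (dark grey) and
  +/-2 (light grey) SD bands, angles shown in degrees, with data histograms
  coloured by mean state probability;
* circular mean-vector diagrams — one arrow per state per sampling interval,
  with a circle of radius equal to the posterior SD of the mean vector;
* trajectories painted point-by-point with a continuous red-yellow-green
  gradient in the posterior probability of the slow state, with an optional
  pie inset of the mean state proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # file output only
import matplotlib.pyplot as plt
import numpy as np

from .postprocess import MeanVectorSummary, PosteriorDensity

__all__ = [
    "ColorGradientSpec",
    "plot_posterior_panels",
    "plot_mean_vectors",
    "plot_trajectory_states",
]


@dataclass(frozen=True)
class ColorGradientSpec:
    """Linear probability -> colour map: state 1 red, state 2 green, yellow midpoint."""

    color_state1: tuple[float, float, float] = (0.85, 0.1, 0.1)
    color_mid: tuple[float, float, float] = (0.95, 0.9, 0.1)
    color_state2: tuple[float, float, float] = (0.1, 0.65, 0.1)

    def __call__(self, p_state1: np.ndarray) -> np.ndarray:
        """Map P(state 1) in [0, 1] to RGB, piecewise-linearly through yellow."""
        p = np.clip(np.asarray(p_state1, dtype=float), 0.0, 1.0)
        c1 = np.asarray(self.color_state1)
        cm = np.asarray(self.color_mid)
        c2 = np.asarray(self.color_state2)
        lo = p[..., None] * 2.0
        out = np.where(
            p[..., None] <= 0.5,
            c2 + (cm - c2) * lo,
            cm + (c1 - cm) * (lo - 1.0),
        )
        return out


def _band(ax, grid, mean, sd, k, color, alpha):
    lo = np.clip(mean - k * sd, 0.0, None)
    ax.fill_between(grid, lo, mean + k * sd, color=color, alpha=alpha, linewidth=0)


def plot_posterior_panels(
    rate_densities: Sequence[PosteriorDensity],
    angle_densities: Sequence[PosteriorDensity],
    out_path: str | Path,
    rate_data: np.ndarray | None = None,
    angle_data: np.ndarray | None = None,
    probs: np.ndarray | None = None,
    gradient: ColorGradientSpec = ColorGradientSpec(),
) -> Path:
    """Per-state rate (top) and angle (bottom) densities with SD bands.

    ``rate_data``/``angle_data`` (optional) are shown as histograms whose bars
    are coloured by the mean P(state 1) of the observations they contain.
    Angle axes are drawn in degrees.
    """
    n = len(rate_densities)
    if len(angle_densities) != n:
        raise ValueError("need one rate and one angle density per state")
    fig, axes = plt.subplots(2, n, figsize=(4.2 * n, 6.0), squeeze=False)
    for j in range(n):
        for row, dens, to_deg in ((0, rate_densities[j], False), (1, angle_densities[j], True)):
            ax = axes[row][j]
            x = np.degrees(dens.grid) if to_deg else dens.grid
            data = (rate_data, angle_data)[row]
            if data is not None and probs is not None:
                vals = np.degrees(data) if to_deg else data
                ok = ~np.isnan(vals)
                counts, edges = np.histogram(vals[ok], bins=24, density=True)
                p1 = probs[ok, 0] if probs.ndim == 2 else probs[ok]
                which = np.digitize((np.degrees(data) if to_deg else data)[ok], edges[1:-1])
                bar_p = np.array(
                    [p1[which == i].mean() if np.any(which == i) else 0.5
                     for i in range(len(counts))]
                )
                ax.bar(
                    0.5 * (edges[:-1] + edges[1:]), counts,
                    width=np.diff(edges), color=gradient(bar_p), alpha=0.7,
                )
            _band(ax, x, dens.mean_curve, dens.sd_curve, 2, "0.75", 0.8)
            _band(ax, x, dens.mean_curve, dens.sd_curve, 1, "0.45", 0.8)
            ax.plot(x, dens.mean_curve, color="k", lw=1.4)
            ax.set_xlabel("turning angle (deg)" if to_deg else "movement rate")
            ax.set_ylabel("density")
            ax.set_title(f"state {j + 1}")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_mean_vectors(
    summaries: Mapping[str, Sequence[MeanVectorSummary]],
    out_path: str | Path,
    reference_length: float | None = None,
    colors: Sequence[str] = ("tab:red", "tab:green", "tab:blue"),
) -> Path:
    """Unit-circle diagram of posterior mean turn vectors.

    ``summaries`` maps an interval label to the per-state mean-vector
    summaries at that interval.  Each arrow head carries a circle of radius
    equal to the posterior SD; an optional dashed reference arrow of stated
    length along the positive x-axis aids scale reading.
    """
    fig, ax = plt.subplots(figsize=(5.4, 5.4))
    th = np.linspace(0, 2 * np.pi, 256)
    ax.plot(np.cos(th), np.sin(th), color="0.6", lw=0.8)
    ax.axhline(0, color="0.85", lw=0.6)
    ax.axvline(0, color="0.85", lw=0.6)
    for li, (label, per_state) in enumerate(summaries.items()):
        for j, s in enumerate(per_state):
            vx, vy = s.vector
            ax.annotate(
                "", xy=(vx, vy), xytext=(0, 0),
                arrowprops=dict(arrowstyle="->", color=colors[j % len(colors)],
                                alpha=1.0 - 0.15 * li),
            )
            ax.plot(vx + s.sd * np.cos(th), vy + s.sd * np.sin(th),
                    color=colors[j % len(colors)], lw=0.8, alpha=1.0 - 0.15 * li)
            ax.annotate(str(label), xy=(vx, vy), fontsize=7,
                        xytext=(vx + 0.03, vy + 0.03))
    if reference_length is not None:
        ax.annotate("", xy=(reference_length, 0), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", linestyle="--", color="k"))
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_aspect("equal")
    ax.set_xlabel("x component of mean vector")
    ax.set_ylabel("y component of mean vector")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def plot_trajectory_states(
    xy: np.ndarray,
    p_state1: np.ndarray,
    out_path: str | Path,
    gradient: ColorGradientSpec = ColorGradientSpec(),
    pie_inset: bool = True,
) -> Path:
    """Trajectory painted by P(state 1) with an optional state-proportion pie.

    ``p_state1`` holds one probability per trajectory point; points whose
    probability is undefined (NaN) are drawn grey.
    """
    xy = np.asarray(xy, dtype=float)
    p = np.asarray(p_state1, dtype=float)
    if xy.shape[0] != p.shape[0]:
        raise ValueError("xy and p_state1 must have equal length")
    fig, ax = plt.subplots(figsize=(6.2, 6.2))
    ax.plot(xy[:, 0], xy[:, 1], color="0.8", lw=0.7, zorder=1)
    ok = ~np.isnan(p)
    colors = np.empty((xy.shape[0], 3))
    colors[ok] = gradient(p[ok])
    colors[~ok] = 0.6
    ax.scatter(xy[:, 0], xy[:, 1], c=colors, s=14, zorder=2)
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if pie_inset and np.any(ok):
        mean_p1 = float(np.nanmean(p))
        ins = ax.inset_axes([0.8, 0.8, 0.18, 0.18])
        ins.pie(
            [mean_p1, 1.0 - mean_p1],
            colors=[gradient(np.array(1.0)), gradient(np.array(0.0))],
        )
        ins.set_aspect("equal")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
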