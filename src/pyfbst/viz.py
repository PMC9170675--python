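"""Visualization of the FBST: the surprise function with shaded evidence areas.

The surprise curve is drawn over the evaluation grid; the tangential set
(parameter values with higher surprise than the null value) is shaded in one
color as the evidence against H0, its complement in a second color as the
evidence in favor.  A point marker sits at (theta0, s(theta0)) and, for
one-sided hypotheses, a left/right boundary restricts the shading to the
stated side.  With a non-flat reference a horizontal line at s = 1 separates
corroborated from non-corroborated parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .core import FBSTResult, TangentialRegion, integrate_posterior_mass  # noqa: E402
from .density import DensityEstimate, SurpriseGrid  # noqa: E402
from .errors import InvalidInputError  # noqa: E402

COLOR_AGAINST = "#1f77b4"  # blue: evidence against H0
COLOR_FAVOR = "#d62728"  # red: evidence in favor of H0


@dataclass(frozen=True)
class PlotSpec:
    """Everything needed to render one FBST figure."""

    surprise: SurpriseGrid
    density: DensityEstimate
    result: FBSTResult
    region: TangentialRegion
    left_boundary: float | None = None
    right_boundary: float | None = None
    output_path: str | Path | None = None
    color_against: str = COLOR_AGAINST
    color_favor: str = COLOR_FAVOR


def plot_fbst(spec: PlotSpec) -> dict:
    """Render the FBST figure; return shaded-area bookkeeping.

    Returns a dictionary with ``against_mass`` and ``favor_mass``, the
    posterior mass integrated over exactly the shaded regions (the same grid
    the e-value was computed on, not a re-estimate).  Without boundaries,
    ``against_mass`` equals the result's ``ev_against``.
    """
    grid = spec.surprise.grid
    s = spec.surprise.s_values
    lo, hi = float(grid[0]), float(grid[-1])
    for name, b in (("left", spec.left_boundary), ("right", spec.right_boundary)):
        if b is not None and not (lo <= b <= hi):
            raise InvalidInputError(
                f"{name} boundary {b} outside the grid range [{lo:.6g}, {hi:.6g}]"
            )
    if (
        spec.left_boundary is not None
        and spec.right_boundary is not None
        and spec.left_boundary >= spec.right_boundary
    ):
        raise InvalidInputError("left boundary must be < right boundary")

    # shading window (one-sided hypotheses restrict it to one side of 0)
    win_lo = spec.left_boundary if spec.left_boundary is not None else lo
    win_hi = spec.right_boundary if spec.right_boundary is not None else hi
    in_window = (grid >= win_lo) & (grid <= win_hi)

    against = np.zeros_like(grid, dtype=bool)
    for a, b in spec.region.intervals:
        against |= (grid >= a) & (grid <= b)
    against &= in_window
    favor = in_window & ~against

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(grid, s, color="black", lw=1.2)
    ev = spec.result.ev_against
    ax.fill_between(
        grid, 0.0, s, where=against, color=spec.color_against, alpha=0.55,
        label=f"against H0: ev_against = {ev:.4f}",
    )
    ax.fill_between(
        grid, 0.0, s, where=favor, color=spec.color_favor, alpha=0.55,
        label=f"in favor of H0: ev = {spec.result.ev_favor:.4f}",
    )
    theta0 = spec.result.hypothesis.theta0
    ax.plot(
        [theta0], [spec.surprise.at(theta0)], "o", color=spec.color_against,
        ms=7, zorder=5, label=f"s* = s({theta0:g})",
    )
    flat = spec.surprise.reference.family == "flat"
    if not flat:
        ax.axhline(1.0, color="gray", lw=0.8, ls="--")
        ax.set_ylabel("surprise s(θ)")
    else:
        ax.set_ylabel("posterior density")
    ax.set_xlabel(spec.result.parameter_name)
    ax.legend(
        loc="upper right", fontsize=8,
        title=f"sev(H0) = {spec.result.sev:.4f}", title_fontsize=8,
    )
    ax.set_title("Full Bayesian Significance Test")
    fig.tight_layout()
    if spec.output_path is not None:
        fig.savefig(spec.output_path)
    plt.close(fig)

    # bookkeeping on the same quadrature the e-value used: the tangential
    # intervals (clipped to the shading window), not the pixel mask
    clipped = tuple(
        (max(a, win_lo), min(b, win_hi))
        for a, b in spec.region.intervals
        if min(b, win_hi) > max(a, win_lo)
    )
    against_mass = integrate_posterior_mass(
        spec.density, TangentialRegion(intervals=clipped, total_mass=0.0)
    )
    window_mass = integrate_posterior_mass(
        spec.density,
        TangentialRegion(intervals=((win_lo, win_hi),), total_mass=0.0),
    )
    info = {
        "against_mass": against_mass,
        "favor_mass": window_mass - against_mass,
        "shaded_colors": 2 if against.any() and favor.any() else 1,
        "marker": (float(theta0), float(spec.surprise.at(theta0))),
    }
    return info
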