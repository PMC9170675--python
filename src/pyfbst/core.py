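"""The Full Bayesian Significance Test: e-values, tangential sets, p-value analogues.

Given the surprise function s(theta) and a sharp null H0: theta = theta0,
the test computes

* ``s* = s(theta0)``, the supremum of the surprise over the null set;
* the tangential set  {theta : s(theta) > s*}  of parameter values more
  consistent with the data than the null value;
* the e-value against H0, the posterior mass of the tangential set
  (``ev_against``), and its complement ``ev_favor = 1 - ev_against``;
* the standardized e-value  sev = 1 - F_{k-h}(F_k^{-1}(ev_against))  with
  chi-square CDF/quantile functions, the test's p-value analogue (k and h
  are the dimensions of the parameter space and of the null set);
* asymptotic significance values: the Bayesian ev0 from the squared distance
  between the null value and the posterior mode, and the frequentist pv0
  from a caller-supplied likelihood-ratio statistic.

A large ``ev_against`` means most posterior mass sits on parameter values
with higher surprise than the null value — evidence against H0.  A small
``ev_against`` never confirms H0; the test only rejects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy import stats

from .density import (
    DEFAULT_GRID_SIZE,
    DensityEstimate,
    FLAT_REFERENCE,
    PosteriorDraws,
    ReferenceFunction,
    SurpriseGrid,
    build_surprise,
    estimate_posterior_density,
)
from .errors import InvalidInputError, NullOutsideSupportError

# Quantile inversion is clipped away from {0, 1} to avoid infinities; exact
# boundary inputs are mapped to exact outputs afterwards.
_PPF_EPS = 1e-15


@dataclass(frozen=True)
class Hypothesis:
    """A sharp null hypothesis H0: theta = theta0.

    ``dim_theta`` (k) is the dimension of the full parameter space of the
    model that produced the draws, ``dim_null`` (h) the dimension of the null
    set; k - h >= 1 are the chi-square degrees of freedom used by the
    standardized e-value.  For a one-parameter model testing a point null,
    k = 1 and h = 0.
    """

    theta0: float
    dim_theta: int = 1
    dim_null: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta0):
            raise InvalidInputError("theta0 must be finite")
        if self.dim_theta < 1 or self.dim_null < 0 or self.dim_null >= self.dim_theta:
            raise InvalidInputError(
                f"need 0 <= dim_null < dim_theta (k - h >= 1), got "
                f"k={self.dim_theta}, h={self.dim_null}"
            )

    @property
    def dof(self) -> int:
        """Chi-square degrees of freedom k - h for standardization."""
        return self.dim_theta - self.dim_null


@dataclass(frozen=True)
class TangentialRegion:
    """Union of disjoint intervals where the surprise exceeds s*."""

    intervals: tuple[tuple[float, float], ...]
    total_mass: float

    def __post_init__(self) -> None:
        for (a, b) in self.intervals:
            if not a <= b:
                raise InvalidInputError(f"malformed interval ({a}, {b})")
        for (_, b), (a2, _) in zip(self.intervals, self.intervals[1:]):
            if b > a2:
                raise InvalidInputError("intervals must be sorted and disjoint")

    @property
    def is_empty(self) -> bool:
        return len(self.intervals) == 0


@dataclass(frozen=True)
class FBSTResult:
    """Complete output of one Full Bayesian Significance Test."""

    ev_against: float
    ev_favor: float
    s_star: float
    sev_bar: float
    sev: float
    hypothesis: Hypothesis
    reference_label: str
    method: str
    ev0: float | None = None
    pv0: float | None = None
    ev_against_montecarlo: float | None = None
    n_draws: int | None = None
    bandwidth: float | None = None
    parameter_name: str = "param"

    @classmethod
    def from_ev_against(
        cls,
        ev_against: float,
        hypothesis: Hypothesis,
        *,
        s_star: float = float("nan"),
        reference_label: str = "flat",
        method: str = "quadrature",
        **extra,
    ) -> "FBSTResult":
        """Derive the complement and standardized values from ev_against."""
        sev_bar, sev = standardized_e_value(ev_against, hypothesis)
        return cls(
            ev_against=ev_against,
            ev_favor=1.0 - ev_against,
            s_star=s_star,
            sev_bar=sev_bar,
            sev=sev,
            hypothesis=hypothesis,
            reference_label=reference_label,
            method=method,
            **extra,
        )


def supremum_surprise(surprise: SurpriseGrid, hyp: Hypothesis) -> float:
    """s* = s(theta0): the surprise at the point null, linearly interpolated.

    Raises :class:`NullOutsideSupportError` if theta0 falls outside the
    evaluable grid range.
    """
    grid = surprise.grid
    theta0 = hyp.theta0
    lo, hi = float(grid[0]), float(grid[-1])
    if not (lo <= theta0 <= hi):
        raise NullOutsideSupportError(
            f"null value {theta0} outside the grid range [{lo:.6g}, {hi:.6g}]"
        )
    idx = int(np.searchsorted(grid, theta0))
    lo_idx = max(idx - 1, 0)
    hi_idx = min(idx, grid.size - 1)
    if not (surprise.evaluable[lo_idx] and surprise.evaluable[hi_idx]):
        raise NullOutsideSupportError(
            f"null value {theta0} lies where the reference function vanishes; "
            f"the surprise function is not evaluable there"
        )
    return float(surprise.at(theta0))


def tangential_region(
    surprise: SurpriseGrid, s_star: float, density: DensityEstimate | None = None
) -> TangentialRegion:
    """All maximal intervals on which s(theta) > s* strictly.

    Interval endpoints are refined by linear interpolation of the surprise
    across each crossing of the level s*; grid points tied exactly at s* are
    excluded (they belong to the complement, not the tangential set).  When
    ``density`` is given, ``total_mass`` is its integral over the region.
    """
    if s_star < 0:
        raise InvalidInputError(f"s_star must be >= 0, got {s_star}")
    grid = surprise.grid
    s = surprise.s_values
    above = s > s_star
    intervals: list[tuple[float, float]] = []
    n = grid.size
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        left = float(grid[i])
        if i > 0:
            left = _cross(grid[i - 1], grid[i], s[i - 1], s[i], s_star)
        right = float(grid[j])
        if j + 1 < n:
            right = _cross(grid[j], grid[j + 1], s[j], s[j + 1], s_star)
        intervals.append((left, right))
        i = j + 1
    region = TangentialRegion(intervals=tuple(intervals), total_mass=0.0)
    if density is not None:
        region = replace(
            region, total_mass=integrate_posterior_mass(density, region)
        )
    return region


def _cross(x0: float, x1: float, y0: float, y1: float, level: float) -> float:
    """Abscissa where the segment (x0,y0)-(x1,y1) crosses ``level``."""
    if y1 == y0:
        return float(x0)
    t = (level - y0) / (y1 - y0)
    return float(x0 + np.clip(t, 0.0, 1.0) * (x1 - x0))


def integrate_posterior_mass(
    density: DensityEstimate, region: TangentialRegion
) -> float:
    """Trapezoidal integral of the normalized posterior over a region."""
    total = 0.0
    for a, b in region.intervals:
        total += _integrate_interval(density, a, b)
    return float(np.clip(total, 0.0, 1.0))


def _integrate_interval(density: DensityEstimate, a: float, b: float) -> float:
    grid, dens = density.grid, density.density
    a = max(a, float(grid[0]))
    b = min(b, float(grid[-1]))
    if b <= a:
        return 0.0
    inside = (grid > a) & (grid < b)
    xs = np.concatenate(([a], grid[inside], [b]))
    ys = np.interp(xs, grid, dens)
    return float(np.trapezoid(ys, xs))


def e_value_montecarlo(
    draws: PosteriorDraws, surprise: SurpriseGrid, s_star: float
) -> float:
    """Draw-fraction estimate of the e-value against H0.

    The fraction of posterior draws whose interpolated surprise strictly
    exceeds s* — a linear search over the draw vector rather than a
    quadrature over the grid.  Draws are clipped to the grid range (the
    grid already extends three bandwidths beyond the draws).
    """
    theta = np.clip(draws.values, surprise.grid[0], surprise.grid[-1])
    s_at = surprise.at(theta)
    return float(np.mean(s_at > s_star))


def standardized_e_value(
    ev_against: float, hyp: Hypothesis
) -> tuple[float, float]:
    """Chi-square standardization of the e-value.

    Returns ``(sev_bar, sev)`` where ``sev_bar = F_{k-h}(F_k^{-1}(ev_against))``
    and ``sev = 1 - sev_bar``; F_k is the chi-square CDF with k degrees of
    freedom.  ``sev`` is the probability of obtaining the observed evidence
    against H0 or more, the test's p-value analogue.  Boundary inputs map
    exactly: 0 -> (0, 1) and 1 -> (1, 0); for h = 0 the map is the identity.
    """
    if not 0.0 <= ev_against <= 1.0:
        raise InvalidInputError(f"ev_against must be in [0, 1], got {ev_against}")
    if ev_against == 0.0:
        return 0.0, 1.0
    if ev_against == 1.0:
        return 1.0, 0.0
    k = hyp.dim_theta
    dof = hyp.dof
    if dof == k:
        # F_k o F_k^{-1} is the identity
        return float(ev_against), float(1.0 - ev_against)
    q = stats.chi2.ppf(np.clip(ev_against, _PPF_EPS, 1.0 - _PPF_EPS), df=k)
    sev_bar = float(stats.chi2.cdf(q, df=dof))
    return sev_bar, 1.0 - sev_bar


def asymptotic_ev0(posterior_mode: float, null_mode: float, k: int) -> float:
    """Large-sample Bayesian significance value ev0 = 1 - F_k(||m0 - M0||^2).

    ``posterior_mode`` (M0) is the mode of the posterior density estimate and
    ``null_mode`` (m0) the null value; their squared Euclidean distance is
    referred to the chi-square CDF with k degrees of freedom.  Rests on
    asymptotic posterior normality (Bernstein-von Mises).
    """
    if k < 1:
        raise InvalidInputError(f"k must be >= 1, got {k}")
    d0 = (null_mode - posterior_mode) ** 2
    return float(stats.chi2.sf(d0, df=k))


def asymptotic_pv0(neg2_log_relative_likelihood: float, hyp: Hypothesis) -> float:
    """Frequentist p-value pv0 = 1 - F_{k-h}(-2 lambda(m0)).

    The caller supplies the likelihood-ratio statistic -2 log L(m0)/L(M)
    (the library sees only posterior draws, never the likelihood); its upper
    chi-square tail with k - h degrees of freedom is returned, per Wilks'
    theorem.
    """
    stat = float(neg2_log_relative_likelihood)
    if stat < 0:
        raise InvalidInputError(f"-2*lambda(m0) must be >= 0, got {stat}")
    return float(stats.chi2.sf(stat, df=hyp.dof))


def run_fbst(
    draws: PosteriorDraws,
    hyp: Hypothesis,
    ref: ReferenceFunction = FLAT_REFERENCE,
    *,
    grid_size: int = DEFAULT_GRID_SIZE,
    bandwidth: float | str = "silverman",
    method: str = "quadrature",
    neg2_log_relative_likelihood: float | None = None,
    standardize_ev0_distance: bool = False,
) -> FBSTResult:
    """Run the complete Full Bayesian Significance Test on posterior draws.

    Pipeline: Gaussian KDE of the posterior -> surprise function against
    ``ref`` -> s* at the null value -> tangential set -> posterior mass of the
    tangential set (``ev_against``).  The standardized e-value, the complement
    ``ev_favor``, and the asymptotic ev0 are derived from it; pv0 is filled
    only when the caller supplies the likelihood-ratio statistic.

    Parameters
    ----------
    draws, hyp, ref
        Posterior draws, sharp null hypothesis, and reference function.
    grid_size, bandwidth
        Passed to :func:`estimate_posterior_density`.
    method
        ``"quadrature"`` reports the trapezoidal tangential-set mass (the
        default); ``"montecarlo"`` reports the draw-fraction estimate.  The
        other estimator is always recorded as a cross-check in
        ``ev_against_montecarlo`` / the result's metadata.
    neg2_log_relative_likelihood
        Optional statistic -2 log L(theta0)/L(MLE) enabling pv0.
    standardize_ev0_distance
        Divide the ev0 distance by the posterior standard deviation of the
        draws (off by default; the plain squared distance is the asymptotic
        formula).
    """
    if method not in ("quadrature", "montecarlo"):
        raise InvalidInputError(f"unknown method {method!r}")
    density = estimate_posterior_density(
        draws, grid_size=grid_size, bandwidth=bandwidth, extend_to=hyp.theta0
    )
    surprise = build_surprise(density, ref)
    s_star = supremum_surprise(surprise, hyp)
    region = tangential_region(surprise, s_star, density)
    ev_quad = region.total_mass
    ev_mc = e_value_montecarlo(draws, surprise, s_star)
    ev_against = ev_quad if method == "quadrature" else ev_mc
    ev_against = float(np.clip(ev_against, 0.0, 1.0))
    sev_bar, sev = standardized_e_value(ev_against, hyp)

    mode = density.mode
    if standardize_ev0_distance:
        sd = float(np.std(draws.values, ddof=1))
        ev0 = asymptotic_ev0(mode / sd, hyp.theta0 / sd, hyp.dim_theta)
    else:
        ev0 = asymptotic_ev0(mode, hyp.theta0, hyp.dim_theta)
    pv0 = (
        asymptotic_pv0(neg2_log_relative_likelihood, hyp)
        if neg2_log_relative_likelihood is not None
        else None
    )
    return FBSTResult(
        ev_against=ev_against,
        ev_favor=1.0 - ev_against,
        s_star=s_star,
        sev_bar=sev_bar,
        sev=sev,
        hypothesis=hyp,
        reference_label=ref.label,
        method=method,
        ev0=ev0,
        pv0=pv0,
        ev_against_montecarlo=ev_mc,
        n_draws=len(draws),
        bandwidth=density.bandwidth,
        parameter_name=draws.name,
    )


def fbst_artifacts(
    draws: PosteriorDraws,
    hyp: Hypothesis,
    ref: ReferenceFunction = FLAT_REFERENCE,
    *,
    grid_size: int = DEFAULT_GRID_SIZE,
    bandwidth: float | str = "silverman",
) -> tuple[DensityEstimate, SurpriseGrid, TangentialRegion, float]:
    """Intermediate pipeline objects (density, surprise, region, s*).

    Used by the plotting layer so the figure is drawn from exactly the grid
    the e-value was integrated on.
    """
    density = estimate_posterior_density(
        draws, grid_size=grid_size, bandwidth=bandwidth, extend_to=hyp.theta0
    )
    surprise = build_surprise(density, ref)
    s_star = supremum_surprise(surprise, hyp)
    region = tangential_region(surprise, s_star, density)
    return density, surprise, region, s_star
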