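"""The mixture index of fit (pi*).

pi*(tau, m) is the smallest contamination fraction ``pi`` such that the
truth can be written ``tau = (1 - pi) m + pi e`` with ``e`` an arbitrary
distribution: the fraction of the population intrinsically outside the
model.  For discrete distributions it has the closed form
``pi* = sup_t [1 - tau(t)/m(t)]``.  For continuous data the sample is
kernel smoothed and the supremum is restricted to the observed data range
(with a small density floor), because the unrestricted supremum equals 1
whenever the estimated density is lighter tailed than the model.  The
family-minimized index ``pi*(tau, M) = inf_theta pi*(tau, m_theta)`` is
computed by derivative-free simplex search with jittered restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from .continuous import (
    Grid,
    KernelDensityEstimate,
    Normal,
    ParametricModel,
)
from .discrete import total_variation

__all__ = [
    "PiStarResult",
    "pistar_fixed_discrete",
    "pistar_oracle",
    "pistar_fixed_continuous",
    "pistar_family",
    "w_index",
]

_TINY = 1e-300


@dataclass
class PiStarResult:
    """Estimated mixture index with the quantities that certify it."""

    pi_star: float
    theta_hat: tuple[float, ...] | None = None
    achieving_point: float | int | None = None
    residual: np.ndarray | None = None
    converged: bool = True
    meta: dict[str, Any] = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.pi_star)


def pistar_fixed_discrete(tau, m) -> PiStarResult:
    """Closed-form pi* against a fixed discrete distribution.

    ``pi* = sup over cells with m(t) > 0 of [1 - tau(t)/m(t)]`` clipped to
    ``[0, 1]``; a cell with ``tau(t) = 0 < m(t)`` forces ``pi* = 1``.  When
    ``0 < pi* < 1`` the residual distribution
    ``e*(t) = [tau(t) - (1 - pi*) m(t)] / pi*`` is returned; it is a valid
    distribution with a touching zero at the achieving cell, so the
    reconstruction ``(1 - pi*) m + pi* e*`` reproduces ``tau``.
    """
    t = np.asarray(tau, dtype=float)
    p = np.asarray(m, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"support sizes differ: {t.size} vs {p.size}")
    pos = p > 0
    ratio = np.full_like(t, np.inf)
    ratio[pos] = t[pos] / p[pos]
    idx = int(np.argmin(ratio))  # smallest index on ties
    pi = float(np.clip(1.0 - ratio[idx], 0.0, 1.0))
    residual = None
    if 0.0 < pi:
        residual = (t - (1.0 - pi) * p) / pi
        residual = np.where(np.abs(residual) < 1e-15, 0.0, residual)
    return PiStarResult(pi, achieving_point=idx, residual=residual)


def pistar_oracle(tau, m, grid_size: int = 1_000_000) -> float:
    """Feasibility-scan oracle for the discrete pi*.

    Scans the grid ``pi in {0, 1/grid_size, ..., 1}`` for the smallest value
    with ``tau(t) - (1 - pi) m(t) >= 0`` at every cell.  Feasibility is
    monotone in ``pi`` (the residual mass only grows), so the scan is
    carried out by bisection over the grid indices, which returns exactly
    the same grid point as a linear scan.
    """
    t = np.asarray(tau, dtype=float)
    p = np.asarray(m, dtype=float)
    if t.size > 50:
        raise ValueError("oracle limited to support <= 50")

    def feasible(pi: float) -> bool:
        return bool(np.all(t - (1.0 - pi) * p >= -1e-15))

    lo, hi = 0, grid_size  # grid point i corresponds to pi = i / grid_size
    if feasible(0.0):
        return 0.0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if feasible(mid / grid_size):
            hi = mid
        else:
            lo = mid
    return hi / grid_size


def _restricted_objective(grid_pts, tau_vals, tau_mass, lo, hi,
                          density_floor: float):
    """Build the pi* objective for a fixed smoothed density.

    Two constraints are combined: the pointwise supremum of
    ``1 - tau(t)/m(t)`` over grid points where the smoothed density is at
    least ``density_floor`` (a fraction of its maximum), and the
    mass-accounting bound ``[tau(R) - m(R)] / [1 - m(R)]`` for ``R`` the
    data range, which follows from integrating the mixture representation
    over ``R``.  The second constraint rules out models that place nearly
    all of their mass outside the observed range, for which the restricted
    pointwise supremum alone would spuriously approach zero.
    """
    mask = tau_vals >= density_floor * tau_vals.max()
    g = grid_pts[mask]
    t = tau_vals[mask]

    def objective(model: ParametricModel) -> tuple[float, float]:
        mv = np.maximum(model.pdf(g), _TINY)
        ratios = t / mv
        k = int(np.argmin(ratios))
        sup_grid = 1.0 - ratios[k]
        m_mass = float(model.cdf(hi) - model.cdf(lo))
        mass_bound = (tau_mass - m_mass) / max(1.0 - m_mass, 1e-12)
        return float(np.clip(max(sup_grid, mass_bound), 0.0, 1.0)), float(g[k])

    return objective


def pistar_fixed_continuous(x, model: ParametricModel,
                            grid: Grid | None = None,
                            density_floor: float = 0.01,
                            bandwidth: float | None = None) -> PiStarResult:
    """pi* of a kernel-smoothed sample against a fixed continuous model.

    The supremum grid spans ``[min(x), max(x)]`` only and drops points
    where the smoothed density falls below ``density_floor`` times its
    maximum; without that restriction any sample lighter tailed than the
    model would be scored as 100% outliers.
    """
    x = np.asarray(x, dtype=float)
    kde = KernelDensityEstimate(x, bandwidth)
    lo, hi = kde.support()
    if grid is None:
        grid = Grid(lo, hi, 512)
    pts = grid.points
    tau_vals = kde.pdf(pts)
    if not np.any(tau_vals >= density_floor * tau_vals.max()):
        raise ValueError("density floor leaves no grid points")
    tau_mass = float(np.trapezoid(tau_vals, pts))
    objective = _restricted_objective(pts, tau_vals, tau_mass,
                                      grid.lo, grid.hi, density_floor)
    value, at = objective(model)
    residual = None
    if value > 0.0:
        mv = model.pdf(pts)
        residual = np.maximum(tau_vals - (1.0 - value) * mv, 0.0) / value
    return PiStarResult(value, achieving_point=at, residual=residual,
                        meta={"bandwidth": kde.bandwidth,
                              "density_floor": density_floor})


def pistar_family(x, theta_init=(0.0, 1.0), grid: Grid | None = None,
                  density_floor: float = 0.01, bandwidth: float | None = None,
                  n_restarts: int = 5, seed=0,
                  maxiter: int = 400) -> PiStarResult:
    """Family-minimized mixture index over the normal family.

    Minimizes ``theta -> pi*(tau_hat, N(mu, sigma^2))`` by Nelder-Mead in
    ``(mu, log sigma)`` starting from ``theta_init`` (mean 0, variance 1 by
    default) plus ``n_restarts`` jittered restarts, keeping the best value.
    The smoothed density is computed once; each objective evaluation only
    prices the candidate normal on the fixed grid.
    """
    x = np.asarray(x, dtype=float)
    kde = KernelDensityEstimate(x, bandwidth)
    lo, hi = kde.support()
    if grid is None:
        grid = Grid(lo, hi, 512)
    pts = grid.points
    tau_vals = kde.pdf(pts)
    tau_mass = float(np.trapezoid(tau_vals, pts))
    objective = _restricted_objective(pts, tau_vals, tau_mass,
                                      grid.lo, grid.hi, density_floor)

    def f(p):
        return objective(Normal(p[0], float(np.exp(p[1]))))[0]

    mu0, sigma0 = float(theta_init[0]), float(theta_init[1])
    if sigma0 <= 0:
        raise ValueError("initial sigma must be positive")
    rng = np.random.default_rng(seed)
    starts = [(mu0, np.log(sigma0))]
    starts += [(mu0 + rng.normal(0.0, 1.0),
                np.log(sigma0) + rng.normal(0.0, 0.5))
               for _ in range(n_restarts)]
    best = None
    any_converged = False
    for p0 in starts:
        res = optimize.minimize(f, p0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": maxiter})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    mu_hat, sigma_hat = float(best.x[0]), float(np.exp(best.x[1]))
    model = Normal(mu_hat, sigma_hat)
    value, at = objective(model)
    residual = None
    if value > 0.0:
        mv = model.pdf(pts)
        residual = np.maximum(tau_vals - (1.0 - value) * mv, 0.0) / value
    return PiStarResult(value, theta_hat=(mu_hat, sigma_hat),
                        achieving_point=at, residual=residual,
                        converged=any_converged,
                        meta={"bandwidth": kde.bandwidth,
                              "density_floor": density_floor,
                              "n_restarts": n_restarts})


def w_index(tau, m) -> float:
    """W index ``V / (1 + V)``: the common contamination level at which the
    two distributions admit a shared two-component mixture representation.
    Takes values in ``[0, 1/2]`` and agrees with ``V`` to first order.
    """
    v = total_variation(tau, m).value
    return v / (1.0 + v)
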