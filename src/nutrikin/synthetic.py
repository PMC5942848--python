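"""Synthetic data generators.

Two kinds of inputs are emulated so that every stage of the analysis is
testable without external data:

* short-incubation uptake experiments — a substrate grid, a true
  rectangular-hyperbola rate curve, and multiplicative lognormal
  measurement noise (uptake-rate error scales with magnitude);
* empirically shaped Tmax-versus-N:C response tables — transport
  capacity rising under moderate N stress, collapsing at extreme
  stress, and (optionally, nitrate-style) repressed below the growth
  requirement near the replete quota.

All generators thread an explicit seed through a local
``numpy.random.Generator``; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import NutrikinError
from .quota import QuotaParams, normalized_quota

DEFAULT_NOISE_CV = 0.1
DEFAULT_N_POINTS = 20


def default_uptake_grid(
    true_K: float, n: int = DEFAULT_N_POINTS
) -> np.ndarray:
    """Log-spaced substrate grid spanning 0.05·K to 50·K (μM).

    Three decades bracketing the half-saturation, the layout of an
    uptake assay designed to resolve both the initial slope and the
    plateau.
    """
    return np.geomspace(0.05 * true_K, 50.0 * true_K, n)


@dataclass(frozen=True)
class UptakeExperiment:
    """One simulated short-incubation uptake experiment."""

    substrate: np.ndarray   # μM, strictly increasing
    rate: np.ndarray        # observed rates, same units as true_Vmax
    true_Vmax: float
    true_K: float
    noise_cv: float
    seed: int


def gen_uptake_experiment(
    true_Vmax: float,
    true_K: float,
    grid: np.ndarray | None = None,
    noise_cv: float = DEFAULT_NOISE_CV,
    seed: int = 0,
) -> UptakeExperiment:
    """Hyperbolic rates on a substrate grid with multiplicative noise.

    Observed rate = Vmax·S/(S+K) × ε, with ε lognormal, mean 1 and
    coefficient of variation ``noise_cv``.  ``noise_cv = 0`` returns the
    exact curve.  Bit-reproducible for a given (parameters, seed).
    """
    if true_Vmax <= 0 or true_K <= 0:
        raise NutrikinError("true_Vmax and true_K must be positive")
    if noise_cv < 0:
        raise NutrikinError("noise_cv must be non-negative")
    if grid is None:
        grid = default_uptake_grid(true_K)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise NutrikinError("substrate grid must be non-negative, increasing")
    rate = true_Vmax * grid / (grid + true_K)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        rate = rate * rng.lognormal(-0.5 * sigma**2, sigma, grid.size)
    return UptakeExperiment(
        substrate=grid,
        rate=rate,
        true_Vmax=true_Vmax,
        true_K=true_K,
        noise_cv=noise_cv,
        seed=seed,
    )


@dataclass(frozen=True)
class SyntheticTmaxTable:
    """Tabulated Tmax-versus-N:C curve plus its smooth generating function."""

    NC: np.ndarray             # gN gC^-1 knots, increasing
    Tmax_specific: np.ndarray  # gN gC^-1 d^-1
    generating_function: Callable[[float], float]
    peak_NC: float
    seed: int

    def table(self) -> np.ndarray:
        return np.column_stack([self.NC, self.Tmax_specific])


def gen_tmax_table(
    quota_params: QuotaParams | None = None,
    floor: float | None = None,
    peak_multiplier: float = 4.0,
    collapse_fraction: float = 0.25,
    n_knots: int = 12,
    seed: int = 0,
    nitrate_repression: bool = False,
) -> SyntheticTmaxTable:
    """Unimodal Tmax(N:C) table shaped like measured transport curves.

    The curve is a Gaussian bump over a linear baseline, parameterized
    on the normalized quota NCu: it holds ``floor`` at the replete quota
    (``floor`` defaults to 1.05 × G_max·NC_max, just above the growth
    requirement so the nutrient remains feasible), peaks at
    ``floor × peak_multiplier`` under moderate stress (peak position and
    width drawn reproducibly from the seed), and collapses to
    ``collapse_fraction`` of the peak at extreme stress (NC_min).  With
    ``nitrate_repression`` the replete end drops below the growth
    requirement, emulating end-product repression of nitrate transport.

    Raises a domain error if the requested parameters fail to produce a
    single-interior-maximum, non-negative curve.
    """
    if quota_params is None:
        quota_params = QuotaParams()
    if peak_multiplier <= 1:
        raise NutrikinError("peak_multiplier must exceed 1")
    if not (0 <= collapse_fraction < 1):
        raise NutrikinError("collapse_fraction must be in [0, 1)")
    if n_knots < 4:
        raise NutrikinError("need at least 4 knots")
    q = quota_params
    if floor is None:
        floor = 1.05 * q.G_max * q.NC_max
    peak = floor * peak_multiplier
    end_val = (0.7 if nitrate_repression else 1.0) * floor

    rng = np.random.default_rng(seed)
    u_peak = rng.uniform(0.25, 0.40)
    width = rng.uniform(0.16, 0.22)

    def bump(u: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-0.5 * ((u - u_peak) / width) ** 2)

    # Solve the linear system pinning f(0), f(1) and f(u_peak):
    #   f(u) = b0 + (b1 - b0)·u + A·bump(u)
    A_mat = np.array(
        [
            [1.0, 0.0, float(bump(0.0))],
            [0.0, 1.0, float(bump(1.0))],
            [1.0 - u_peak, u_peak, 1.0],
        ]
    )
    rhs = np.array([collapse_fraction * peak, end_val, peak])
    b0, b1, A = np.linalg.solve(A_mat, rhs)

    def f_of_u(u: np.ndarray | float):
        return b0 + (b1 - b0) * np.asarray(u, dtype=float) + A * bump(u)

    # Validate shape on a dense grid: non-negative, one interior maximum.
    u_dense = np.linspace(0.0, 1.0, 512)
    vals = f_of_u(u_dense)
    if np.any(vals < 0):
        raise NutrikinError("parameters produce negative Tmax values")
    sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(vals)))) > 0)
    i_max = int(np.argmax(vals))
    if sign_changes > 2 or i_max in (0, u_dense.size - 1):
        raise NutrikinError(
            "parameters violate unimodality of the Tmax curve"
        )

    nc_knots = np.linspace(q.NC_min, q.NC_max, n_knots)
    u_knots = np.array([normalized_quota(nc, q) for nc in nc_knots])
    tmax_knots = np.asarray(f_of_u(u_knots), dtype=float)

    def generating_function(NC: float) -> float:
        nc = float(np.clip(NC, q.NC_min, q.NC_max))
        return float(f_of_u(normalized_quota(nc, q)))

    # Locate the peak on the NC axis (knot-free, from the smooth curve).
    nc_dense = np.linspace(q.NC_min, q.NC_max, 512)
    dense_vals = [generating_function(nc) for nc in nc_dense]
    peak_NC = float(nc_dense[int(np.argmax(dense_vals))])

    return SyntheticTmaxTable(
        NC=nc_knots,
        Tmax_specific=tmax_knots,
        generating_function=generating_function,
        peak_NC=peak_NC,
        seed=seed,
    )
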