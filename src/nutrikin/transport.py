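"""Transporter rate density and saturable membrane transport.

The cell membrane can hold only so many transporter proteins per unit
area, capping the transporter rate density at ``TRD_max``
(pgN μm⁻² d⁻¹).  Sustaining growth at ``G_max`` requires a density
``TRD_Gmax = G_max·NC_max·C_cell/SA``; the headroom between the two is
the over-capacity index ``δ_TRD = TRD_max/TRD_Gmax`` and, in relative
form, the multiplier ``T_add = (TRD_max − TRD_Gmax)/TRD_Gmax``.

Nutrient-stressed cells up-regulate transport: the instantaneous maximum
C-specific transport rate rises from the replete floor ``G_max·NC_max``
toward ``(1+T_add)`` times that floor as the normalized N status NCu
falls from 1 to 0, following a normalized saturating curve shaped by
``KT_con``.  Actual transport obeys Michaelis–Menten kinetics in the
membrane-surface substrate concentration S0 with half-saturation
``K_T``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import InfeasibleConfigError, NutrikinError, SaturationError
from .quota import QuotaParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransporterParams:
    """Transporter kinetics and expression-ceiling parameters.

    K_T : μM, half-saturation at the membrane surface;
    TRD_max : pgN μm⁻² d⁻¹, ceiling of transporter rate density;
    KT_con : dimensionless shape constant of the stress-response curve
    (smaller values make the up-regulation steeper).
    """

    K_T: float = 1.0
    TRD_max: float = 0.4
    KT_con: float = 0.1

    def __post_init__(self) -> None:
        for name in ("K_T", "TRD_max", "KT_con"):
            if getattr(self, name) <= 0:
                raise NutrikinError(f"TransporterParams.{name} must be positive")


@dataclass(frozen=True)
class TransportCapacity:
    """Transport capacity of one configuration at one N status."""

    TRD_Gmax: float       # pgN μm^-2 d^-1
    T_add: float          # dimensionless
    delta_TRD: float      # TRD_max / TRD_Gmax
    Tmax_specific: float  # gN gC^-1 d^-1 at the given NCu
    Tmax_cell: float      # pgN cell^-1 d^-1


def trd_gmax(G_max: float, NC_max: float, C_cell: float, SA: float) -> float:
    """Transporter rate density needed to sustain G_max, pgN μm⁻² d⁻¹."""
    if min(G_max, NC_max, C_cell, SA) <= 0:
        raise NutrikinError("trd_gmax inputs must be positive")
    return G_max * NC_max * C_cell / SA


def t_add(TRD_max: float, TRD_Gmax: float) -> float:
    """Relative transport over-capacity (TRD_max − TRD_Gmax)/TRD_Gmax.

    Raises :class:`InfeasibleConfigError` when the required density
    exceeds the ceiling — such a cell cannot attain G_max at all.
    """
    if TRD_Gmax <= 0:
        raise NutrikinError("TRD_Gmax must be positive")
    if TRD_Gmax > TRD_max:
        raise InfeasibleConfigError(
            f"TRD_Gmax={TRD_Gmax:.4g} exceeds TRD_max={TRD_max:.4g}: "
            "G_max unattainable for this size/carbon density"
        )
    return (TRD_max - TRD_Gmax) / TRD_Gmax


def tmax_hypothetical(
    NCu: float, quota_params: QuotaParams, T_add: float, KT_con: float
) -> float:
    """C-specific maximum transport rate at N status NCu, gN gC⁻¹ d⁻¹.

    Tmax = G_max·NC_max·(1 + T_add·(1+KT_con)(1−NCu)/((1−NCu)+KT_con)).
    The bracketed stress term is a normalized hyperbola: it equals 0 at
    NCu = 1 and exactly 1 at NCu = 0 for any KT_con, so the curve spans
    [floor, floor·(1+T_add)].  Multiply by C_cell for the per-cell rate.
    """
    if not (0.0 <= NCu <= 1.0):
        raise NutrikinError(f"NCu={NCu} outside [0, 1]")
    if T_add < 0:
        raise NutrikinError("T_add must be non-negative")
    stress = 1.0 - NCu
    shape = (1.0 + KT_con) * stress / (stress + KT_con)
    floor = quota_params.G_max * quota_params.NC_max
    return floor * (1.0 + T_add * shape)


def transport_capacity(
    NCu: float,
    quota_params: QuotaParams,
    transporter: TransporterParams,
    C_cell: float,
    SA: float,
) -> TransportCapacity:
    """Full transport-capacity budget at one N status."""
    TRDG = trd_gmax(quota_params.G_max, quota_params.NC_max, C_cell, SA)
    Tadd = t_add(transporter.TRD_max, TRDG)
    Tmax_sp = tmax_hypothetical(NCu, quota_params, Tadd, transporter.KT_con)
    return TransportCapacity(
        TRD_Gmax=TRDG,
        T_add=Tadd,
        delta_TRD=transporter.TRD_max / TRDG,
        Tmax_specific=Tmax_sp,
        Tmax_cell=Tmax_sp * C_cell,
    )


def transport_rate(S0: float, Tmax_cell: float, K_T: float) -> float:
    """Saturating transport at membrane substrate S0 (μM), pgN cell⁻¹ d⁻¹."""
    if S0 < 0:
        raise NutrikinError("S0 must be non-negative")
    return Tmax_cell * S0 / (S0 + K_T)


def substrate_at_membrane(T: float, Tmax_cell: float, K_T: float) -> float:
    """Membrane substrate concentration S0 (μM) sustaining transport T.

    S0 = T·K_T/(Tmax_cell − T); the exact inverse of
    :func:`transport_rate`.  Demand at or above capacity raises
    :class:`SaturationError` (no finite concentration suffices).
    """
    if T < 0:
        raise NutrikinError("T must be non-negative")
    if T >= Tmax_cell:
        raise SaturationError(
            f"demand T={T:.4g} >= capacity Tmax={Tmax_cell:.4g} "
            "pgN cell^-1 d^-1"
        )
    return T * K_T / (Tmax_cell - T)


def empirical_tmax_curve(
    table: Sequence[tuple[float, float]] | np.ndarray,
) -> Callable[[float], float]:
    """Monotone-preserving interpolator through (NC, Tmax_specific) pairs.

    Built on a piecewise-cubic Hermite (PCHIP) scheme, which cannot
    overshoot between knots — important because measured Tmax curves are
    smooth, non-negative and unimodal, and spline ringing would create
    spurious negative capacity.  Queries outside the tabulated quota
    range are clamped to the end values with a logged warning.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise NutrikinError("need >= 3 (NC, Tmax) pairs")
    nc, tmax = arr[:, 0], arr[:, 1]
    if not np.all(np.diff(nc) > 0):
        raise NutrikinError("NC knots must be strictly increasing")
    if np.any(tmax < 0):
        raise NutrikinError("Tmax values must be non-negative")
    interp = PchipInterpolator(nc, tmax, extrapolate=False)
    lo, hi = nc[0], nc[-1]

    def curve(NC: float) -> float:
        x = float(NC)
        if x < lo or x > hi:
            logger.warning(
                "Tmax query NC=%.4g outside table range [%.4g, %.4g]; "
                "clamping", x, lo, hi,
            )
            x = min(max(x, lo), hi)
        return float(interp(x))

    return curve


def multi_transporter_halfsat(
    n_transporters: float, k_cat: float, K_T: float, demand_at_Gmax: float
) -> float:
    """Substrate concentration supporting half-maximal growth when many
    identical transporters share the load.

    Solves n·k_cat·S/(S+K_T) = demand/2 for S, giving
    S = K_T·(d/2)/(n·k_cat − d/2).  As transporter number rises the
    apparent half-saturation falls below the per-protein K_T, vanishing
    in the limit n → ∞.
    """
    half_demand = demand_at_Gmax / 2.0
    capacity = n_transporters * k_cat
    if capacity <= half_demand:
        raise SaturationError(
            "total transporter capacity <= half of the demand at G_max"
        )
    return K_T * half_demand / (capacity - half_demand)
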