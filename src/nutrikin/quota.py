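"""Normalized N:C quota control of growth.

Growth under nitrogen limitation is governed by the cellular N:C mass
ratio (the quota, ``NC``), bounded by ``NC_min`` (growth stops) and
``NC_max`` (growth at ``G_max``).  The quota is mapped onto a normalized
status ``NCu`` in [0, 1] through a saturating curve whose shape constant
``KQ`` controls curvature; at ``KQ = 10`` the map is nearly linear, the
behaviour expected for N-quota physiology.  Growth is then
``G = G_max · NCu``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NutrikinError


@dataclass(frozen=True)
class QuotaParams:
    """Stoichiometric parameters of the N quota–growth relationship.

    NC_max, NC_min : gN gC⁻¹ quota bounds; KQ : dimensionless shape
    constant; G_max : d⁻¹ maximum growth rate.
    """

    NC_max: float = 0.18
    NC_min: float = 0.05
    KQ: float = 10.0
    G_max: float = 0.693

    def __post_init__(self) -> None:
        if not (0 < self.NC_min < self.NC_max):
            raise NutrikinError("need 0 < NC_min < NC_max")
        if self.KQ <= 0:
            raise NutrikinError("KQ must be positive")
        if self.G_max <= 0:
            raise NutrikinError("G_max must be positive")


@dataclass(frozen=True)
class QuotaState:
    """Quota, normalized status and growth rate at one operating point."""

    NC: float   # gN gC^-1
    NCu: float  # dimensionless, in [0, 1]
    G: float    # d^-1


def normalized_quota(NC: float, params: QuotaParams) -> float:
    """Normalized N status NCu ∈ [0, 1] from the N:C quota.

    NCu = (1+KQ)(NC − NC_min) / ((NC − NC_min) + KQ(NC_max − NC_min)).
    """
    if not (params.NC_min <= NC <= params.NC_max):
        raise NutrikinError(
            f"NC={NC} outside quota bounds "
            f"[{params.NC_min}, {params.NC_max}]"
        )
    x = NC - params.NC_min
    span = params.NC_max - params.NC_min
    return (1.0 + params.KQ) * x / (x + params.KQ * span)


def quota_from_nstatus(NCu: float, params: QuotaParams) -> float:
    """Exact algebraic inverse of :func:`normalized_quota`.

    NC = NC_min + NCu·KQ·(NC_max − NC_min) / (1 + KQ − NCu).
    """
    if not (0.0 <= NCu <= 1.0):
        raise NutrikinError(f"NCu={NCu} outside [0, 1]")
    span = params.NC_max - params.NC_min
    return params.NC_min + NCu * params.KQ * span / (1.0 + params.KQ - NCu)


def growth_rate(NCu: float, params: QuotaParams) -> float:
    """Growth rate under normalized-quota control: G = G_max · NCu."""
    if not (0.0 <= NCu <= 1.0):
        raise NutrikinError(f"NCu={NCu} outside [0, 1]")
    return params.G_max * NCu


def required_transport(G: float, NC: float, C_cell: float) -> float:
    """Steady-state N transport demand, pgN cell⁻¹ d⁻¹.

    A cell of carbon content ``C_cell`` (pgC) growing at rate ``G``
    (d⁻¹) while holding quota ``NC`` (gN gC⁻¹) must import
    ``G · NC · C_cell`` of nitrogen per day.
    """
    if G < 0 or NC < 0 or C_cell < 0:
        raise NutrikinError("required_transport inputs must be non-negative")
    return G * NC * C_cell


def quota_state(G: float, params: QuotaParams) -> QuotaState:
    """Quota state consistent with growing at rate ``G``."""
    if not (0.0 <= G <= params.G_max):
        raise NutrikinError(f"G={G} outside [0, G_max={params.G_max}]")
    NCu = G / params.G_max
    return QuotaState(NC=quota_from_nstatus(NCu, params), NCu=NCu, G=G)
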