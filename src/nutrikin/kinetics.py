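"""Emergent growth kinetics: from cell traits to K_G and its scaling.

The central computation chains the component models, with no iteration:
for a growth rate G, the quota inverse gives the N:C the cell must hold;
demand is ``T = G·NC·C_cell``; the stress-dependent capacity Tmax and
the Michaelis–Menten inverse give the membrane concentration S0; and the
boundary-layer inverse lifts S0 to the bulk concentration S_∞.  The bulk
concentration at G = G_max/2 is the emergent growth half-saturation
constant K_G — an output of the physiology, not an input constant.

On top of the point solver the module provides growth sweeps (kinetic
curves), trait-space scans over cell size, power-law fits of G_max/K_G
against ESD, rectangular-hyperbola (Michaelis–Menten/Monod, "RHt2")
fits to the emergent curves, K_T sensitivity, and the transporter-
density feasibility surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .diffusion import DiffusionContext, bulk_substrate
from .errors import FitError, NutrikinError, SaturationError
from .geometry import (
    CarbonModel,
    CellMorphology,
    Environment,
    morphology,
    resolve_carbon_model,
    sinking_speed,
    swimming_speed,
)
from .quota import QuotaParams, quota_from_nstatus, required_transport
from .transport import (
    TransporterParams,
    substrate_at_membrane,
    t_add,
    tmax_hypothetical,
    trd_gmax,
)

logger = logging.getLogger(__name__)

Motion = Literal["none", "swim", "sink"]
TmaxMode = Literal["stress", "flat", "empirical"]


@dataclass(frozen=True)
class OrganismConfig:
    """Complete trait set of one organism configuration.

    ``tmax_mode`` selects how the maximum transport rate responds to N
    status: ``stress`` (stress-dependent up-regulation with the headroom
    implied by TRD_max), ``flat`` (constant at the replete floor, as most
    ecosystem models assume), or ``empirical`` (a tabulated
    Tmax-versus-N:C curve supplied as ``tmax_curve``).
    """

    ESD: float
    carbon_model: CarbonModel | str = "C150"
    motion: Motion = "none"
    quota: QuotaParams = field(default_factory=QuotaParams)
    transporter: TransporterParams = field(default_factory=TransporterParams)
    tmax_mode: TmaxMode = "stress"
    tmax_curve: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.motion not in ("none", "swim", "sink"):
            raise NutrikinError(f"unknown motion mode {self.motion!r}")
        if self.tmax_mode not in ("stress", "flat", "empirical"):
            raise NutrikinError(f"unknown tmax mode {self.tmax_mode!r}")
        if self.tmax_mode == "empirical" and self.tmax_curve is None:
            raise NutrikinError("empirical tmax mode requires tmax_curve")
        # Feasibility at construction: raises InfeasibleConfigError when
        # the density required for G_max exceeds the membrane ceiling.
        morph = self.morphology()
        t_add(
            self.transporter.TRD_max,
            trd_gmax(self.quota.G_max, self.quota.NC_max, morph.C_cell, morph.SA),
        )

    def morphology(self) -> CellMorphology:
        return morphology(self.ESD, resolve_carbon_model(self.carbon_model))

    def speed_um_s(self, env: Environment) -> float:
        """Motion speed per the configured mode, μm s⁻¹."""
        if self.motion == "swim":
            return swimming_speed(self.ESD)
        if self.motion == "sink":
            return sinking_speed(self.ESD / 2.0, env)
        return 0.0

    def provenance(self, env: Environment) -> dict[str, Any]:
        """Flat snapshot of the resolved configuration, for output headers."""
        model = resolve_carbon_model(self.carbon_model)
        d: dict[str, Any] = {
            "ESD": self.ESD,
            "carbon_model": self.carbon_model
            if isinstance(self.carbon_model, str)
            else model.kind,
            "motion": self.motion,
            "tmax_mode": self.tmax_mode,
        }
        if model.kind == "fixed_density":
            d["carbon_density"] = model.density
        else:
            d["carbon_a"], d["carbon_b"] = model.a, model.b
        d.update(
            NC_max=self.quota.NC_max,
            NC_min=self.quota.NC_min,
            KQ=self.quota.KQ,
            G_max=self.quota.G_max,
            K_T=self.transporter.K_T,
            TRD_max=self.transporter.TRD_max,
            KT_con=self.transporter.KT_con,
            D=env.D,
            eta=env.eta,
            rho_org=env.rho_org,
            rho_w=env.rho_w,
            g=env.g,
            molar_mass_N=env.molar_mass_N,
        )
        return d


@dataclass(frozen=True)
class PhysiologicalState:
    """Quota, transport and substrate concentrations at one growth rate."""

    G: float           # d^-1
    NC: float          # gN gC^-1
    NCu: float         # dimensionless
    T: float           # pgN cell^-1 d^-1
    Tmax_cell: float   # pgN cell^-1 d^-1
    S0: float          # μM
    S_inf: float       # μM


@dataclass(frozen=True)
class KineticCurve:
    """Emergent (S_∞, S_0, G) relation over a growth sweep."""

    states: pd.DataFrame
    provenance: dict[str, Any]

    @property
    def S_inf(self) -> np.ndarray:
        return self.states["S_inf"].to_numpy()

    @property
    def G(self) -> np.ndarray:
        return self.states["G"].to_numpy()


@dataclass(frozen=True)
class FitResult:
    """Parameters and goodness-of-fit of a curve fit."""

    model: Literal["RHt2_free", "RHt2_fixed_max", "power_law"]
    params: dict[str, float]
    r_squared: float
    rmse: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "power_law":
            return self.params["a"] * x ** self.params["b"]
        V, K = self.params["Vmax"], self.params["K"]
        return V * x / (x + K)


@dataclass(frozen=True)
class KGResult:
    """Emergent half-saturation constant and its additive components."""

    K_G: float        # μM, bulk medium
    S0: float         # μM, membrane-surface component
    diffusion: float  # μM, boundary-layer gradient (K_G − S0)

    def __float__(self) -> float:
        return self.K_G


def _tmax_specific(config: OrganismConfig, NC: float, NCu: float) -> float:
    """C-specific maximum transport rate under the configured mode."""
    q, tp = config.quota, config.transporter
    if config.tmax_mode == "flat":
        return q.G_max * q.NC_max
    if config.tmax_mode == "empirical":
        return config.tmax_curve(NC)
    morph = config.morphology()
    Tadd = t_add(tp.TRD_max, trd_gmax(q.G_max, q.NC_max, morph.C_cell, morph.SA))
    return tmax_hypothetical(NCu, q, Tadd, tp.KT_con)


def solve_state_at_growth(
    G: float, config: OrganismConfig, env: Environment
) -> PhysiologicalState:
    """Deterministic forward solution of the physiology at growth rate G.

    Chains quota inverse → demand → capacity → membrane substrate →
    bulk substrate.  Raises :class:`SaturationError` when the demand
    meets or exceeds the instantaneous capacity (e.g. G = G_max in flat
    Tmax mode).
    """
    q = config.quota
    if not (0.0 <= G <= q.G_max):
        raise NutrikinError(f"G={G} outside [0, G_max={q.G_max}]")
    morph = config.morphology()
    NCu = G / q.G_max
    NC = quota_from_nstatus(NCu, q)
    T = required_transport(G, NC, morph.C_cell)
    Tmax_cell = _tmax_specific(config, NC, NCu) * morph.C_cell
    S0 = substrate_at_membrane(T, Tmax_cell, config.transporter.K_T)
    ctx = DiffusionContext.from_environment(
        morph.radius, env, config.speed_um_s(env)
    )
    S_inf = bulk_substrate(T, S0, ctx)
    return PhysiologicalState(
        G=G, NC=NC, NCu=NCu, T=T, Tmax_cell=Tmax_cell, S0=S0, S_inf=S_inf
    )


def half_saturation_growth(config: OrganismConfig, env: Environment) -> KGResult:
    """Emergent K_G: the bulk substrate concentration at G = G_max/2.

    Evaluated directly at NCu = 0.5 (the forward chain is explicit, so
    no root-finding is needed).  The result decomposes additively into
    the membrane-surface component S0 and the diffusion-gradient
    component.
    """
    state = solve_state_at_growth(config.quota.G_max / 2.0, config, env)
    return KGResult(
        K_G=state.S_inf, S0=state.S0, diffusion=state.S_inf - state.S0
    )


def kinetic_curve(
    config: OrganismConfig,
    env: Environment,
    g_grid: Sequence[float] | np.ndarray | None = None,
) -> KineticCurve:
    """Sweep growth rate and tabulate the emergent states.

    The default grid is 200 evenly spaced points on [0, G_max).  Points
    at which demand saturates capacity are truncated with a warning.
    """
    q = config.quota
    if g_grid is None:
        g_grid = np.linspace(0.0, q.G_max, 200, endpoint=False)
    rows = []
    for G in np.asarray(g_grid, dtype=float):
        try:
            s = solve_state_at_growth(float(G), config, env)
        except SaturationError:
            logger.warning(
                "growth sweep truncated at G=%.4g (transport saturated)", G
            )
            break
        rows.append(s.__dict__)
    df = pd.DataFrame(rows)
    return KineticCurve(states=df, provenance=config.provenance(env))


def esd_scan(
    config_template: OrganismConfig,
    env: Environment,
    esd_grid: Sequence[float] | np.ndarray | None = None,
) -> pd.DataFrame:
    """K_G across cell sizes for one configuration.

    Returns a long-format table with columns ESD, feasible, K_G, S0,
    Gmax_over_KG and error.  Infeasible sizes (TRD_Gmax > TRD_max) are
    recorded, not raised, and are excluded from downstream fits.
    """
    from dataclasses import replace

    if esd_grid is None:
        esd_grid = default_esd_grid()
    rows = []
    for esd in np.asarray(esd_grid, dtype=float):
        row: dict[str, Any] = {"ESD": float(esd), "feasible": True, "error": ""}
        try:
            cfg = replace(config_template, ESD=float(esd))
            res = half_saturation_growth(cfg, env)
            row.update(
                K_G=res.K_G,
                S0=res.S0,
                Gmax_over_KG=config_template.quota.G_max / res.K_G,
            )
        except NutrikinError as exc:
            row.update(
                feasible=False, K_G=np.nan, S0=np.nan, Gmax_over_KG=np.nan,
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def default_esd_grid(
    lo: float = 2.0, hi: float = 80.0, n: int = 25
) -> np.ndarray:
    """Default log-spaced cell-size grid for scans, μm."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def power_fit(
    scan_table: pd.DataFrame | np.ndarray,
    x: str = "ESD",
    y: str = "Gmax_over_KG",
) -> FitResult:
    """Ordinary least squares of log10(y) on log10(x): y = a·x^b.

    Accepts the output of :func:`esd_scan` (infeasible rows are dropped)
    or a two-column array.  R² is reported on the log scale on which the
    regression is performed.
    """
    if isinstance(scan_table, pd.DataFrame):
        df = scan_table
        if "feasible" in df.columns:
            df = df[df["feasible"]]
        xv = df[x].to_numpy(dtype=float)
        yv = df[y].to_numpy(dtype=float)
    else:
        arr = np.asarray(scan_table, dtype=float)
        xv, yv = arr[:, 0], arr[:, 1]
    mask = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[mask], yv[mask]
    if xv.size < 5:
        raise NutrikinError("power_fit needs >= 5 finite points")
    if np.any(xv <= 0) or np.any(yv <= 0):
        raise NutrikinError("power_fit requires strictly positive values")
    lx, ly = np.log10(xv), np.log10(yv)
    b, loga = np.polyfit(lx, ly, 1)
    resid = ly - (loga + b * lx)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(
        model="power_law",
        params={"a": float(10**loga), "b": float(b)},
        r_squared=r2,
        rmse=float(np.sqrt(ss_res / lx.size)),
        n=int(lx.size),
    )


def _rht2(S: np.ndarray, V: float, K: float) -> np.ndarray:
    return V * S / (S + K)


def _reciprocal_init(S: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Double-reciprocal (Lineweaver–Burk) starting values."""
    mask = (S > 0) & (y > 0)
    if mask.sum() < 2:
        return float(y.max() if y.size else 1.0), float(np.median(S) or 1.0)
    slope, icpt = np.polyfit(1.0 / S[mask], 1.0 / y[mask], 1)
    if icpt <= 0 or slope <= 0:
        return float(y.max()), float(np.median(S[mask]))
    return 1.0 / icpt, slope / icpt


def fit_rht2(
    curve: KineticCurve | pd.DataFrame | np.ndarray,
    fix_max: float | None = None,
    loss: Literal["linear", "log"] = "linear",
) -> FitResult:
    """Nonlinear least-squares fit of a rectangular hyperbola (RHt2).

    Fits V·S/(S+K) to (S_∞, rate) data — an emergent kinetic curve or
    any uptake-style data set.  With ``fix_max`` the plateau is pinned
    (e.g. to G_max) and only K is free.  ``loss="log"`` minimizes
    log-scale residuals, the maximum-likelihood choice for data with
    multiplicative (lognormal) noise; the default linear loss matches
    conventional least-squares curve fitting.  The fitted K is an
    apparent bulk half-saturation (a K_U-style parameter), not the
    transporter constant K_T.
    """
    if isinstance(curve, KineticCurve):
        S, y = curve.S_inf, curve.G
    elif isinstance(curve, pd.DataFrame):
        S = curve["S_inf"].to_numpy(dtype=float)
        y = curve["G"].to_numpy(dtype=float)
    else:
        arr = np.asarray(curve, dtype=float)
        S, y = arr[:, 0], arr[:, 1]
    if S.size < 5:
        raise NutrikinError("fit_rht2 needs >= 5 points")
    V0, K0 = _reciprocal_init(S, y)
    if fix_max is not None:
        V0 = fix_max

    if loss == "log":
        pos = (S > 0) & (y > 0)
        S_f, y_f = S[pos], y[pos]

        def residuals(p: np.ndarray) -> np.ndarray:
            V = fix_max if fix_max is not None else p[0]
            K = p[-1]
            return np.log(_rht2(S_f, V, K)) - np.log(y_f)

    else:
        S_f, y_f = S, y

        def residuals(p: np.ndarray) -> np.ndarray:
            V = fix_max if fix_max is not None else p[0]
            K = p[-1]
            return _rht2(S_f, V, K) - y_f

    p0 = np.array([K0] if fix_max is not None else [V0, K0])
    sol = least_squares(
        residuals, p0, bounds=(1e-12, np.inf), max_nfev=10_000
    )
    if not sol.success:
        raise FitError(f"RHt2 fit did not converge: {sol.message}")
    V_hat = fix_max if fix_max is not None else float(sol.x[0])
    K_hat = float(sol.x[-1])
    pred = _rht2(S, V_hat, K_hat)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return FitResult(
        model="RHt2_fixed_max" if fix_max is not None else "RHt2_free",
        params={"Vmax": V_hat, "K": K_hat},
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        rmse=float(np.sqrt(ss_res / S.size)),
        n=int(S.size),
    )


def kt_sensitivity(
    config: OrganismConfig,
    env: Environment,
    factors: Sequence[float] = (0.5, 2.0),
) -> pd.DataFrame:
    """K_G under rescaled transporter half-saturation K_T.

    Returns one row per factor with K_G(f·K_T) and its ratio to the
    baseline.  The membrane component S0 scales exactly linearly in K_T
    while the diffusion component is invariant, so the ratio interpolates
    between those two limits.
    """
    from dataclasses import replace

    base = half_saturation_growth(config, env)
    rows = []
    for f in factors:
        tp = replace(config.transporter, K_T=config.transporter.K_T * f)
        res = half_saturation_growth(replace(config, transporter=tp), env)
        rows.append(
            {"factor": f, "K_G": res.K_G, "ratio": res.K_G / base.K_G}
        )
    return pd.DataFrame(rows)


def trd_feasibility_surface(
    carbon_models: Sequence[str | CarbonModel],
    esd_grid: Sequence[float] | np.ndarray,
    gmax_grid: Sequence[float] | np.ndarray,
    NC_max: float = 0.18,
    TRD_max: float = 0.4,
) -> pd.DataFrame:
    """TRD_Gmax over (carbon model, ESD, G_max) with feasibility flags.

    Exposes the frontier at which the transporter density required to
    sustain G_max reaches the membrane ceiling — the regime where large,
    fast-growing protists become transport-limited.
    """
    rows = []
    for cm in carbon_models:
        model = resolve_carbon_model(cm)
        name = cm if isinstance(cm, str) else model.kind
        for esd in np.asarray(esd_grid, dtype=float):
            morph = morphology(float(esd), model)
            for gmax in np.asarray(gmax_grid, dtype=float):
                val = trd_gmax(float(gmax), NC_max, morph.C_cell, morph.SA)
                rows.append(
                    {
                        "carbon_model": name,
                        "ESD": float(esd),
                        "G_max": float(gmax),
                        "TRD_Gmax": val,
                        "feasible": val <= TRD_max,
                    }
                )
    return pd.DataFrame(rows)
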