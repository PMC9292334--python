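"""Zero-dimensional mixed-layer plankton ecosystem with five trace metals.

The model is an NPZD-style box: one dissolved macronutrient, two
phytoplankton groups (nanophytoplankton, diatoms) with Droop-type variable
metal quotas, one microzooplankton pool with *fixed* metal:C stoichiometry,
and particulate organic carbon/metal.  Grazing follows a multi-prey
Michaelis-Menten response over nanophytoplankton, diatoms and particles.
Zooplankton assimilate metals with an efficiency that declines as the
stoichiometric food quality of the diet departs from 1; unassimilated
material is split between dissolved excretion (the recycling flux this
package exists to study) and particulate egestion.

Integration uses fixed-step RK4 (default dt = 0.25 d) with conservative
positivity clipping; per-element budget accumulators are carried in the
state so mass closure can be verified on any trajectory.

The module-level operator functions (:func:`temperature_factor`,
:func:`growth_rate`, :func:`metal_uptake`, :func:`grazing_fluxes`,
:func:`zoo_budget`) are the plain-Python reference of the compiled kernel in
``_kernel.py``; tests cross-check the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import xarray as xr

from . import _kernel as K
from .elements import (
    DEFAULT_ELEMENT_PARAMS,
    ELEMENTS,
    ElementParams,
    _ae_kernel,
)

__all__ = [
    "GROUPS",
    "EcosystemParams",
    "EcosystemState",
    "FluxDiagnostics",
    "Forcing",
    "ZooBudget",
    "IntegrationError",
    "temperature_factor",
    "growth_rate",
    "metal_uptake",
    "grazing_fluxes",
    "zoo_budget",
    "step",
    "run",
    "budget_check",
    "initial_state",
    "state_vector",
    "state_from_vector",
    "trajectory_state_vector",
]

GROUPS: tuple[str, str] = ("nano", "diatom")
T_REF = 20.0  # deg C reference of the Q10 factor

#: Deep-reservoir dissolved metal concentrations (mol m^-3); typical
#: sub-thermocline values (1e-6 mol m^-3 = 1 nM).
DEFAULT_D_DEEP: dict[str, float] = {
    "Fe": 0.6e-6,
    "Zn": 5.0e-6,
    "Cu": 2.0e-6,
    "Co": 0.05e-6,
    "Mn": 0.3e-6,
}

#: Constant external metal sources (aerosol/river analogue, mol m^-3 d^-1).
DEFAULT_S_M: dict[str, float] = {
    "Fe": 2e-10,
    "Zn": 5e-10,
    "Cu": 2e-10,
    "Co": 5e-12,
    "Mn": 2e-10,
}


class IntegrationError(RuntimeError):
    """Raised when a pool becomes NaN or significantly negative."""


@dataclass
class EcosystemParams:
    """Rate constants and stoichiometric settings of the box model.

    Units: rates d^-1, concentrations mol m^-3, quotas mol:mol.  ``m_z`` is
    the quadratic zooplankton closure coefficient ((mol C m^-3)^-1 d^-1).
    ``rcn`` is the fixed C:N ratio linking the carbon pools to the implicit
    macronutrient currency.  ``v_max`` maps element -> (nano, diatom)
    maximum uptake rates (mol metal per mol C per day); if omitted it is
    derived as ``3 * mu_max * q_max`` so replete cells can track their
    quota ceiling.
    """

    mu_max: tuple[float, float] = (1.0, 1.4)
    k_n: tuple[float, float] = (1e-4, 1e-3)
    q10: float = 1.88
    g_max: float = 2.5
    k_g: float = 2e-3
    preferences: tuple[float, float, float] = (1.0, 0.5, 0.25)
    ae_c: float = 0.6
    sigma_diss: float = 0.5
    m_z: float = 800.0
    m_p: float = 0.05
    lam_sink: float = 0.1
    lam_rem: float = 0.05
    kappa0: float = 0.02
    n_deep: float = 4e-3
    d_deep: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_D_DEEP))
    s_n: float = 0.0
    s_m: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_S_M))
    fe_q_min: float = 4e-6
    rcn: float = 122.0 / 16.0
    elements: dict[str, ElementParams] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_PARAMS)
    )
    v_max: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        rates = {
            "g_max": self.g_max,
            "m_z": self.m_z,
            "m_p": self.m_p,
            "lam_sink": self.lam_sink,
            "lam_rem": self.lam_rem,
            "kappa0": self.kappa0,
            "s_n": self.s_n,
        }
        for name, v in rates.items():
            if v < 0:
                raise ValueError(f"EcosystemParams.{name} must be >= 0")
        if not 0 < self.ae_c < 1:
            raise ValueError("ae_c must be in (0, 1)")
        if not 0 < self.sigma_diss < 1:
            raise ValueError("sigma_diss must be in (0, 1)")
        if len(self.preferences) != 3 or any(p < 0 for p in self.preferences):
            raise ValueError("preferences must be three non-negative weights")
        if not any(p > 0 for p in self.preferences):
            raise ValueError("at least one grazing preference must be positive")
        if set(self.elements) != set(ELEMENTS):
            raise ValueError(f"elements must cover exactly {ELEMENTS}")
        for e in ELEMENTS:
            fe = self.elements["Fe"]
            if self.fe_q_min >= min(fe.q_max_nano, fe.q_max_diatom):
                raise ValueError("fe_q_min must lie below the maximum Fe quota")
        if self.v_max is None:
            # Diatom Fe uptake capacity is reduced (lower surface:volume ->
            # weaker affinity): diatoms run Fe-stressed while the smaller
            # nanophytoplankton are controlled by grazing, which is what
            # keeps the two groups coexisting in a single well-mixed box.
            self.v_max = {
                e: (
                    3.0 * self.mu_max[0] * self.elements[e].q_max_nano,
                    (0.4 if e == "Fe" else 3.0)
                    * self.mu_max[1]
                    * self.elements[e].q_max_diatom,
                )
                for e in ELEMENTS
            }

    # --- kernel packing -----------------------------------------------------
    def pack(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to the (pv, ep) arrays consumed by the compiled kernel."""
        pv = np.zeros(22)
        pv[0], pv[1] = self.mu_max
        pv[2], pv[3] = self.k_n
        pv[4] = self.q10
        pv[5] = self.g_max
        pv[6] = self.k_g
        pv[7], pv[8], pv[9] = self.preferences
        pv[10] = self.ae_c
        pv[11] = self.sigma_diss
        pv[12] = self.m_z
        pv[13] = self.m_p
        pv[14] = self.lam_sink
        pv[15] = self.lam_rem
        pv[17] = self.n_deep
        pv[18] = self.s_n
        pv[19] = self.fe_q_min
        pv[20] = self.rcn
        pv[21] = T_REF
        ep = np.zeros((5, 10))
        assert self.v_max is not None
        for i, e in enumerate(ELEMENTS):
            p = self.elements[e]
            ep[i, 0] = p.q_max_nano
            ep[i, 1] = p.q_max_diatom
            ep[i, 2] = p.q_zoo
            ep[i, 3] = p.k_uptake
            ep[i, 4] = p.ae_max
            ep[i, 5] = p.ae_shape
            ep[i, 6], ep[i, 7] = self.v_max[e]
            ep[i, 8] = self.d_deep[e]
            ep[i, 9] = self.s_m[e]
        return pv, ep

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["elements"] = {k: asdict(v) for k, v in self.elements.items()}
        return d


@dataclass
class EcosystemState:
    """Pools of the box at one instant (all mol m^-3; ``t_model`` in days)."""

    n: float
    d: dict[str, float]
    p_c: dict[str, float]
    p_m: dict[tuple[str, str], float]
    z_c: float
    poc: float
    pom: dict[str, float]
    t_model: float = 0.0

    def validate(self, params: EcosystemParams, tol: float = 1e-9) -> None:
        pools = [self.n, self.z_c, self.poc]
        pools += [self.d[e] for e in ELEMENTS]
        pools += [self.p_c[g] for g in GROUPS]
        pools += [self.p_m[(g, e)] for g in GROUPS for e in ELEMENTS]
        pools += [self.pom[e] for e in ELEMENTS]
        if any(p < 0 for p in pools):
            raise ValueError("all pools must be >= 0")
        for gi, g in enumerate(GROUPS):
            pc = self.p_c[g]
            if pc <= 0:
                continue
            for e in ELEMENTS:
                q_max = (
                    params.elements[e].q_max_nano
                    if gi == 0
                    else params.elements[e].q_max_diatom
                )
                if self.p_m[(g, e)] / pc > q_max * (1 + tol):
                    raise ValueError(
                        f"phytoplankton quota {g}/{e} exceeds its maximum"
                    )


def state_vector(state: EcosystemState, acc: np.ndarray | None = None) -> np.ndarray:
    """Flatten an :class:`EcosystemState` into the kernel's 31-vector."""
    y = np.zeros(K.N_STATE)
    y[K.I_N] = state.n
    for i, e in enumerate(ELEMENTS):
        y[K.I_D + i] = state.d[e]
        y[K.I_POM + i] = state.pom[e]
    for gi, g in enumerate(GROUPS):
        y[K.I_PC + gi] = state.p_c[g]
        for i, e in enumerate(ELEMENTS):
            y[K.I_PM + 5 * gi + i] = state.p_m[(g, e)]
    y[K.I_Z] = state.z_c
    y[K.I_POC] = state.poc
    if acc is not None:
        y[K.I_ACC : K.I_ACC + 5] = acc[:5]
        y[K.I_ACCC] = acc[5]
    return y


def state_from_vector(y: np.ndarray, t_model: float = 0.0) -> EcosystemState:
    return EcosystemState(
        n=float(y[K.I_N]),
        d={e: float(y[K.I_D + i]) for i, e in enumerate(ELEMENTS)},
        p_c={g: float(y[K.I_PC + gi]) for gi, g in enumerate(GROUPS)},
        p_m={
            (g, e): float(y[K.I_PM + 5 * gi + i])
            for gi, g in enumerate(GROUPS)
            for i, e in enumerate(ELEMENTS)
        },
        z_c=float(y[K.I_Z]),
        poc=float(y[K.I_POC]),
        pom={e: float(y[K.I_POM + i]) for i, e in enumerate(ELEMENTS)},
        t_model=t_model,
    )


def initial_state(params: EcosystemParams) -> EcosystemState:
    """A plausible oligotrophic-ish starting point (pools well inside bounds)."""
    p_c = {"nano": 1e-3, "diatom": 5e-4}
    p_m = {}
    for gi, g in enumerate(GROUPS):
        for e in ELEMENTS:
            ep = params.elements[e]
            q_max = ep.q_max_nano if gi == 0 else ep.q_max_diatom
            p_m[(g, e)] = 0.5 * q_max * p_c[g]
    poc = 1e-3
    return EcosystemState(
        n=4e-3,
        d={e: 0.5 * params.d_deep[e] for e in ELEMENTS},
        p_c=p_c,
        p_m=p_m,
        z_c=5e-4,
        poc=poc,
        pom={e: 0.3 * params.elements[e].q_max_nano * poc for e in ELEMENTS},
    )


@dataclass
class Forcing:
    """Environmental forcing of the box: temperature and mixing.

    ``temperature(t) = base_temp + seasonal_amp * sin(2 pi t / 365) + warming(t)``
    and ``kappa(t) = kappa0 * mixing_factor(t)``.  ``warming`` and
    ``mixing_factor`` are optional callables of model time in days; constant
    forcing is the default.
    """

    base_temp: float = 18.0
    seasonal_amp: float = 2.0
    warming: Callable[[np.ndarray], np.ndarray] | None = None
    mixing_factor: Callable[[np.ndarray], np.ndarray] | None = None

    def temperature(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = self.base_temp + self.seasonal_amp * np.sin(2 * np.pi * t / 365.0)
        if self.warming is not None:
            out = out + self.warming(t)
        return out

    def kappa(self, t: np.ndarray | float, kappa0: float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        fac = np.ones_like(t) if self.mixing_factor is None else self.mixing_factor(t)
        return kappa0 * fac


@dataclass
class FluxDiagnostics:
    """Instantaneous fluxes and drivers diagnosed at one save time.

    ``recycle_c`` / ``recycle_m`` are the dissolved excretion fluxes of the
    microzooplankton (mol m^-3 d^-1); ``recycle_stoich`` their metal:C ratio;
    ``fq`` the per-element food quality of the instantaneous diet; ``prey_q``
    the preference-weighted prey metal content (mol m^-3); ``sst`` the
    forcing temperature; ``zoo_b`` the zooplankton biomass; ``npp`` gross
    primary production; ``export_*`` the sinking fluxes.
    """

    recycle_c: float
    recycle_m: dict[str, float]
    recycle_stoich: dict[str, float]
    fq: dict[str, float]
    prey_q: dict[str, float]
    sst: float
    zoo_b: float
    npp: float
    export_c: float
    export_m: dict[str, float]
    grazing_c: float

    @classmethod
    def from_vector(cls, diag: np.ndarray) -> "FluxDiagnostics":
        pick = lambda base: {e: float(diag[base + i]) for i, e in enumerate(ELEMENTS)}
        return cls(
            recycle_c=float(diag[K.D_RC]),
            recycle_m=pick(K.D_RM),
            recycle_stoich=pick(K.D_STO),
            fq=pick(K.D_FQ),
            prey_q=pick(K.D_PQ),
            sst=float(diag[K.D_SST]),
            zoo_b=float(diag[K.D_ZOO]),
            npp=float(diag[K.D_NPP]),
            export_c=float(diag[K.D_EXC]),
            export_m=pick(K.D_EXM),
            grazing_c=float(diag[K.D_GRZ]),
        )


# ---------------------------------------------------------------------------
# reference operators (plain Python mirrors of the kernel)
# ---------------------------------------------------------------------------

def temperature_factor(t: float, q10: float, t_ref: float = T_REF) -> float:
    """Q10 metabolic scaling, 1 at the reference temperature."""
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    return q10 ** ((t - t_ref) / 10.0)


def growth_rate(
    state: EcosystemState, params: EcosystemParams, t: float, group: str
) -> float:
    """Specific growth rate (d^-1): mu_max * Q10 * min(N limitation, Fe limitation).

    Only the Fe quota limits growth (Droop floor ``fe_q_min``); the other
    metals are tracked but non-limiting.
    """
    gi = GROUPS.index(group)
    pc = state.p_c[group]
    q_fe = state.p_m[(group, "Fe")] / pc if pc > 0 else 0.0
    fe = params.elements["Fe"]
    q_max = fe.q_max_nano if gi == 0 else fe.q_max_diatom
    fe_lim = min(max((q_fe - params.fe_q_min) / (q_max - params.fe_q_min), 0.0), 1.0)
    n_lim = state.n / (state.n + params.k_n[gi]) if state.n > 0 else 0.0
    tf = temperature_factor(t, params.q10)
    return params.mu_max[gi] * tf * min(n_lim, fe_lim)


def metal_uptake(
    state: EcosystemState, params: EcosystemParams, group: str, element: str
) -> float:
    """Specific metal uptake (mol metal per mol C per day), Droop-capped.

    ``v = v_max * d/(d + k) * (1 - q/q_max)``; quota dynamics then follow
    dq/dt = v - mu q, so slow-growing cells accumulate metal toward q_max.
    """
    gi = GROUPS.index(group)
    ep = params.elements[element]
    assert params.v_max is not None
    v_max = params.v_max[element][gi]
    q_max = ep.q_max_nano if gi == 0 else ep.q_max_diatom
    pc = state.p_c[group]
    q = state.p_m[(group, element)] / pc if pc > 0 else 0.0
    d = max(state.d[element], 0.0)
    v = v_max * d / (d + ep.k_uptake) * (1.0 - q / q_max)
    return max(v, 0.0)


def grazing_fluxes(
    state: EcosystemState, params: EcosystemParams, t: float
) -> dict[str, float]:
    """Carbon grazing flux per prey (mol C m^-3 d^-1), keys nano/diatom/poc."""
    tf = temperature_factor(t, params.q10)
    f = (max(state.p_c["nano"], 0.0), max(state.p_c["diatom"], 0.0), max(state.poc, 0.0))
    pr = params.preferences
    den = params.k_g + sum(p * x for p, x in zip(pr, f))
    if den <= 0 or state.z_c <= 0:
        return {"nano": 0.0, "diatom": 0.0, "poc": 0.0}
    base = params.g_max * tf * state.z_c / den
    return {
        "nano": base * pr[0] * f[0],
        "diatom": base * pr[1] * f[1],
        "poc": base * pr[2] * f[2],
    }


@dataclass
class ZooBudget:
    """Partition of one element's ingestion through the zooplankton.

    All terms mol m^-3 d^-1.  ``dissolved_draw`` is the direct uptake from
    the dissolved pool needed to hold the fixed zooplankton quota when
    assimilation from the diet falls short of demand (the simulator
    additionally caps it by dissolved availability within a step).
    """

    growth_c: float
    recycle_c: float
    egest_c: float
    ingested_m: float
    assimilated_m: float
    recycle_m: float
    egest_m: float
    dissolved_draw: float


def zoo_budget(
    grazing: Mapping[str, float] | Sequence[float],
    prey_quotas: Mapping[str, float] | Sequence[float],
    params: EcosystemParams,
    element_params: ElementParams,
    frozen_fq: float | None = None,
) -> ZooBudget:
    """Partition ingested carbon and one metal through the grazer.

    Carbon: a fraction ``ae_c`` fuels growth; the rest is excreted dissolved
    (``sigma_diss``) or egested.  Metal: gross assimilation is
    ``AE(FQ) * ingested``, capped at the fixed-stoichiometry demand
    ``ae_c * ingested_C * q_zoo``; the unassimilated remainder is split like
    carbon; any shortfall against demand is met from the dissolved pool
    (reported as ``dissolved_draw``), preserving the fixed zoo quota.
    """
    if isinstance(grazing, Mapping):
        g = [grazing[k] for k in ("nano", "diatom", "poc")]
        q = [prey_quotas[k] for k in ("nano", "diatom", "poc")]  # type: ignore[index]
    else:
        g = list(grazing)
        q = list(prey_quotas)  # type: ignore[arg-type]
    if any(x < 0 for x in g):
        raise ValueError("grazing fluxes must be >= 0")
    i_c = sum(g)
    if i_c == 0:
        return ZooBudget(0, 0, 0, 0, 0, 0, 0, 0)
    i_m = sum(gi * qi for gi, qi in zip(g, q))
    growth_c = params.ae_c * i_c
    recycle_c = params.sigma_diss * (1 - params.ae_c) * i_c
    egest_c = (1 - params.sigma_diss) * (1 - params.ae_c) * i_c
    demand = growth_c * element_params.q_zoo
    assim = 0.0
    if i_m > 0:
        fq = element_params.q_zoo / (i_m / i_c)
        if frozen_fq is not None and frozen_fq > 0 and np.isfinite(frozen_fq):
            fq = frozen_fq
        assim = min(_ae_kernel(fq, element_params.ae_max, element_params.ae_shape) * i_m, demand)
    u = i_m - assim
    rec = params.sigma_diss * u
    eg = (1 - params.sigma_diss) * u
    draw = max(demand - assim, 0.0)
    return ZooBudget(growth_c, recycle_c, egest_c, i_m, assim, rec, eg, draw)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

_POOL_NAMES = (
    ["n"]
    + [f"d[{e}]" for e in ELEMENTS]
    + [f"p_c[{g}]" for g in GROUPS]
    + [f"p_m[{g},{e}]" for g in GROUPS for e in ELEMENTS]
    + ["z_c", "poc"]
    + [f"pom[{e}]" for e in ELEMENTS]
)


def _forcing_grids(
    forcing: Forcing, params: EcosystemParams, t_start: float, dt: float, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    t = t_start + 0.5 * dt * np.arange(2 * n_steps + 1)
    tg = np.asarray(forcing.temperature(t), dtype=float)
    kg = np.asarray(forcing.kappa(t, params.kappa0), dtype=float)
    if tg.ndim == 0:
        tg = np.full(t.shape, float(tg))
    if kg.ndim == 0:
        kg = np.full(t.shape, float(kg))
    return tg, kg


def _frozen_vector(frozen_fq: Mapping[str, float] | None) -> tuple[np.ndarray, bool]:
    if frozen_fq is None:
        return np.full(5, np.nan), False
    return np.array([float(frozen_fq[e]) for e in ELEMENTS]), True


def step(
    state: EcosystemState,
    params: EcosystemParams,
    forcing: Forcing,
    dt: float,
    frozen_fq: Mapping[str, float] | None = None,
) -> tuple[EcosystemState, FluxDiagnostics]:
    """Advance one RK4 step; diagnostics are evaluated at the *start* state."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.validate(params)
    pv, ep = params.pack()
    y0 = state_vector(state)
    tg, kg = _forcing_grids(forcing, params, state.t_model, dt, 1)
    fz, use = _frozen_vector(frozen_fq)
    times, ys, ds, status, bad, bad_t = K.integrate(
        y0, pv, ep, tg, kg, dt, 1, 1, fz, use, state.t_model
    )
    if status != 0:
        raise IntegrationError(
            f"integration unstable in pool {_POOL_NAMES[bad]} at t={bad_t:.3f} d"
        )
    new = state_from_vector(ys[-1], t_model=state.t_model + dt)
    return new, FluxDiagnostics.from_vector(ds[0])


def run(
    params: EcosystemParams,
    forcing: Forcing,
    t_end: float,
    dt: float = 0.25,
    save_every_days: float = 5.0,
    state0: EcosystemState | np.ndarray | None = None,
    t_start: float = 0.0,
    frozen_fq: Mapping[str, float] | None = None,
) -> xr.Dataset:
    """Integrate the box model and return a trajectory Dataset.

    The trajectory has dimensions (time[, element, group]) and carries both
    pools and flux diagnostics; the per-element budget accumulators travel
    with the state so :func:`budget_check` works on any (sliced or
    concatenated) trajectory.  Deterministic given (params, forcing, dt).
    """
    if dt <= 0 or t_end <= t_start:
        raise ValueError("need dt > 0 and t_end > t_start")
    n_steps = int(round((t_end - t_start) / dt))
    save_every = max(int(round(save_every_days / dt)), 1)
    pv, ep = params.pack()
    if state0 is None:
        y0 = state_vector(initial_state(params))
    elif isinstance(state0, EcosystemState):
        state0.validate(params)
        y0 = state_vector(state0)
    else:
        y0 = np.asarray(state0, dtype=float).copy()
        if y0.shape != (K.N_STATE,):
            raise ValueError(f"state vector must have length {K.N_STATE}")
    tg, kg = _forcing_grids(forcing, params, t_start, dt, n_steps)
    fz, use = _frozen_vector(frozen_fq)
    times, ys, ds, status, bad, bad_t = K.integrate(
        y0, pv, ep, tg, kg, dt, n_steps, save_every, fz, use, t_start
    )
    if status != 0:
        raise IntegrationError(
            f"integration unstable in pool {_POOL_NAMES[bad]} at t={bad_t:.3f} d"
        )
    return _build_dataset(times, ys, ds, params, dt, bool(use), fz)


def _build_dataset(
    times: np.ndarray,
    ys: np.ndarray,
    ds: np.ndarray,
    params: EcosystemParams,
    dt: float,
    frozen: bool,
    fz: np.ndarray,
) -> xr.Dataset:
    el = list(ELEMENTS)
    gr = list(GROUPS)
    nt = len(times)
    pm = ys[:, K.I_PM : K.I_PM + 10].reshape(nt, 2, 5)

    def dvar(base: int) -> xr.DataArray:
        return xr.DataArray(
            ds[:, base : base + 5], dims=("time", "element"), coords={"element": el}
        )

    out = xr.Dataset(
        {
            "n": ("time", ys[:, K.I_N]),
            "dissolved": (("time", "element"), ys[:, K.I_D : K.I_D + 5]),
            "phyto_c": (("time", "group"), ys[:, K.I_PC : K.I_PC + 2]),
            "phyto_m": (("time", "group", "element"), pm),
            "zoo_c": ("time", ys[:, K.I_Z]),
            "poc": ("time", ys[:, K.I_POC]),
            "pom": (("time", "element"), ys[:, K.I_POM : K.I_POM + 5]),
            "budget_acc": (("time", "element"), ys[:, K.I_ACC : K.I_ACC + 5]),
            "budget_acc_c": ("time", ys[:, K.I_ACCC]),
            "recycle_c": ("time", ds[:, K.D_RC]),
            "recycle_m": dvar(K.D_RM),
            "recycle_stoich": dvar(K.D_STO),
            "fq": dvar(K.D_FQ),
            "prey_q": dvar(K.D_PQ),
            "sst": ("time", ds[:, K.D_SST]),
            "zoo_b": ("time", ds[:, K.D_ZOO]),
            "npp": ("time", ds[:, K.D_NPP]),
            "export_c": ("time", ds[:, K.D_EXC]),
            "export_m": dvar(K.D_EXM),
            "grazing_c": ("time", ds[:, K.D_GRZ]),
        },
        coords={"time": times, "element": el, "group": gr},
        attrs={
            "dt_days": dt,
            "integrator": "rk4-fixed",
            "frozen_fq": int(frozen),
            "frozen_fq_values": fz.tolist() if frozen else [],
            "params_json": json.dumps(params.to_jsonable()),
        },
    )
    return out


def trajectory_state_vector(traj: xr.Dataset, itime: int = -1) -> np.ndarray:
    """Reassemble the kernel state vector from a saved trajectory row.

    Used to branch a new run (e.g. a climate scenario) from a saved point;
    the budget accumulators travel along, so budget checks remain valid
    across concatenated segments.
    """
    y = np.zeros(K.N_STATE)
    y[K.I_N] = float(traj["n"][itime])
    y[K.I_D : K.I_D + 5] = traj["dissolved"][itime].values
    y[K.I_PC : K.I_PC + 2] = traj["phyto_c"][itime].values
    y[K.I_PM : K.I_PM + 10] = traj["phyto_m"][itime].values.reshape(10)
    y[K.I_Z] = float(traj["zoo_c"][itime])
    y[K.I_POC] = float(traj["poc"][itime])
    y[K.I_POM : K.I_POM + 5] = traj["pom"][itime].values
    y[K.I_ACC : K.I_ACC + 5] = traj["budget_acc"][itime].values
    y[K.I_ACCC] = float(traj["budget_acc_c"][itime])
    return y


def budget_check(traj: xr.Dataset, params: EcosystemParams) -> dict[str, float]:
    """Relative budget residual per element (and carbon) over a trajectory.

    For each element the inventory is dissolved + phytoplankton internal +
    zooplankton (z_c * q_zoo, the fixed-quota implicit pool) + particulate;
    the residual is ``max_t |delta inventory - delta accumulated
    (sources + mixing - export)| / max_t inventory``.
    """
    res: dict[str, float] = {}
    zc = traj["zoo_c"].values
    for i, e in enumerate(ELEMENTS):
        inv = (
            traj["dissolved"].values[:, i]
            + traj["phyto_m"].values[:, :, i].sum(axis=1)
            + zc * params.elements[e].q_zoo
            + traj["pom"].values[:, i]
        )
        acc = traj["budget_acc"].values[:, i]
        resid = np.abs((inv - inv[0]) - (acc - acc[0]))
        res[e] = float(resid.max() / np.abs(inv).max())
    inv_c = (
        params.rcn * traj["n"].values
        + traj["phyto_c"].values.sum(axis=1)
        + zc
        + traj["poc"].values
    )
    acc_c = traj["budget_acc_c"].values
    resid = np.abs((inv_c - inv_c[0]) - (acc_c - acc_c[0]))
    res["C"] = float(resid.max() / np.abs(inv_c).max())
    return res
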