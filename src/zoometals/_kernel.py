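"""JIT-compiled right-hand side and RK4 integrator of the mixed-layer box model.

State vector layout (length 31)::

    0        n        dissolved macronutrient (mol N m^-3)
    1..5     d[e]     dissolved metal, element order Fe Zn Cu Co Mn (mol m^-3)
    6..7     p_c[g]   phytoplankton carbon, groups nano / diatom (mol C m^-3)
    8..17    p_m[g,e] phytoplankton internal metal (mol m^-3), index 8 + 5*g + e
    18       z_c      microzooplankton carbon (mol C m^-3)
    19       poc      particulate organic carbon (mol C m^-3)
    20..24   pom[e]   particulate metal (mol m^-3)
    25..29   acc[e]   running integral of (source + mixing - export) per metal
    30       acc_c    same integral for carbon-equivalent inventory

The accumulators are integrated by the same RK4 stages as the pools, so a
budget check reduces to comparing inventory changes against them; internal
transfers cancel analytically and the residual measures only round-off plus
any genuinely unclosable corner (see `zoo budget` below).

Positivity is enforced by conservative clipping: within each stage every
pool's total outflow is rescaled so it cannot exceed pool/dt.  Because
outflows are rescaled at the source and routed afterwards, the rescaling
never breaks conservation.

Parameter vector ``pv`` layout (length 22)::

    0 mu_max_nano  1 mu_max_diatom  2 k_n_nano  3 k_n_diatom  4 q10
    5 g_max  6 k_g  7 pref_nano  8 pref_diatom  9 pref_poc
    10 ae_c  11 sigma_diss  12 m_z  13 m_p  14 lam_sink  15 lam_rem
    16 (reserved)  17 n_deep  18 s_n  19 fe_q_min  20 rcn  21 t_ref

Element parameter matrix ``ep`` (5 x 10)::

    0 q_max_nano  1 q_max_diatom  2 q_zoo  3 k_uptake  4 ae_max  5 ae_shape
    6 v_max_nano  7 v_max_diatom  8 d_deep  9 s_m
"""

from __future__ import annotations

import numpy as np
from numba import njit

NE = 5
NG = 2

# state indices
I_N = 0
I_D = 1
I_PC = 6
I_PM = 8
I_Z = 18
I_POC = 19
I_POM = 20
I_ACC = 25
I_ACCC = 30
N_STATE = 31
N_POOLS = 25

# diagnostics indices
D_RC = 0
D_RM = 1
D_STO = 6
D_FQ = 11
D_PQ = 16
D_SST = 21
D_ZOO = 22
D_NPP = 23
D_EXC = 24
D_EXM = 25
D_GRZ = 30
N_DIAG = 31


@njit(cache=True)
def _scale(pool: float, out: float, dt: float) -> float:
    """Factor rescaling a pool's total outflow so outflow*dt <= pool."""
    if out <= 0.0:
        return 1.0
    avail = pool / dt if pool > 0.0 else 0.0
    if out > avail:
        return avail / out
    return 1.0


@njit(cache=True)
def rhs(y, dy, diag, pv, ep, temp, kap, dt, fq_frozen, use_frozen):
    for i in range(N_STATE):
        dy[i] = 0.0
    for i in range(N_DIAG):
        diag[i] = 0.0

    q10 = pv[4]
    ae_c = pv[10]
    sigma = pv[11]
    lam_sink = pv[14]
    lam_rem = pv[15]
    rcn = pv[20]
    tf = q10 ** ((temp - pv[21]) / 10.0)

    n = y[I_N]
    n_pos = n if n > 0.0 else 0.0
    z = y[I_Z]
    z_pos = z if z > 0.0 else 0.0
    poc = y[I_POC]
    poc_pos = poc if poc > 0.0 else 0.0

    # --- phytoplankton: growth, uptake, linear mortality -------------------
    quota = np.zeros((NG, NE))
    upt = np.zeros((NG, NE))
    mort_m = np.zeros((NG, NE))
    growth_c = np.zeros(NG)
    mort_c = np.zeros(NG)
    for g in range(NG):
        pc = y[I_PC + g]
        pc_pos = pc if pc > 0.0 else 0.0
        if pc > 1e-300:
            for e in range(NE):
                q = y[I_PM + 5 * g + e] / pc
                quota[g, e] = q if q > 0.0 else 0.0
        # only Fe limits growth (Droop floor between fe_q_min and q_max)
        fe_lim = (quota[g, 0] - pv[19]) / (ep[0, g] - pv[19])
        if fe_lim < 0.0:
            fe_lim = 0.0
        elif fe_lim > 1.0:
            fe_lim = 1.0
        nlim = n_pos / (n_pos + pv[2 + g])
        lim = nlim if nlim < fe_lim else fe_lim
        growth_c[g] = pv[g] * tf * lim * pc_pos
        mort_c[g] = pv[13] * pc_pos
        for e in range(NE):
            d_e = y[I_D + e]
            d_pos = d_e if d_e > 0.0 else 0.0
            v = ep[e, 6 + g] * d_pos / (d_pos + ep[e, 3]) * (1.0 - quota[g, e] / ep[e, g])
            if v < 0.0:
                v = 0.0
            upt[g, e] = v * pc_pos
            pm = y[I_PM + 5 * g + e]
            mort_m[g, e] = pv[13] * (pm if pm > 0.0 else 0.0)

    # limit total macronutrient drawdown
    s = _scale(n, (growth_c[0] + growth_c[1]) / rcn, dt)
    growth_c[0] *= s
    growth_c[1] *= s

    # --- grazing (Michaelis-Menten multi-prey) ------------------------------
    f0 = y[I_PC] if y[I_PC] > 0.0 else 0.0
    f1 = y[I_PC + 1] if y[I_PC + 1] > 0.0 else 0.0
    den = pv[6] + pv[7] * f0 + pv[8] * f1 + pv[9] * poc_pos
    g_c = np.zeros(3)
    if den > 0.0 and z_pos > 0.0:
        gbase = pv[5] * tf * z_pos / den
        g_c[0] = gbase * pv[7] * f0
        g_c[1] = gbase * pv[8] * f1
        g_c[2] = gbase * pv[9] * poc_pos

    # per-pool carbon limiters
    for g in range(NG):
        s = _scale(y[I_PC + g], mort_c[g] + g_c[g], dt)
        mort_c[g] *= s
        g_c[g] *= s
    sink_poc = lam_sink * poc_pos
    rem_poc = lam_rem * poc_pos
    s = _scale(poc, g_c[2] + sink_poc + rem_poc, dt)
    g_c[2] *= s
    sink_poc *= s
    rem_poc *= s

    # metal grazing tied to (already limited) carbon grazing via quotas
    gm = np.zeros((3, NE))
    sink_pom = np.zeros(NE)
    rem_pom = np.zeros(NE)
    for e in range(NE):
        gm[0, e] = g_c[0] * quota[0, e]
        gm[1, e] = g_c[1] * quota[1, e]
        pom = y[I_POM + e]
        pom_pos = pom if pom > 0.0 else 0.0
        q_pom = pom_pos / poc if poc > 1e-300 else 0.0
        gm[2, e] = g_c[2] * q_pom
        sink_pom[e] = lam_sink * pom_pos
        rem_pom[e] = lam_rem * pom_pos
        for g in range(NG):
            s = _scale(y[I_PM + 5 * g + e], mort_m[g, e] + gm[g, e], dt)
            mort_m[g, e] *= s
            gm[g, e] *= s
        s = _scale(pom, gm[2, e] + sink_pom[e] + rem_pom[e], dt)
        gm[2, e] *= s
        sink_pom[e] *= s
        rem_pom[e] *= s

    # dissolved-pool limiter for uptake; remaining capacity feeds zoo draw
    upt_tot = np.zeros(NE)
    d_left = np.zeros(NE)
    for e in range(NE):
        tot = upt[0, e] + upt[1, e]
        s = _scale(y[I_D + e], tot, dt)
        upt[0, e] *= s
        upt[1, e] *= s
        upt_tot[e] = tot * s
        d_e = y[I_D + e]
        avail = d_e / dt if d_e > 0.0 else 0.0
        d_left[e] = avail - upt_tot[e]
        if d_left[e] < 0.0:
            d_left[e] = 0.0

    # zooplankton quadratic mortality
    mz = pv[12] * z_pos * z_pos
    mz *= _scale(z, mz, dt)

    # --- zooplankton ingestion budget ---------------------------------------
    i_c = g_c[0] + g_c[1] + g_c[2]
    zoo_growth = ae_c * i_c
    recycle_c = sigma * (1.0 - ae_c) * i_c
    egest_c = (1.0 - sigma) * (1.0 - ae_c) * i_c
    rec_m = np.zeros(NE)
    eg_m = np.zeros(NE)
    draw = np.zeros(NE)
    for e in range(NE):
        fq_live = np.nan
        if i_c > 0.0:
            i_m = gm[0, e] + gm[1, e] + gm[2, e]
            diet_q = i_m / i_c
            if diet_q > 0.0:
                fq_live = ep[e, 2] / diet_q
            demand = ae_c * i_c * ep[e, 2]
            assim = 0.0
            if i_m > 0.0:
                fq_use = fq_live
                if use_frozen and fq_frozen[e] > 0.0 and fq_frozen[e] == fq_frozen[e]:
                    fq_use = fq_frozen[e]
                r = fq_use if fq_use < 1.0 / fq_use else 1.0 / fq_use
                ae = ep[e, 4] * r ** ep[e, 5]
                assim = ae * i_m
                if assim > demand:
                    assim = demand
            u = i_m - assim
            rec = sigma * u
            eg = (1.0 - sigma) * u
            short = demand - assim
            if short > 0.0:
                # fixed zoo stoichiometry: shortfall met first by direct
                # uptake from the dissolved pool, then (only if the pool is
                # exhausted within the step) by clawing back excretion and
                # egestion.  Keeps the budget closed and AE's effect on
                # recycling monotone.
                dd = short if short < d_left[e] else d_left[e]
                draw[e] = dd
                d_left[e] -= dd
                short -= dd
                if short > 0.0:
                    t1 = short if short < rec else rec
                    rec -= t1
                    short -= t1
                if short > 0.0:
                    t2 = short if short < eg else eg
                    eg -= t2
                    short -= t2
                # any residual shortfall is an unclosable corner (no metal
                # left anywhere); it surfaces in the budget residual.
            rec_m[e] = rec
            eg_m[e] = eg
        diag[D_FQ + e] = fq_live

    # --- assemble tendencies ------------------------------------------------
    mortz_diss_c = sigma * mz
    mortz_part_c = (1.0 - sigma) * mz
    dy[I_N] = (
        -(growth_c[0] + growth_c[1]) / rcn
        + (recycle_c + rem_poc + mortz_diss_c) / rcn
        + kap * (pv[17] - n)
        + pv[18]
    )
    for g in range(NG):
        dy[I_PC + g] = growth_c[g] - mort_c[g] - g_c[g]
        for e in range(NE):
            dy[I_PM + 5 * g + e] = upt[g, e] - mort_m[g, e] - gm[g, e]
    dy[I_Z] = zoo_growth - mz
    dy[I_POC] = (
        mort_c[0] + mort_c[1] + egest_c + mortz_part_c - g_c[2] - sink_poc - rem_poc
    )
    for e in range(NE):
        d_e = y[I_D + e]
        mix = kap * (ep[e, 8] - d_e)
        dy[I_D + e] = (
            -upt_tot[e]
            - draw[e]
            + rec_m[e]
            + rem_pom[e]
            + mortz_diss_c * ep[e, 2]
            + mix
            + ep[e, 9]
        )
        dy[I_POM + e] = (
            mort_m[0, e]
            + mort_m[1, e]
            + eg_m[e]
            + mortz_part_c * ep[e, 2]
            - gm[2, e]
            - sink_pom[e]
            - rem_pom[e]
        )
        dy[I_ACC + e] = ep[e, 9] + mix - sink_pom[e]
    dy[I_ACCC] = rcn * (pv[18] + kap * (pv[17] - n)) - sink_poc

    # --- diagnostics ---------------------------------------------------------
    diag[D_RC] = recycle_c
    for e in range(NE):
        diag[D_RM + e] = rec_m[e]
        diag[D_STO + e] = rec_m[e] / recycle_c if recycle_c > 0.0 else np.nan
        diag[D_PQ + e] = (
            pv[7] * y[I_PM + e]
            + pv[8] * y[I_PM + 5 + e]
            + pv[9] * y[I_POM + e]
        )
        diag[D_EXM + e] = sink_pom[e]
    diag[D_SST] = temp
    diag[D_ZOO] = z_pos
    diag[D_NPP] = growth_c[0] + growth_c[1]
    diag[D_EXC] = sink_poc
    diag[D_GRZ] = i_c


@njit(cache=True)
def integrate(y0, pv, ep, tgrid, kgrid, dt, n_steps, save_every, fq_frozen, use_frozen, t0):
    """Fixed-step RK4 with forcing sampled on a half-step grid.

    Returns (times, states, diagnostics, status, bad_pool, bad_time);
    status 1 flags a NaN or significantly negative pool.
    """
    n_save = n_steps // save_every + 1
    times = np.empty(n_save)
    states = np.empty((n_save, N_STATE))
    diags = np.empty((n_save, N_DIAG))
    y = y0.copy()
    k1 = np.empty(N_STATE)
    k2 = np.empty(N_STATE)
    k3 = np.empty(N_STATE)
    k4 = np.empty(N_STATE)
    yt = np.empty(N_STATE)
    diag = np.empty(N_DIAG)
    scratch = np.empty(N_DIAG)

    rhs(y, k1, diag, pv, ep, tgrid[0], kgrid[0], dt, fq_frozen, use_frozen)
    times[0] = t0
    states[0] = y
    diags[0] = diag
    isave = 1
    status = 0
    bad = -1
    bad_t = 0.0

    for i in range(n_steps):
        rhs(y, k1, scratch, pv, ep, tgrid[2 * i], kgrid[2 * i], dt, fq_frozen, use_frozen)
        for j in range(N_STATE):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        rhs(yt, k2, scratch, pv, ep, tgrid[2 * i + 1], kgrid[2 * i + 1], dt, fq_frozen, use_frozen)
        for j in range(N_STATE):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        rhs(yt, k3, scratch, pv, ep, tgrid[2 * i + 1], kgrid[2 * i + 1], dt, fq_frozen, use_frozen)
        for j in range(N_STATE):
            yt[j] = y[j] + dt * k3[j]
        rhs(yt, k4, scratch, pv, ep, tgrid[2 * i + 2], kgrid[2 * i + 2], dt, fq_frozen, use_frozen)
        for j in range(N_STATE):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

        for j in range(N_POOLS):
            v = y[j]
            if not (v == v) or v < -1e-9:
                status = 1
                bad = j
                bad_t = t0 + (i + 1) * dt
                break
        if status != 0:
            break

        if (i + 1) % save_every == 0:
            rhs(y, k1, diag, pv, ep, tgrid[2 * i + 2], kgrid[2 * i + 2], dt, fq_frozen, use_frozen)
            times[isave] = t0 + (i + 1) * dt
            states[isave] = y
            diags[isave] = diag
            isave += 1

    return times[:isave], states[:isave], diags[:isave], status, bad, bad_t
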