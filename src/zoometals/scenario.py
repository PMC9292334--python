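"""Climate-forcing scenarios: control/climate pairs and the fixed-food-quality run.

A scenario is a 300-model-year experiment on the calendar 1801-2100 (model
year ``y`` maps to calendar year ``1800 + y``).  The control run keeps
constant (seasonally cycling) forcing throughout; the climate run branches
from the control state in 1851 and ramps temperature up by ``delta_t`` and
mixing down by the fraction ``delta_kappa`` until 2100 — a two-knob summary
of the warming / stratification / reduced-nutrient-supply response of
high-emission earth-system projections.

Analysis windows:

* ``PI_REF``  — 1801-1900, the preindustrial reference used for
  normalising trends and for freezing food quality;
* ``PRESENT`` — 1991-2000;
* ``FUTURE``  — 2091-2100.

The fixed-food-quality counterfactual repeats the climate run with the
per-element food quality *as seen by the assimilation-efficiency function*
frozen at its PI_REF climatology from the control run; every other coupling
(biomass, prey quantity, temperature) evolves freely.  Comparing it with
the climate run isolates the contribution of food-quality change to the
recycling stoichiometry response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .elements import ELEMENTS
from .ecosystem import (
    EcosystemParams,
    Forcing,
    run,
    trajectory_state_vector,
)

__all__ = [
    "YEAR_DAYS",
    "CALENDAR_OFFSET",
    "WINDOWS",
    "ScenarioSpec",
    "ScenarioResult",
    "WindowAverage",
    "build_forcing",
    "run_pair",
    "window_mean",
    "fixed_fq_counterfactual",
    "normalized_trend",
    "annual_mean",
    "extract_driver_panel",
]

YEAR_DAYS = 365.0
CALENDAR_OFFSET = 1800  # model year y <-> calendar year 1800 + y

#: Analysis windows as (first calendar year, last calendar year), inclusive.
WINDOWS: dict[str, tuple[int, int]] = {
    "PI_REF": (1801, 1900),
    "PRESENT": (1991, 2000),
    "FUTURE": (2091, 2100),
}


def window_time_range(window: str) -> tuple[float, float]:
    """Model-time interval [t0, t1) in days covered by a named window."""
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {list(WINDOWS)}")
    y0, y1 = WINDOWS[window]
    t0 = (y0 - CALENDAR_OFFSET - 1) * YEAR_DAYS
    t1 = (y1 - CALENDAR_OFFSET) * YEAR_DAYS
    return t0, t1


@dataclass
class ScenarioSpec:
    """Design of a control/climate experiment.

    ``delta_t`` (deg C) and ``delta_kappa`` (fractional mixing reduction,
    in [0, 1)) are the values reached at the end of the run; the ramp rises
    from ``ramp_start_year`` (model years; default 50 = calendar 1851) to
    the end, linearly or quadratically.  ``spinup_years`` are integrated
    and discarded before calendar year 1801 so the control starts on its
    seasonal attractor.
    """

    years_total: int = 300
    delta_t: float = 4.0
    delta_kappa: float = 0.4
    ramp_start_year: int = 50
    ramp_shape: str = "linear"
    base_temp: float = 18.0
    seasonal_amp: float = 2.0
    mixing_seasonal_amp: float = 0.0
    spinup_years: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.delta_kappa < 1:
            raise ValueError("delta_kappa must be in [0, 1)")
        if not 0 <= self.ramp_start_year < self.years_total:
            raise ValueError("ramp_start_year must lie inside the run")
        if self.ramp_shape not in ("linear", "quadratic"):
            raise ValueError("ramp_shape must be 'linear' or 'quadratic'")
        if not 0 <= self.mixing_seasonal_amp < 1:
            raise ValueError("mixing_seasonal_amp must be in [0, 1)")

    @property
    def t_end(self) -> float:
        return self.years_total * YEAR_DAYS

    @property
    def t_ramp(self) -> float:
        return self.ramp_start_year * YEAR_DAYS

    def ramp_fraction(self, t: np.ndarray | float) -> np.ndarray:
        """0 before the ramp start, 1 at the end of the run."""
        t = np.asarray(t, dtype=float)
        span = self.t_end - self.t_ramp
        frac = np.clip((t - self.t_ramp) / span, 0.0, 1.0)
        if self.ramp_shape == "quadratic":
            frac = frac**2
        return frac


def build_forcing(spec: ScenarioSpec) -> tuple[Forcing, Forcing]:
    """(control, climate) forcings for a scenario.

    The control is the seasonal cycle alone; the climate variant adds the
    warming ramp and scales mixing down by the stratification ramp.  A null
    scenario (delta_t = delta_kappa = 0) yields identical forcing.  A
    non-zero ``mixing_seasonal_amp`` adds a deep-mixing season in quadrature
    with the temperature season (mixing peaks a quarter-year before the
    temperature maximum, the way winter convection precedes summer warmth).
    """
    m_amp = spec.mixing_seasonal_amp

    def season_mix(t: np.ndarray) -> np.ndarray:
        return 1.0 - m_amp * np.cos(2 * np.pi * np.asarray(t, dtype=float) / YEAR_DAYS)

    control = Forcing(
        base_temp=spec.base_temp,
        seasonal_amp=spec.seasonal_amp,
        mixing_factor=season_mix if m_amp else None,
    )
    climate = Forcing(
        base_temp=spec.base_temp,
        seasonal_amp=spec.seasonal_amp,
        warming=lambda t: spec.delta_t * spec.ramp_fraction(t),
        mixing_factor=lambda t: season_mix(t)
        * (1.0 - spec.delta_kappa * spec.ramp_fraction(t)),
    )
    return control, climate


@dataclass
class ScenarioResult:
    """Trajectories of one scenario experiment."""

    spec: ScenarioSpec
    control: xr.Dataset
    climate: xr.Dataset
    counterfactual: xr.Dataset | None = None
    frozen_fq: dict[str, float] = field(default_factory=dict)


def _concat(seg1: xr.Dataset, rest: xr.Dataset) -> xr.Dataset:
    out = xr.concat([seg1, rest.isel(time=slice(1, None))], dim="time")
    out.attrs.update(rest.attrs)
    return out


def run_pair(
    params: EcosystemParams,
    spec: ScenarioSpec,
    dt: float = 0.25,
    save_every_days: float = 5.0,
) -> ScenarioResult:
    """Run the control and the climate trajectory of a scenario.

    The climate run branches from the control state at ``ramp_start_year``;
    both share the pre-branch segment sample for sample, so they are
    bit-identical before the ramp starts.
    """
    control_f, climate_f = build_forcing(spec)
    # spin-up on control forcing, discarded
    y0 = None
    if spec.spinup_years > 0:
        spin = run(
            params,
            control_f,
            t_end=spec.spinup_years * YEAR_DAYS,
            dt=dt,
            save_every_days=save_every_days,
        )
        y0 = trajectory_state_vector(spin, -1)
        y0[-6:] = 0.0  # restart budget accumulators at calendar zero
    seg1 = run(
        params,
        control_f,
        t_end=spec.t_ramp,
        dt=dt,
        save_every_days=save_every_days,
        state0=y0,
    )
    y_branch = trajectory_state_vector(seg1, -1)
    control_rest = run(
        params,
        control_f,
        t_end=spec.t_end,
        t_start=spec.t_ramp,
        dt=dt,
        save_every_days=save_every_days,
        state0=y_branch,
    )
    climate_rest = run(
        params,
        climate_f,
        t_end=spec.t_end,
        t_start=spec.t_ramp,
        dt=dt,
        save_every_days=save_every_days,
        state0=y_branch.copy(),
    )
    return ScenarioResult(
        spec=spec,
        control=_concat(seg1, control_rest),
        climate=_concat(seg1, climate_rest),
    )


@dataclass
class WindowAverage:
    """Time-means of every trajectory variable over a named window."""

    label: str
    years: tuple[int, int]
    means: xr.Dataset

    def value(self, var: str, element: str | None = None) -> float:
        da = self.means[var]
        if element is not None:
            da = da.sel(element=element)
        return float(da)


def window_mean(traj: xr.Dataset, window: str) -> WindowAverage:
    """Arithmetic time-mean of each variable over a named window.

    NaN samples (e.g. an undefined stoichiometry at a grazing-free instant)
    are skipped.  Raises if the trajectory does not cover the window.
    """
    t0, t1 = window_time_range(window)
    times = traj.time.values
    tmin, tmax = float(times.min()), float(times.max())
    spacing = float(np.median(np.diff(times))) if times.size > 1 else 0.0
    if tmin > t0 or tmax < t1 - spacing - 1e-9:
        raise ValueError(
            f"trajectory [{tmin:.0f}, {tmax:.0f}] d does not cover window "
            f"{window} [{t0:.0f}, {t1:.0f}) d"
        )
    sub = traj.sel(time=slice(t0, t1 - 1e-9))
    return WindowAverage(window, WINDOWS[window], sub.mean(dim="time", skipna=True))


def fixed_fq_counterfactual(
    params: EcosystemParams,
    spec: ScenarioSpec,
    pair: ScenarioResult,
    dt: float = 0.25,
    save_every_days: float = 5.0,
) -> xr.Dataset:
    """Re-run the climate scenario with food quality frozen at PI levels.

    The per-element food quality entering the assimilation-efficiency
    function is fixed to its PI_REF (1801-1900) time-mean from the control
    run; everything else is identical to the climate run, including the
    branch state at ``ramp_start_year``.  The result is stored on ``pair``
    and returned.
    """
    if pair.control is None:
        raise ValueError("control trajectory required to define the PI climatology")
    pi = window_mean(pair.control, "PI_REF")
    frozen = {e: pi.value("fq", e) for e in ELEMENTS}
    if any(not np.isfinite(v) or v <= 0 for v in frozen.values()):
        raise ValueError(f"PI_REF food-quality climatology invalid: {frozen}")
    _, climate_f = build_forcing(spec)
    it = int(np.argmin(np.abs(pair.control.time.values - spec.t_ramp)))
    if abs(float(pair.control.time[it]) - spec.t_ramp) > 1e-6:
        raise ValueError("control trajectory has no save point at the branch time")
    y_branch = trajectory_state_vector(pair.control, it)
    rest = run(
        params,
        climate_f,
        t_end=spec.t_end,
        t_start=spec.t_ramp,
        dt=dt,
        save_every_days=save_every_days,
        state0=y_branch,
        frozen_fq=frozen,
    )
    seg1 = pair.control.sel(time=slice(None, spec.t_ramp))
    cf = _concat(seg1, rest)
    pair.counterfactual = cf
    pair.frozen_fq = frozen
    return cf


def normalized_trend(
    series: xr.DataArray | np.ndarray, reference_mean: float
) -> xr.DataArray | np.ndarray:
    """Series divided by a (positive) reference mean; 1 means 'at reference'."""
    if not np.isfinite(reference_mean) or reference_mean <= 0:
        raise ValueError("reference mean must be positive and finite")
    return series / reference_mean


def annual_mean(da: xr.DataArray) -> xr.DataArray:
    """Calendar-year means of a time series (years of 365 days).

    Returns a DataArray indexed by integer calendar ``year``.
    """
    year = (
        CALENDAR_OFFSET + 1 + np.floor(da.time.values / YEAR_DAYS)
    ).astype(int)
    out = da.assign_coords(year=("time", year)).groupby("year").mean(skipna=True)
    return out


def extract_driver_panel(
    traj: xr.Dataset,
    region: str,
    windows: Sequence[str] = ("PRESENT", "FUTURE"),
    elements: Sequence[str] = ELEMENTS,
    response_kinds: Sequence[str] = ("flux", "stoichiometry"),
) -> pd.DataFrame:
    """Monthly driver/response panel rows from one trajectory.

    For each window, samples are aggregated into months of 365/12 days and
    one row is emitted per (month, element, response_kind) with the response
    (metal recycling flux or recycling stoichiometry) and the four drivers:
    food quality, prey quantity, sea-surface temperature and zooplankton
    biomass.  ``region`` labels the rows (ensemble members play the role of
    regions).
    """
    month_days = YEAR_DAYS / 12.0
    frames: list[pd.DataFrame] = []
    for window in windows:
        t0, t1 = window_time_range(window)
        sub = traj.sel(time=slice(t0, t1 - 1e-9))
        if sub.sizes.get("time", 0) == 0:
            raise ValueError(f"trajectory does not cover window {window}")
        month = np.floor((sub.time.values - t0) / month_days).astype(int)
        for e in elements:
            df = pd.DataFrame(
                {
                    "month": month,
                    "flux": sub["recycle_m"].sel(element=e).values,
                    "stoichiometry": sub["recycle_stoich"].sel(element=e).values,
                    "fq": sub["fq"].sel(element=e).values,
                    "prey_q": sub["prey_q"].sel(element=e).values,
                    "sst": sub["sst"].values,
                    "zoo_b": sub["zoo_b"].values,
                }
            )
            m = df.groupby("month").mean()
            for kind in response_kinds:
                frames.append(
                    pd.DataFrame(
                        {
                            "response": m[kind].values,
                            "fq": m["fq"].values,
                            "prey_q": m["prey_q"].values,
                            "sst": m["sst"].values,
                            "zoo_b": m["zoo_b"].values,
                            "region": region,
                            "time": m.index.values,
                            "element": e,
                            "response_kind": kind,
                            "period": window,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)
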