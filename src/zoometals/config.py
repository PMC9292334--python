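"""Run configuration, schema validation, manifests and tabular output.

Configuration is TOML with five optional sections — ``[run]``,
``[integrator]``, ``[ecosystem]``, ``[elements.<El>]``, ``[scenario]``,
``[attribution]`` — validated strictly: unknown keys are rejected with the
offending key named, and value errors name the key and constraint.  An
empty file yields the full default configuration (including the packaged
default element table).

Outputs are deterministic, diff-able CSV (floats at 12 significant digits)
plus a JSON run manifest recording the config echo, seeds, package version,
timestamps and a checksum for every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import metadata, resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import xarray as xr

from .ecosystem import EcosystemParams
from .elements import ELEMENTS, ElementParams
from .scenario import ScenarioSpec

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_config",
    "save_config",
    "packaged_element_params",
    "trajectory_to_frame",
    "write_csv",
]

FLOAT_FMT = "%.12g"

_RUN_KEYS = {"seed": int, "outdir": str}
_INTEGRATOR_KEYS = {"dt": float, "save_every_days": float}
_ATTR_KEYS = {"threshold": float, "group_by": list}
_ELEMENT_KEYS = {f.name: float for f in dataclasses.fields(ElementParams)}
_SCENARIO_KEYS = {
    "years_total": int,
    "delta_t": float,
    "delta_kappa": float,
    "ramp_start_year": int,
    "ramp_shape": str,
    "base_temp": float,
    "seasonal_amp": float,
    "mixing_seasonal_amp": float,
    "spinup_years": int,
    "seed": int,
}
# scalar/tuple/dict ecosystem keys handled explicitly
_ECO_SCALARS = {
    "q10", "g_max", "k_g", "ae_c", "sigma_diss", "m_z", "m_p",
    "lam_sink", "lam_rem", "kappa0", "n_deep", "s_n", "fe_q_min", "rcn",
}
_ECO_PAIRS = {"mu_max", "k_n"}
_ECO_TRIPLES = {"preferences"}
_ECO_ELEMENT_MAPS = {"d_deep", "s_m"}


def packaged_element_params() -> dict[str, ElementParams]:
    """Element defaults from the packaged ``data/elements.toml``."""
    text = resources.files("zoometals.data").joinpath("elements.toml").read_text()
    raw = tomllib.loads(text)
    return {e: ElementParams(**raw[e]) for e in ELEMENTS}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "zoometals_runs"
    dt: float = 0.25
    save_every_days: float = 5.0
    params: EcosystemParams = field(default_factory=EcosystemParams)
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    threshold: float = 0.5
    group_by: list[str] = field(
        default_factory=lambda: ["region", "element", "response_kind", "period"]
    )
    filled_defaults: list[str] = field(default_factory=list, compare=False)

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "dt": self.dt,
            "save_every_days": self.save_every_days,
            "ecosystem": self.params.to_jsonable(),
            "scenario": dataclasses.asdict(self.scenario),
            "threshold": self.threshold,
            "group_by": list(self.group_by),
        }


def _reject_unknown(section: str, raw: Mapping[str, Any], allowed) -> None:
    for k in raw:
        if k not in allowed:
            raise ValueError(f"unknown configuration key [{section}] {k!r}")


def _coerce(section: str, key: str, value: Any, typ: type) -> Any:
    if typ is float and isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if typ is int and isinstance(value, int) and not isinstance(value, bool):
        return value
    if typ in (str, list) and isinstance(value, typ):
        return value
    raise ValueError(
        f"configuration key [{section}] {key!r} must be of type {typ.__name__}"
    )


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a TOML configuration, filling defaults.

    An empty file returns the full-default config (packaged element quotas
    included).  Unknown keys and constraint violations raise ``ValueError``
    naming the key.
    """
    raw = tomllib.loads(Path(path).read_text())
    _reject_unknown(
        "", raw, {"run", "integrator", "ecosystem", "elements", "scenario", "attribution"}
    )
    filled: list[str] = []

    def section(name: str) -> dict:
        if name not in raw:
            filled.append(name)
            return {}
        return dict(raw[name])

    run_raw = section("run")
    _reject_unknown("run", run_raw, _RUN_KEYS)
    run_kw = {k: _coerce("run", k, v, _RUN_KEYS[k]) for k, v in run_raw.items()}

    integ_raw = section("integrator")
    _reject_unknown("integrator", integ_raw, _INTEGRATOR_KEYS)
    integ_kw = {k: _coerce("integrator", k, v, _INTEGRATOR_KEYS[k]) for k, v in integ_raw.items()}
    if integ_kw.get("dt", 0.25) <= 0:
        raise ValueError("configuration key [integrator] 'dt' must be > 0")

    elements = packaged_element_params()
    el_raw = raw.get("elements", {})
    if el_raw:
        _reject_unknown("elements", el_raw, set(ELEMENTS))
        for e, table in el_raw.items():
            _reject_unknown(f"elements.{e}", table, _ELEMENT_KEYS)
            merged = {**dataclasses.asdict(elements[e]), **table}
            try:
                elements[e] = ElementParams(**merged)
            except ValueError as err:
                raise ValueError(f"configuration key [elements.{e}]: {err}") from err
    else:
        filled.append("elements")

    eco_raw = section("ecosystem")
    allowed = _ECO_SCALARS | _ECO_PAIRS | _ECO_TRIPLES | _ECO_ELEMENT_MAPS
    _reject_unknown("ecosystem", eco_raw, allowed)
    eco_kw: dict[str, Any] = {}
    for k, v in eco_raw.items():
        if k in _ECO_SCALARS:
            eco_kw[k] = _coerce("ecosystem", k, v, float)
        elif k in _ECO_PAIRS or k in _ECO_TRIPLES:
            want = 2 if k in _ECO_PAIRS else 3
            if not isinstance(v, list) or len(v) != want:
                raise ValueError(
                    f"configuration key [ecosystem] {k!r} must be a list of {want} numbers"
                )
            eco_kw[k] = tuple(float(x) for x in v)
        else:
            if not isinstance(v, Mapping):
                raise ValueError(f"configuration key [ecosystem] {k!r} must be a table")
            _reject_unknown(f"ecosystem.{k}", v, set(ELEMENTS))
            base = dict(getattr(EcosystemParams(), k))
            base.update({e: float(x) for e, x in v.items()})
            eco_kw[k] = base
    try:
        params = EcosystemParams(elements=elements, **eco_kw)
    except ValueError as err:
        raise ValueError(f"configuration section [ecosystem]: {err}") from err

    scen_raw = section("scenario")
    _reject_unknown("scenario", scen_raw, _SCENARIO_KEYS)
    scen_kw = {k: _coerce("scenario", k, v, _SCENARIO_KEYS[k]) for k, v in scen_raw.items()}
    try:
        scenario = ScenarioSpec(**scen_kw)
    except ValueError as err:
        raise ValueError(f"configuration section [scenario]: {err}") from err

    attr_raw = section("attribution")
    _reject_unknown("attribution", attr_raw, _ATTR_KEYS)
    attr_kw = {k: _coerce("attribution", k, v, _ATTR_KEYS[k]) for k, v in attr_raw.items()}

    return RunConfig(
        **run_kw,
        **integ_kw,
        params=params,
        scenario=scenario,
        **attr_kw,
        filled_defaults=filled,
    )


# --- minimal TOML emitter (round-trips the restricted schema above) --------

def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot emit TOML value of type {type(v)!r}")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to TOML (load/save/load is the identity)."""
    lines: list[str] = []

    def table(name: str, items: Mapping[str, Any]) -> None:
        lines.append(f"[{name}]")
        for k, v in items.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")

    table("run", {"seed": cfg.seed, "outdir": cfg.outdir})
    table("integrator", {"dt": cfg.dt, "save_every_days": cfg.save_every_days})
    p = cfg.params
    table(
        "ecosystem",
        {
            "mu_max": list(p.mu_max), "k_n": list(p.k_n), "q10": p.q10,
            "g_max": p.g_max, "k_g": p.k_g, "preferences": list(p.preferences),
            "ae_c": p.ae_c, "sigma_diss": p.sigma_diss, "m_z": p.m_z,
            "m_p": p.m_p, "lam_sink": p.lam_sink, "lam_rem": p.lam_rem,
            "kappa0": p.kappa0, "n_deep": p.n_deep, "s_n": p.s_n,
            "fe_q_min": p.fe_q_min, "rcn": p.rcn,
        },
    )
    table("ecosystem.d_deep", p.d_deep)
    table("ecosystem.s_m", p.s_m)
    for e in ELEMENTS:
        table(f"elements.{e}", dataclasses.asdict(p.elements[e]))
    table("scenario", dataclasses.asdict(cfg.scenario))
    table(
        "attribution",
        {"threshold": cfg.threshold, "group_by": list(cfg.group_by)},
    )
    Path(path).write_text("\n".join(lines))


# --- manifests and tabular output ------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI run's outputs."""

    config: dict
    seed: int
    command: str
    version: str = ""
    started: str = ""
    finished: str = ""
    outputs: list[dict] = field(default_factory=list)
    stages: list[dict] = field(default_factory=list)
    filled_defaults: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.version:
            try:
                self.version = metadata.version("zoometals")
            except metadata.PackageNotFoundError:
                self.version = "unknown"
        if not self.started:
            self.started = datetime.now(timezone.utc).isoformat()

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs.append({"path": str(p), "sha256": _sha256(p)})

    def add_stage(self, name: str, status: str, **info: Any) -> None:
        self.stages.append({"stage": name, "status": status, **info})

    def write(self, path: str | Path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def trajectory_to_frame(traj: xr.Dataset) -> pd.DataFrame:
    """Tidy long-format view of a trajectory (one row per time x variable)."""
    frames = []
    for name, da in traj.data_vars.items():
        df = da.to_dataframe(name="value").reset_index()
        df.insert(1, "variable", name)
        for col in ("element", "group"):
            if col not in df.columns:
                df[col] = ""
        frames.append(df[["time", "variable", "element", "group", "value"]])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["time", "variable", "element", "group"]).reset_index(drop=True)


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(p, index=False, float_format=FLOAT_FMT)
    return p
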