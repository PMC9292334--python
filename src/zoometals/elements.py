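"""Trace-metal stoichiometry: elements, quotas and the food-quality operators.

Carbon is the reference currency of the model; the five micronutrients
(Fe, Zn, Cu, Co, Mn) are carried as molar metal:carbon ratios ("quotas").
All quotas are absolute mol:mol ratios (e.g. the maximum Fe quota of
nanophytoplankton is ``80e-6``), concentrations are mol m^-3 and fluxes
mol m^-3 d^-1 throughout the package.

The three dimensionless operators defined here are shared by the ecosystem
simulator and the attribution pipeline:

* **food quality** -- zooplankton metal quota divided by the metal quota of
  the ingested diet.  1 means a stoichiometrically balanced diet; above 1
  the diet is metal-poor relative to zooplankton demand, below 1 it is
  metal-rich.
* **prey quantity** -- preference-weighted sum of the metal content of the
  available prey pools.
* **assimilation efficiency** -- maximal for a balanced diet and declining
  symmetrically (in log space) as food quality departs from 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ELEMENTS",
    "Element",
    "ElementParams",
    "PreyPool",
    "DEFAULT_ELEMENT_PARAMS",
    "UNDEFINED_RATIO",
    "food_quality",
    "prey_quantity",
    "ingested_stoichiometry",
    "assimilation_efficiency",
    "recycling_stoichiometry",
]

#: Canonical element order used everywhere (arrays, trajectories, panels).
ELEMENTS: tuple[str, ...] = ("Fe", "Zn", "Cu", "Co", "Mn")

#: Sentinel returned by :func:`recycling_stoichiometry` when the carbon flux
#: is zero and the ratio is undefined.  NaN keeps time series aligned and is
#: skipped by window averages.
UNDEFINED_RATIO: float = float("nan")


class Element(str):
    """One of the five supported micronutrients.

    A thin ``str`` subclass that validates its value, so an ``Element`` can
    be used directly as a dict key or DataFrame label.  Carbon is the
    reference currency of every ratio and is deliberately *not* an Element.
    """

    __slots__ = ()

    def __new__(cls, name: str) -> "Element":
        if name not in ELEMENTS:
            raise ValueError(
                f"unknown element {name!r}; supported micronutrients: {ELEMENTS}"
            )
        return super().__new__(cls, name)

    @property
    def index(self) -> int:
        return ELEMENTS.index(self)


@dataclass(frozen=True)
class ElementParams:
    """Stoichiometric constants of one micronutrient.

    Parameters
    ----------
    q_max_nano, q_max_diatom : float
        Maximum internal metal:C quota of nanophytoplankton / diatoms
        (mol metal per mol C).  Cell quotas vary Droop-style up to this cap.
    q_zoo : float
        Fixed zooplankton metal:C quota (mol:mol).  Zooplankton regulate
        their body stoichiometry homeostatically; this is the demand side
        of the food-quality ratio.  It may exceed the phytoplankton maxima.
    k_uptake : float
        Half-saturation of dissolved metal uptake (mol m^-3).
    ae_max : float
        Assimilation efficiency at food quality 1, in (0, 1].
    ae_shape : float
        Exponent controlling how fast assimilation efficiency declines as
        food quality departs from 1 (>= 0; 0 makes AE independent of food
        quality, which is useful for counterfactual isolation checks).
    """

    q_max_nano: float
    q_max_diatom: float
    q_zoo: float
    k_uptake: float
    ae_max: float = 0.8
    ae_shape: float = 1.0

    def __post_init__(self) -> None:
        for name in ("q_max_nano", "q_max_diatom", "q_zoo", "k_uptake"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ElementParams.{name} must be positive")
        if not 0 < self.ae_max <= 1:
            raise ValueError("ElementParams.ae_max must be in (0, 1]")
        if self.ae_shape < 0:
            raise ValueError("ElementParams.ae_shape must be >= 0")


#: Default per-element constants.  Maximum phytoplankton quotas and the fixed
#: zooplankton quotas follow the observational syntheses used by global
#: trace-metal ecosystem models; uptake half-saturations are typical surface
#: ocean values (mol m^-3; 1e-6 mol m^-3 = 1 nM).
DEFAULT_ELEMENT_PARAMS: dict[str, ElementParams] = {
    "Fe": ElementParams(80e-6, 80e-6, 10e-6, k_uptake=0.1e-6),
    "Zn": ElementParams(40e-6, 123e-6, 10e-6, k_uptake=1.0e-6),
    "Cu": ElementParams(16e-6, 16e-6, 10e-6, k_uptake=0.5e-6),
    "Co": ElementParams(1.2e-6, 1.2e-6, 0.16e-6, k_uptake=0.02e-6),
    "Mn": ElementParams(8e-6, 8e-6, 1e-6, k_uptake=0.1e-6),
}


@dataclass(frozen=True)
class PreyPool:
    """One prey type as seen by microzooplankton.

    ``carbon`` is the prey biomass (mol C m^-3), ``metal_content`` maps each
    element to its bulk metal concentration in that pool (mol m^-3), and
    ``preference`` is the dimensionless grazing preference weight.
    """

    carbon: float
    metal_content: Mapping[str, float] = field(default_factory=dict)
    preference: float = 1.0

    def __post_init__(self) -> None:
        if self.carbon < 0:
            raise ValueError("PreyPool.carbon must be >= 0")
        if self.preference < 0:
            raise ValueError("PreyPool.preference must be >= 0")
        if any(v < 0 for v in self.metal_content.values()):
            raise ValueError("PreyPool.metal_content must be >= 0 elementwise")

    def quota(self, element: str) -> float:
        """Implied metal:C quota of this pool (mol:mol)."""
        if self.carbon <= 0:
            raise ValueError("quota undefined for a carbon-free prey pool")
        return self.metal_content.get(str(element), 0.0) / self.carbon


def food_quality(q_zoo: float, mc_prey: float) -> float:
    """Food quality: zooplankton metal:C divided by prey metal:C.

    Values above 1 mean zooplankton demand exceeds the metal content of the
    diet (metal-poor prey); below 1 the diet carries excess metal.
    """
    if q_zoo <= 0 or mc_prey <= 0:
        raise ValueError(
            "food_quality requires positive stoichiometries "
            f"(got q_zoo={q_zoo!r}, mc_prey={mc_prey!r}); an empty or "
            "metal-free prey field must be handled upstream"
        )
    return q_zoo / mc_prey


def prey_quantity(pools: Sequence[PreyPool], element: str) -> float:
    """Preference-weighted sum of prey metal content (mol m^-3).

    This is the "prey quantity" driver: the amount of micronutrient
    available to the grazer, weighting each prey type's metal concentration
    by the grazer's preference for it.
    """
    if len(pools) == 0:
        raise ValueError("prey_quantity requires at least one prey pool")
    el = str(element)
    return float(
        sum(p.metal_content.get(el, 0.0) * p.preference for p in pools)
    )


def ingested_stoichiometry(
    grazing_c: Sequence[float], prey_quotas: Sequence[float], element: str | None = None
) -> float:
    """Bulk metal:C quota of the mixed diet (mol:mol).

    Grazing-rate-weighted mean of the per-prey quotas; this is the
    denominator of the food-quality ratio for a mixed diet.  Bounded by the
    smallest and largest prey quota.
    """
    g = np.asarray(grazing_c, dtype=float)
    q = np.asarray(prey_quotas, dtype=float)
    if g.shape != q.shape:
        raise ValueError("grazing_c and prey_quotas must have equal length")
    total = g.sum()
    if total <= 0:
        raise ValueError("ingested_stoichiometry undefined: zero total grazing")
    return float((g * q).sum() / total)


def assimilation_efficiency(fq: float, params: ElementParams) -> float:
    """Assimilation efficiency as a function of food quality.

    ``ae_max * min(fq, 1/fq) ** ae_shape``: maximal at a balanced diet
    (fq = 1), symmetric under fq -> 1/fq, and strictly decreasing in
    ``|ln fq|`` when ``ae_shape > 0``.
    """
    if fq <= 0:
        raise ValueError(f"food quality must be positive (got {fq!r})")
    return params.ae_max * min(fq, 1.0 / fq) ** params.ae_shape


def recycling_stoichiometry(flux_metal: float, flux_c: float) -> float:
    """Metal:C ratio of a recycled flux pair (mol:mol).

    Returns :data:`UNDEFINED_RATIO` (NaN) when the carbon flux is zero so
    that time series keep their alignment instead of raising mid-run.
    """
    if flux_c < 0:
        raise ValueError("carbon recycling flux must be >= 0")
    if flux_metal < 0:
        raise ValueError("metal recycling flux must be >= 0")
    if flux_c == 0.0:
        return UNDEFINED_RATIO
    return flux_metal / flux_c


def _ae_kernel(fq: float, ae_max: float, ae_shape: float) -> float:
    """Scalar AE form shared with the compiled ecosystem kernel."""
    r = fq if fq < 1.0 / fq else 1.0 / fq
    return ae_max * math.pow(r, ae_shape)
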