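"""Control vs climate scenario and the fixed-food-quality counterfactual.

Runs the 1801-2100 experiment (climate branch from 1851: +4 degC and -40%
mixing by 2100), compares PRESENT/FUTURE window means, then repeats the
climate run with food quality frozen at preindustrial levels to isolate
the food-quality contribution to recycled iron stoichiometry.
"""

from zoometals import (
    EcosystemParams,
    ScenarioSpec,
    annual_mean,
    fixed_fq_counterfactual,
    normalized_trend,
    run_pair,
    window_mean,
)

params = EcosystemParams()
spec = ScenarioSpec()  # delta_t=4, delta_kappa=0.4, linear ramp 1851-2100

pair = run_pair(params, spec)
for window in ("PRESENT", "FUTURE"):
    wc = window_mean(pair.control, window)
    wk = window_mean(pair.climate, window)
    print(f"{window}: SST {wk.value('sst'):.2f} degC "
          f"(control {wc.value('sst'):.2f}), "
          f"Fe recycling stoich {wk.value('recycle_stoich', 'Fe') * 1e6:.1f}e-6 "
          f"(control {wc.value('recycle_stoich', 'Fe') * 1e6:.1f}e-6)")

# Under the default (metal-rich diet) regime zooplankton assimilate at their
# demand cap, so freezing food quality barely changes recycling.  The
# food-quality channel matters when the diet is metal-poor: use the
# iron-drift setup, where stratification starves the grazer of iron.
from zoometals.experiments import fq_drift_setup

dparams, dspec = fq_drift_setup()
dpair = run_pair(dparams, dspec)
cf = fixed_fq_counterfactual(dparams, dspec, dpair)
print("\niron-drift scenario (stratification-only, iron-hungry grazer):")
print(f"  frozen preindustrial Fe food quality: {dpair.frozen_fq['Fe']:.3f}")

pi = window_mean(dpair.control, "PI_REF")
ref0 = pi.value("recycle_stoich", "Fe")
fq_2100 = float(annual_mean(dpair.climate.fq.sel(element="Fe")).sel(year=2100))
ref_2100 = float(annual_mean(dpair.climate.recycle_stoich.sel(element="Fe")).sel(year=2100))
cf_2100 = float(annual_mean(cf.recycle_stoich.sel(element="Fe")).sel(year=2100))
print(f"  Fe food quality by 2100: {fq_2100:.3f} (drifting away from 1)")
print("  year-2100 Fe recycling stoichiometry, normalised to the 1801-1900 mean:")
print(f"    reference climate run: {float(normalized_trend(ref_2100, ref0)):.3f}")
print(f"    fixed food quality:    {float(normalized_trend(cf_2100, ref0)):.3f}")
print(
    "interpretation: with food quality frozen, assimilation stays efficient "
    "and less iron is excreted - the gap between the runs is the "
    "food-quality contribution to the recycling stoichiometry response."
)
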