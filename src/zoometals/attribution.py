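"""Variance attribution of recycling to its four drivers.

Each response series (metal recycling flux, or recycling stoichiometry) is
modelled as a Gaussian linear model in four drivers::

    response = alpha * food_quality + beta * prey_quantity
             + gamma * sea_temperature + delta * zooplankton_biomass + eps

fitted independently per (region, element, response kind, period) group.
The variance explained is then decomposed into per-driver shares with the
LMG relative-importance metric: the share of driver j is its increase in
R-squared when entering the model, averaged over all orderings of the
predictors.  Shares are non-negative and sum to the model R-squared, so
they read directly as "fraction of response variance explained by driver j".

For display, the three *biotic* shares (food quality, prey quantity,
zooplankton biomass) are renormalised to ternary coordinates, the
temperature share is carried separately, and groups whose model explains
half the variance or less are flagged out of the ternary output.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PREDICTORS",
    "GLMFit",
    "ImportanceShares",
    "TernaryPoint",
    "AttributionResult",
    "standardize",
    "fit_glm",
    "lmg_shares",
    "lmg_shares_bruteforce",
    "classify_dominance",
    "ternary_coordinates",
    "attribute_by_group",
]

#: Driver columns, in the fixed order (alpha, beta, gamma, delta).
PREDICTORS: tuple[str, ...] = ("fq", "prey_q", "sst", "zoo_b")
#: Greek coefficient names in the same order.
COEF_NAMES: tuple[str, ...] = ("alpha", "beta", "gamma", "delta")

RESPONSE = "response"


def _check_panel(panel: pd.DataFrame, min_extra: int = 2) -> None:
    cols = [RESPONSE, *PREDICTORS]
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing mandated column(s): {missing}")
    sub = panel[cols]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"panel has missing values in fitted column(s): {bad}")
    if len(panel) < len(PREDICTORS) + min_extra:
        raise ValueError(
            f"need at least {len(PREDICTORS) + min_extra} rows, got {len(panel)}"
        )


def standardize(panel: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Zero-mean, unit-variance (ddof=1) response and predictors.

    Returns the transformed panel plus the invertible transform record
    ``{column: (mean, sd)}``.  R-squared-based importance shares are
    invariant to this affine rescaling; standardizing simply conditions the
    fit.  A zero-variance column (a degenerate group, e.g. constant SST)
    raises with the column named.
    """
    _check_panel(panel)
    out = panel.copy()
    record: dict[str, tuple[float, float]] = {}
    for col in (RESPONSE, *PREDICTORS):
        x = out[col].to_numpy(dtype=float)
        mu = x.mean()
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"zero-variance column: {col}")
        out[col] = (x - mu) / sd
        record[col] = (float(mu), float(sd))
    return out, record


@dataclass
class GLMFit:
    """An ordinary-least-squares fit of the four-driver linear model.

    ``coefficients`` maps predictor name to its slope (alpha..delta in the
    order of :data:`PREDICTORS`); ``residual_variance`` is the unbiased
    error variance of the eps term; ``stderr`` the coefficient standard
    errors.
    """

    coefficients: dict[str, float]
    intercept: float
    residual_variance: float
    r_squared: float
    n: int
    stderr: dict[str, float]

    @property
    def greek(self) -> dict[str, float]:
        return {g: self.coefficients[p] for g, p in zip(COEF_NAMES, PREDICTORS)}


def _collinear_groups(x: np.ndarray) -> list[str]:
    """Names of predictors involved in (near-)exact linear dependence."""
    xs = (x - x.mean(0)) / np.where(x.std(0) > 0, x.std(0), 1.0)
    corr = np.corrcoef(xs, rowvar=False)
    bad: set[str] = set()
    p = x.shape[1]
    for i in range(p):
        if x[:, i].std() == 0:
            bad.add(PREDICTORS[i])
        for j in range(i + 1, p):
            if abs(corr[i, j]) > 1 - 1e-10:
                bad.update((PREDICTORS[i], PREDICTORS[j]))
    return sorted(bad) if bad else list(PREDICTORS)


def fit_glm(panel: pd.DataFrame) -> GLMFit:
    """OLS fit (Gaussian error, identity link) of response on the four drivers."""
    _check_panel(panel)
    y = panel[RESPONSE].to_numpy(dtype=float)
    x = panel[list(PREDICTORS)].to_numpy(dtype=float)
    flat = [c for c, col in zip(PREDICTORS, x.T) if col.std() == 0]
    if y.std() == 0:
        flat.append(RESPONSE)
    if flat:
        raise ValueError(f"zero-variance column: {', '.join(flat)}")
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(
            "rank-deficient design; collinear predictor(s): "
            + ", ".join(_collinear_groups(x))
        )
    res = sm.OLS(y, design).fit()
    return GLMFit(
        coefficients={p: float(b) for p, b in zip(PREDICTORS, res.params[1:])},
        intercept=float(res.params[0]),
        residual_variance=float(res.mse_resid),
        r_squared=float(res.rsquared),
        n=int(res.nobs),
        stderr={p: float(s) for p, s in zip(PREDICTORS, res.bse[1:])},
    )


@dataclass
class ImportanceShares:
    """Per-driver fractions of response variance; they sum to R-squared."""

    shares: dict[str, float]
    r_squared: float

    def biotic(self) -> tuple[float, float, float]:
        """(food quality, prey quantity, zooplankton biomass) shares."""
        return (self.shares["fq"], self.shares["prey_q"], self.shares["zoo_b"])


def _moment_r2_factory(panel: pd.DataFrame):
    """R-squared of any predictor subset, from centred second moments."""
    y = panel[RESPONSE].to_numpy(dtype=float)
    x = panel[list(PREDICTORS)].to_numpy(dtype=float)
    # standardize internally: R^2 is scale-invariant and the moment solve
    # stays well conditioned even when drivers differ by orders of magnitude
    xs = x - x.mean(0)
    sd = xs.std(0, ddof=1)
    if np.any(sd <= 0):
        bad = [PREDICTORS[i] for i in np.where(sd <= 0)[0]]
        raise ValueError(f"zero-variance column: {', '.join(bad)}")
    xs /= sd
    ys = y - y.mean()
    sdy = ys.std(ddof=1)
    if sdy <= 0:
        raise ValueError("zero-variance column: response")
    ys /= sdy
    cxx = xs.T @ xs
    cxy = xs.T @ ys
    cyy = ys @ ys

    def r2(subset: tuple[int, ...]) -> float:
        if not subset:
            return 0.0
        idx = list(subset)
        beta = np.linalg.solve(cxx[np.ix_(idx, idx)], cxy[idx])
        return float(cxy[idx] @ beta / cyy)

    return r2


def lmg_shares(panel: pd.DataFrame) -> ImportanceShares:
    """LMG relative-importance decomposition of the four-driver model.

    Implements the subset-weighted form: the share of predictor j is
    ``sum over S subset of others of w(|S|) * (R2(S+j) - R2(S))`` with
    ``w(k) = k! (p-1-k)! / p!`` — algebraically the average sequential
    R-squared gain of j over all p! predictor orderings.
    """
    _check_panel(panel)
    p = len(PREDICTORS)
    r2 = _moment_r2_factory(panel)
    cache = {s: r2(s) for k in range(p + 1) for s in itertools.combinations(range(p), k)}
    shares: dict[str, float] = {}
    for j in range(p):
        others = [i for i in range(p) if i != j]
        total = 0.0
        for k in range(p):
            w = math.factorial(k) * math.factorial(p - 1 - k) / math.factorial(p)
            for s in itertools.combinations(others, k):
                total += w * (cache[tuple(sorted((*s, j)))] - cache[s])
        shares[PREDICTORS[j]] = total
    return ImportanceShares(shares=shares, r_squared=cache[tuple(range(p))])


def lmg_shares_bruteforce(panel: pd.DataFrame) -> ImportanceShares:
    """Oracle LMG: explicit enumeration of all p! predictor orderings.

    Independent of :func:`lmg_shares`: R-squared values are obtained by
    least-squares fits of the growing design rather than from the moment
    matrix.  Only intended for small p (p! fits of up to p predictors).
    """
    _check_panel(panel)
    p = len(PREDICTORS)
    if p > 6:
        raise ValueError("bruteforce enumeration limited to p <= 6")
    y = panel[RESPONSE].to_numpy(dtype=float)
    ys = (y - y.mean()) / y.std(ddof=1)
    x = panel[list(PREDICTORS)].to_numpy(dtype=float)
    xs = (x - x.mean(0)) / x.std(0, ddof=1)
    sst = float(ys @ ys)

    def r2_fit(idx: Sequence[int]) -> float:
        if not idx:
            return 0.0
        a = xs[:, list(idx)]
        coef, *_ = np.linalg.lstsq(a, ys, rcond=None)
        resid = ys - a @ coef
        return 1.0 - float(resid @ resid) / sst

    totals = np.zeros(p)
    count = 0
    for order in itertools.permutations(range(p)):
        prev = 0.0
        for pos in range(p):
            cur = r2_fit(order[: pos + 1])
            totals[order[pos]] += cur - prev
            prev = cur
        count += 1
    shares = totals / count
    return ImportanceShares(
        shares={PREDICTORS[j]: float(shares[j]) for j in range(p)},
        r_squared=r2_fit(range(p)),
    )


@dataclass
class TernaryPoint:
    """Ternary (biotic) coordinates of one fitted group.

    ``qual``/``quant``/``zoo`` are the food-quality, prey-quantity and
    zooplankton-biomass shares renormalised to sum to 1; the temperature
    share is kept separately as an absolute fraction of response variance.
    ``included`` applies the R-squared > threshold filter; ``tie`` flags a
    dominance decided by the fixed order qual > quant > zoo.
    """

    qual: float
    quant: float
    zoo: float
    temperature_share: float
    r_squared: float
    included: bool
    dominant: str | None
    tie: bool


def classify_dominance(shares: ImportanceShares, threshold: float = 0.5) -> TernaryPoint:
    """Ternary coordinates, dominant biotic driver and the R-squared filter."""
    b = shares.biotic()
    s = sum(b)
    included = shares.r_squared > threshold
    if s <= 0:
        return TernaryPoint(
            math.nan, math.nan, math.nan, shares.shares["sst"],
            shares.r_squared, False, None, False,
        )
    qual, quant, zoo = (v / s for v in b)
    labels = ("qual", "quant", "zoo")
    coords = (qual, quant, zoo)
    top = max(coords)
    winners = [l for l, c in zip(labels, coords) if c == top]
    return TernaryPoint(
        qual=qual,
        quant=quant,
        zoo=zoo,
        temperature_share=shares.shares["sst"],
        r_squared=shares.r_squared,
        included=included,
        dominant=winners[0],
        tie=len(winners) > 1,
    )


def ternary_coordinates(point: TernaryPoint) -> tuple[float, float]:
    """Equilateral-triangle embedding of (qual, quant, zoo).

    qual at (0,0), quant at (1,0), zoo at the apex (0.5, sqrt(3)/2).
    """
    a, b, c = point.qual, point.quant, point.zoo
    s = a + b + c
    if not np.isfinite(s) or s <= 0:
        return (math.nan, math.nan)
    return (0.5 * (2 * b + c) / s, math.sqrt(3.0) / 2.0 * c / s)


@dataclass
class AttributionResult:
    """Per-group fits, shares and ternary points, plus recorded failures."""

    table: pd.DataFrame
    failures: pd.DataFrame
    threshold: float

    def ternary_table(self) -> pd.DataFrame:
        """Rows passing the variance-explained filter (R-squared > threshold)."""
        return self.table[self.table["included"]].reset_index(drop=True)


def attribute_by_group(
    panel: pd.DataFrame,
    threshold: float = 0.5,
    by: Sequence[str] | None = None,
) -> AttributionResult:
    """Fit model + LMG shares per group and classify dominance.

    Groups are (region, element, response_kind, period) by default — any of
    those columns present in the panel.  Groups failing the fit
    preconditions (too few rows, zero-variance or collinear columns) are
    reported in ``failures`` rather than silently dropped.
    """
    if by is None:
        by = [c for c in ("region", "element", "response_kind", "period") if c in panel.columns]
    by = list(by)
    rows: list[dict] = []
    fails: list[dict] = []
    groups: Iterable = panel.groupby(by) if by else [((), panel)]
    for key, df in groups:
        if not isinstance(key, tuple):
            key = (key,)
        keyd = dict(zip(by, key))
        try:
            fit = fit_glm(df)
            shares = lmg_shares(df)
            point = classify_dominance(shares, threshold=threshold)
            tx, ty = ternary_coordinates(point)
        except ValueError as err:
            fails.append({**keyd, "reason": str(err), "n": len(df)})
            continue
        rows.append(
            {
                **keyd,
                "n": fit.n,
                **{f"coef_{p}": fit.coefficients[p] for p in PREDICTORS},
                "intercept": fit.intercept,
                "residual_variance": fit.residual_variance,
                "r_squared": fit.r_squared,
                **{f"share_{p}": shares.shares[p] for p in PREDICTORS},
                "qual": point.qual,
                "quant": point.quant,
                "zoo": point.zoo,
                "temperature_share": point.temperature_share,
                "dominant": point.dominant,
                "tie": point.tie,
                "included": point.included,
                "ternary_x": tx,
                "ternary_y": ty,
            }
        )
    return AttributionResult(
        table=pd.DataFrame(rows),
        failures=pd.DataFrame(fails, columns=[*by, "reason", "n"]),
        threshold=threshold,
    )
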