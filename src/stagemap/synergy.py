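"""Median-effect dose–response fitting and combination-index synergy.

Viability wells (raw luminescence) are normalized as a percentage of the
vehicle-treated wells; the fraction affected is fa = 1 - viability/100.
Single-agent curves follow the median-effect equation

    fa / (1 - fa) = (D / Dm)^m,

fit by ordinary least squares on the linearized form
log10(fa/(1-fa)) = m log10 D - m log10 Dm; Dm is the median-effect dose and
is taken as the IC50 throughout.  For a two-drug dose grid the Combination
Index at an interior point with observed effect fa is

    CI = d1/Dx1(fa) + d2/Dx2(fa)        (mutually exclusive model),

with Dx(fa) = Dm (fa/(1-fa))^(1/m) the single-agent dose producing the same
effect; the mutually nonexclusive variant adds (d1 d2)/(Dx1 Dx2).  CI < 1
indicates synergy, CI = 1 additivity, CI > 1 antagonism; the grid's
non-constant-ratio design uses each point's observed effect directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, FitError

logger = logging.getLogger(__name__)

DEFAULT_ADDITIVITY_BAND = 0.1


@dataclass
class MedianEffectFit:
    """Fitted median-effect parameters for one drug."""

    drug: str
    Dm: float  # median-effect dose (IC50), µM
    slope: float  # sigmoidicity m
    r_squared: float
    n_points_used: int
    flagged: bool = False  # non-positive slope or otherwise suspect fit


def _canonical(table: pd.DataFrame) -> pd.DataFrame:
    """Accept single-agent (drug, dose) or pair (drug1.., drug2..) layouts."""
    t = table.copy()
    if "drug" in t.columns and "drug1" not in t.columns:
        t = t.rename(columns={"drug": "drug1", "dose": "dose1"})
    if "drug2" not in t.columns:
        t["drug2"] = ""
        t["dose2"] = 0.0
    t["drug2"] = t["drug2"].fillna("")
    t["dose2"] = t["dose2"].fillna(0.0)
    required = {"drug1", "dose1", "drug2", "dose2", "replicate", "rlu"}
    missing = required - set(t.columns)
    if missing:
        raise ConfigurationError(f"viability table missing columns: {sorted(missing)}")
    if (t["rlu"] < 0).any():
        raise ConfigurationError("viability table: rlu must be >= 0")
    return t


def normalize_viability(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition percent viability and fraction affected.

    Conditions are (drug1, dose1, drug2, dose2) cells; viability is
    100 x mean(rlu) / mean(rlu of the vehicle wells, all doses 0).  Points
    with fa outside (0, 1) are retained but marked non-informative so fits
    can exclude them.
    """
    t = _canonical(table)
    vehicle = t[(t["dose1"] == 0) & (t["dose2"] == 0)]
    if vehicle.empty:
        raise ConfigurationError("normalize_viability: no vehicle (all-doses-zero) wells present")
    v0 = vehicle["rlu"].mean()
    cond = (
        t.groupby(["drug1", "dose1", "drug2", "dose2"], as_index=False)
        .agg(rlu_mean=("rlu", "mean"), n_reps=("replicate", "size"))
    )
    cond["viability_pct"] = 100.0 * cond["rlu_mean"] / v0
    cond["fa"] = 1.0 - cond["viability_pct"] / 100.0
    cond["informative"] = (cond["fa"] > 0) & (cond["fa"] < 1) & (cond[["dose1", "dose2"]].sum(axis=1) > 0)
    return cond


def fit_median_effect(doses: np.ndarray, fa: np.ndarray, drug: str = "drug") -> MedianEffectFit:
    """OLS fit of the linearized median-effect equation.

    Only informative points (dose > 0, fa strictly inside (0, 1)) enter the
    fit; fewer than two of them raises :class:`FitError`.  A non-positive
    fitted slope is reported but flagged.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    keep = (doses > 0) & (fa > 0) & (fa < 1)
    d, f = doses[keep], fa[keep]
    if len(d) < 2 or len(np.unique(d)) < 2:
        raise FitError(f"fit_median_effect({drug}): need >= 2 informative points at distinct doses")
    x = np.log10(d)
    y = np.log10(f / (1.0 - f))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    flagged = slope <= 0
    if flagged:
        logger.warning("fit_median_effect(%s): non-positive slope %.4g", drug, slope)
        dm = np.nan
    else:
        dm = 10.0 ** (-intercept / slope)
    return MedianEffectFit(drug=drug, Dm=float(dm), slope=float(slope), r_squared=r2,
                           n_points_used=int(len(d)), flagged=bool(flagged))


def fit_from_table(table: pd.DataFrame, drug: str) -> MedianEffectFit:
    """Fit one drug's median-effect curve from its single-agent wells."""
    cond = normalize_viability(table)
    single = cond[(cond["drug1"] == drug) & (cond["dose2"] == 0) & (cond["dose1"] > 0)]
    alt = cond[(cond["drug2"] == drug) & (cond["dose1"] == 0) & (cond["dose2"] > 0)]
    doses = np.concatenate([single["dose1"].to_numpy(), alt["dose2"].to_numpy()])
    fa = np.concatenate([single["fa"].to_numpy(), alt["fa"].to_numpy()])
    if doses.size == 0:
        raise FitError(f"fit_from_table: no single-agent wells for {drug!r}")
    return fit_median_effect(doses, fa, drug=drug)


def dose_for_effect(fit: MedianEffectFit, fa: float | np.ndarray) -> float | np.ndarray:
    """Single-agent dose producing effect fa: Dx = Dm (fa/(1-fa))^(1/m)."""
    fa_arr = np.asarray(fa, dtype=float)
    if np.any((fa_arr <= 0) | (fa_arr >= 1)):
        raise ConfigurationError("dose_for_effect: fa must lie strictly in (0, 1)")
    dx = fit.Dm * (fa_arr / (1.0 - fa_arr)) ** (1.0 / fit.slope)
    return float(dx) if np.isscalar(fa) else dx


def _classify(ci: float, band: float) -> str:
    if not np.isfinite(ci):
        return "undefined"
    if ci < 1.0 - band:
        return "synergy"
    if ci > 1.0 + band:
        return "antagonism"
    return "additive"


def combination_index(
    grid: pd.DataFrame,
    fitA: MedianEffectFit | None = None,
    fitB: MedianEffectFit | None = None,
    model: str = "exclusive",
    band: float = DEFAULT_ADDITIVITY_BAND,
) -> pd.DataFrame:
    """Combination indices for every interior point of a two-drug dose grid.

    Single-agent fits default to the grid's own zero-dose rows/columns.  A
    point whose observed fa falls outside (0, 1) gets CI = NaN and
    classification "undefined" rather than being silently dropped.
    """
    if model not in ("exclusive", "nonexclusive"):
        raise ConfigurationError("combination_index: model must be 'exclusive' or 'nonexclusive'")
    cond = normalize_viability(grid)
    drugs1 = sorted(set(cond.loc[cond["dose1"] > 0, "drug1"]))
    drugs2 = sorted(set(cond.loc[cond["dose2"] > 0, "drug2"]))
    if len(drugs1) != 1 or len(drugs2) != 1:
        raise ConfigurationError("combination_index: grid must involve exactly one drug per axis")
    if fitA is None:
        fitA = fit_from_table(grid, drugs1[0])
    if fitB is None:
        fitB = fit_from_table(grid, drugs2[0])
    if fitA.flagged or fitB.flagged:
        raise FitError("combination_index: flagged single-agent fit; cannot invert the curve")

    interior = cond[(cond["dose1"] > 0) & (cond["dose2"] > 0)]
    rows = []
    for _, pt in interior.iterrows():
        fa = float(pt["fa"])
        if 0 < fa < 1:
            dx1 = dose_for_effect(fitA, fa)
            dx2 = dose_for_effect(fitB, fa)
            ci = pt["dose1"] / dx1 + pt["dose2"] / dx2
            if model == "nonexclusive":
                ci += (pt["dose1"] * pt["dose2"]) / (dx1 * dx2)
        else:
            dx1 = dx2 = ci = np.nan
        rows.append(
            {
                "d1": pt["dose1"], "d2": pt["dose2"], "fa": fa,
                "Dx1": dx1, "Dx2": dx2, "CI": ci,
                "classification": _classify(ci, band),
            }
        )
    return pd.DataFrame(rows, columns=["d1", "d2", "fa", "Dx1", "Dx2", "CI", "classification"])


def fit_summary(fits: list[MedianEffectFit]) -> pd.DataFrame:
    """Per-drug fit summary table (drug, Dm, m, r2, n)."""
    return pd.DataFrame(
        [
            {"drug": f.drug, "Dm": f.Dm, "m": f.slope, "r2": f.r_squared, "n": f.n_points_used}
            for f in fits
        ]
    )
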