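"""Steady-state toxicokinetics and reverse dosimetry for EAR-MED screening.

The chain translates an in vitro activity concentration (ACC, μM) into a
human administered-dose scale and compares it with the dose implied by a
measured water concentration:

* MED (measured equivalent dose, mg/kg/d) — water concentration (μg/L)
  × 0.2 L/kg/d ingestion (the conservative birth-to-<1-month rate)
  × 0.001 mg/μg.
* Css — steady-state plasma concentration per unit oral dose from the
  three-compartment steady-state model with restrictive, well-stirred
  hepatic clearance and renal clearance by glomerular filtration of the
  unbound fraction, assuming 100 % oral bioavailability:

      CLint_whole [L/h] = CLint [μL/min/10⁶ cells] × hepatocellularity
                          [10⁶ cells/g] × liver mass [g] × 60 × 1e-6
      CL_h = Q_liver · f_up · CLint_whole / (Q_liver + f_up · CLint_whole)
      CL_r = GFR · f_up
      Css [mg/L] = (dose · BW / 24) / (CL_r + CL_h),   μM = Css/MW × 1000

* Css₉₅ — the 95th population percentile of Css under Monte Carlo
  variation of intrinsic clearance, fraction unbound, liver blood flow
  and glomerular filtration rate (truncated normals about the central
  values).
* AED₉₅ (mg/kg/d) = ACC (μM) / Css₉₅ (μM per mg/kg/d) — the administered
  dose whose conservative (95th-percentile) plasma level equals the ACC.
  Note the customary subscript: AED₉₅ is a *low* (protective) dose
  because it is driven by the high quantile of Css.
* Per chemical, the 5th percentile of AED₉₅ across endpoints is the
  floor; EAR_MED = MED / floor, summed per sample to ∑EAR-MED with the
  same 0.001 / 1 screening thresholds and 1e-5 inclusion screen as ∑EAR.

Quantiles use linear interpolation between order statistics throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError

INGESTION_L_PER_KG_DAY = 0.2
UG_TO_MG = 1e-3
EARMED_INCLUSION_MIN = 1e-5
EARMED_SCREENING_LEVEL = 0.001
EARMED_ELEVATED_LEVEL = 1.0


@dataclass(frozen=True)
class TkParams:
    """Chemical-specific toxicokinetic constants.

    intrinsic_clearance is in μL/min per 10⁶ hepatocytes; fraction
    unbound in plasma lies in (0, 1]; molecular weight in g/mol.
    """

    analyte_id: str
    molecular_weight: float
    fraction_unbound: float
    intrinsic_clearance: float

    def __post_init__(self) -> None:
        if not self.molecular_weight > 0:
            raise ValidationError(f"{self.analyte_id}: molecular_weight must be > 0")
        if not (0 < self.fraction_unbound <= 1):
            raise ValidationError(f"{self.analyte_id}: fraction_unbound must be in (0, 1]")
        if self.intrinsic_clearance < 0:
            raise ValidationError(f"{self.analyte_id}: intrinsic_clearance must be >= 0")


@dataclass(frozen=True)
class Physiology:
    """Reference adult physiology (all configurable).

    Defaults: 70 kg body weight, 90 L/h liver blood flow, 6.7 L/h
    glomerular filtration rate, 110 ×10⁶ hepatocytes per g liver,
    1820 g liver.
    """

    body_weight: float = 70.0
    liver_blood_flow: float = 90.0
    glomerular_filtration_rate: float = 6.7
    hepatocellularity: float = 110.0
    liver_mass: float = 1820.0

    def __post_init__(self) -> None:
        for name in ("body_weight", "liver_blood_flow", "glomerular_filtration_rate",
                     "hepatocellularity", "liver_mass"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"physiology: {name} must be > 0")


@dataclass(frozen=True)
class VariabilitySpec:
    """Monte Carlo population-variability settings.

    Each varied parameter is drawn from a normal with the stated CV
    about its central value, truncated to ``truncation`` multipliers of
    that value (fraction unbound additionally clipped to (0, 1]).
    """

    cv_intrinsic_clearance: float = 0.3
    cv_fraction_unbound: float = 0.3
    cv_liver_blood_flow: float = 0.3
    cv_glomerular_filtration_rate: float = 0.3
    n_draws: int = 5000
    seed: int = 0
    truncation: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")
        for name in ("cv_intrinsic_clearance", "cv_fraction_unbound",
                     "cv_liver_blood_flow", "cv_glomerular_filtration_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


class NonComputableCss(ValueError):
    """Total clearance is zero: steady state does not exist for this chemical."""


def compute_med(concentration_ugL: float | np.ndarray) -> float | np.ndarray:
    """Measured equivalent dose (mg/kg/d) from a water concentration (μg/L)."""
    c = np.asarray(concentration_ugL, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be >= 0")
    med = c * INGESTION_L_PER_KG_DAY * UG_TO_MG
    return float(med) if np.isscalar(concentration_ugL) else med


def whole_liver_clint(intrinsic_clearance: float, phys: Physiology) -> float:
    """Scale per-cell intrinsic clearance (μL/min/10⁶ cells) to whole liver (L/h)."""
    return intrinsic_clearance * phys.hepatocellularity * phys.liver_mass * 60.0 * 1e-6


def css_steady_state(
    tk: TkParams,
    phys: Physiology = Physiology(),
    dose: float = 1.0,
    _fup: float | np.ndarray | None = None,
    _clint: float | np.ndarray | None = None,
    _q: float | np.ndarray | None = None,
    _gfr: float | np.ndarray | None = None,
) -> float | np.ndarray:
    """Steady-state plasma concentration (μM) at the given oral dose (mg/kg/d).

    The underscore-prefixed arguments override individual parameters and
    accept arrays; they exist for the Monte Carlo sampler.
    """
    if dose <= 0:
        raise ValidationError("dose must be > 0")
    fup = tk.fraction_unbound if _fup is None else _fup
    clint = tk.intrinsic_clearance if _clint is None else _clint
    q = phys.liver_blood_flow if _q is None else _q
    gfr = phys.glomerular_filtration_rate if _gfr is None else _gfr

    clint_whole = np.asarray(clint, dtype=float) * phys.hepatocellularity * phys.liver_mass * 60.0 * 1e-6
    cl_h = (q * fup * clint_whole) / (q + fup * clint_whole)
    cl_r = np.asarray(gfr, dtype=float) * fup
    cl_total = cl_h + cl_r
    dose_rate = dose * phys.body_weight / 24.0  # mg/h
    scalar = np.ndim(cl_total) == 0
    if scalar and cl_total == 0:
        raise NonComputableCss(tk.analyte_id)
    css_mgL = dose_rate / cl_total
    css_uM = css_mgL / tk.molecular_weight * 1000.0
    return float(css_uM) if scalar else css_uM


def _truncnorm_draws(rng: np.random.Generator, center: float, cv: float,
                     n: int, lo_mult: float, hi_mult: float,
                     hard_hi: float = np.inf) -> np.ndarray:
    if cv == 0 or center == 0:
        return np.full(n, min(center, hard_hi))
    sd = cv * center
    lo = lo_mult * center
    hi = min(hi_mult * center, hard_hi)
    a, b = (lo - center) / sd, (hi - center) / sd
    return stats.truncnorm.rvs(a, b, loc=center, scale=sd, size=n, random_state=rng)


def css95_monte_carlo(
    tk: TkParams,
    phys: Physiology = Physiology(),
    var: VariabilitySpec = VariabilitySpec(),
) -> float:
    """95th population percentile of Css (μM per 1 mg/kg/d) by Monte Carlo.

    Deterministic for a fixed ``var.seed``; with all CVs zero this
    reduces exactly to the deterministic :func:`css_steady_state`.
    """
    rng = np.random.default_rng(var.seed)
    n = var.n_draws
    lo, hi = var.truncation
    clint = _truncnorm_draws(rng, tk.intrinsic_clearance, var.cv_intrinsic_clearance, n, lo, hi)
    fup = _truncnorm_draws(rng, tk.fraction_unbound, var.cv_fraction_unbound, n, lo, hi, hard_hi=1.0)
    fup = np.clip(fup, np.finfo(float).tiny, 1.0)
    q = _truncnorm_draws(rng, phys.liver_blood_flow, var.cv_liver_blood_flow, n, lo, hi)
    gfr = _truncnorm_draws(rng, phys.glomerular_filtration_rate,
                           var.cv_glomerular_filtration_rate, n, lo, hi)
    css = css_steady_state(tk, phys, dose=1.0, _fup=fup, _clint=clint, _q=q, _gfr=gfr)
    css = np.asarray(css, dtype=float)
    finite = css[np.isfinite(css)]
    if finite.size == 0:
        raise NonComputableCss(tk.analyte_id)
    return float(np.percentile(finite, 95))


def aed95_per_endpoint(acc_uM: float | np.ndarray, css95_uM: float) -> float | np.ndarray:
    """Administered equivalent dose (mg/kg/d) for an endpoint's ACC."""
    acc = np.asarray(acc_uM, dtype=float)
    if np.any(acc <= 0) or not css95_uM > 0:
        raise ValidationError("acc_uM and css95_uM must be positive")
    out = acc / css95_uM
    return float(out) if np.isscalar(acc_uM) else out


def chemical_aed_floor(aed95_values) -> float:
    """5th percentile (linear interpolation) of AED₉₅ across endpoints."""
    vals = np.asarray(list(aed95_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no AED95 values: chemical lacks toxicokinetic coverage")
    return float(np.percentile(vals, 5))


def build_aed_floors(
    acc_filtered: pd.DataFrame,
    tk_table: pd.DataFrame,
    phys: Physiology = Physiology(),
    var: VariabilitySpec = VariabilitySpec(),
    catalog: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the reverse-dosimetry chain for every chemical with TK coverage.

    ``acc_filtered`` needs ``acc_uM`` (derived from acc_ugL / MW when
    absent).  Chemicals missing molecular weight, fraction unbound or
    intrinsic clearance are excluded and reported in the coverage table.

    Per-chemical seeds are derived deterministically from ``var.seed``
    and the alphabetical rank of the analyte, so results do not depend
    on table order.

    Returns ``(floors, aed_per_endpoint, coverage)``.
    """
    acc = acc_filtered.copy()
    if "acc_uM" not in acc.columns:
        acc["acc_uM"] = np.nan
    if acc["acc_uM"].isna().any():
        mw_map: dict[str, float] = {}
        if catalog is not None:
            mw_map.update(dict(zip(catalog["analyte_id"], catalog["molecular_weight"])))
        mw_map.update(dict(zip(tk_table["analyte_id"], tk_table["molecular_weight"])))
        need = acc["acc_uM"].isna()
        acc.loc[need, "acc_uM"] = (
            acc.loc[need, "acc_ugL"] / acc.loc[need, "analyte_id"].map(mw_map))

    tk_ok = tk_table.dropna(
        subset=["molecular_weight", "fraction_unbound", "intrinsic_clearance"])
    tk_map = {r.analyte_id: TkParams(r.analyte_id, r.molecular_weight,
                                     r.fraction_unbound, r.intrinsic_clearance)
              for r in tk_ok.itertuples()}

    analytes = sorted(set(acc["analyte_id"]))
    floor_rows, aed_rows, cov_rows = [], [], []
    for i, aid in enumerate(analytes):
        grp = acc.loc[(acc["analyte_id"] == aid) & acc["acc_uM"].notna()]
        if aid not in tk_map:
            cov_rows.append((aid, len(grp), False, "no toxicokinetic parameters"))
            continue
        if grp.empty:
            cov_rows.append((aid, 0, False, "no usable ACC in uM"))
            continue
        tk = tk_map[aid]
        sub_seed = int(np.random.SeedSequence([var.seed, i]).generate_state(1)[0] % (2**31))
        var_i = VariabilitySpec(
            cv_intrinsic_clearance=var.cv_intrinsic_clearance,
            cv_fraction_unbound=var.cv_fraction_unbound,
            cv_liver_blood_flow=var.cv_liver_blood_flow,
            cv_glomerular_filtration_rate=var.cv_glomerular_filtration_rate,
            n_draws=var.n_draws, seed=sub_seed, truncation=var.truncation)
        try:
            css95 = css95_monte_carlo(tk, phys, var_i)
        except NonComputableCss:
            cov_rows.append((aid, len(grp), False, "zero total clearance"))
            continue
        aeds = aed95_per_endpoint(grp["acc_uM"].to_numpy(), css95)
        for ep, acc_um, aed in zip(grp["endpoint_id"], grp["acc_uM"], np.atleast_1d(aeds)):
            aed_rows.append((aid, ep, acc_um, css95, aed))
        floor_rows.append((aid, css95, chemical_aed_floor(np.atleast_1d(aeds)), len(grp)))
        cov_rows.append((aid, len(grp), True, ""))

    floors = pd.DataFrame(floor_rows, columns=["analyte_id", "css95_uM", "aed_floor", "n_endpoints"])
    aed = pd.DataFrame(aed_rows, columns=["analyte_id", "endpoint_id", "acc_uM", "css95_uM", "aed95"])
    coverage = pd.DataFrame(cov_rows, columns=["analyte_id", "n_endpoints", "covered", "reason"])
    return floors, aed, coverage


def summarize_sample_ear_med(
    detections: pd.DataFrame,
    floors: pd.DataFrame,
    samples: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample ∑EAR-MED summary and driver contributions.

    Each detected organic chemical with an AED floor contributes
    EAR_MED = MED / floor; chemicals below the 1e-5 inclusion screen are
    dropped from the sum.  Returns ``(summary, contributions)`` in the
    same shape as the TQ/EAR summaries.
    """
    from .benchmarks import _summarize_quotients
    from .datamodel import ORGANIC_CLASSES

    det = detections
    if "detected" in det.columns:
        det = det.loc[det["detected"]]
    if "analyte_class" in det.columns:
        det = det.loc[det["analyte_class"].isin(ORGANIC_CLASSES)]
    merged = det.merge(floors[["analyte_id", "aed_floor"]], on="analyte_id", how="inner")
    merged = merged.copy()
    merged["med"] = compute_med(merged["concentration"].to_numpy())
    merged["ear_med"] = merged["med"] / merged["aed_floor"]
    merged["included"] = merged["ear_med"] >= EARMED_INCLUSION_MIN
    q = merged[["sample_id", "analyte_id", "med", "aed_floor", "ear_med", "included"]]
    return _summarize_quotients(
        q, samples, "ear_med", "sum_ear_med",
        (EARMED_SCREENING_LEVEL, EARMED_ELEVATED_LEVEL))
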