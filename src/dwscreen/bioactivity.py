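"""Bioactivity (exposure–activity ratio) screening against ACC endpoints.

EAR = detected water concentration / activity concentration at cutoff
(ACC), the in vitro concentration at which a high-throughput assay
endpoint reaches its positive-response threshold.  Endpoints flagged as
non-specific, baseline, or having an unreliable concentration–response
curve are excluded before any ratio is formed.

Chemical-level aggregation defaults to the maximum EAR across retained
endpoints, which is then summed across detected organic chemicals under
concentration addition to the per-sample ∑EAR.  An endpoint-wise
alternative (sum within endpoint across chemicals, report the maximum
endpoint sum) is available as ``aggregation="per_endpoint"``.

∑EAR = 0.001 is the screening level of potential concern; ∑EAR > 1
flags elevated probability of molecular-level effects.  Individual
chemical EARs below 1e-5 are screened out of the assessment.  Only
organic analyte classes are screened; inorganics and microbial rows are
excluded by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import ORGANIC_CLASSES

EAR_INCLUSION_MIN = 1e-5
EAR_SCREENING_LEVEL = 0.001
EAR_ELEVATED_LEVEL = 1.0

FLAG_COLUMNS = ("flag_nonspecific", "flag_baseline", "flag_unreliable")


def filter_endpoints(acc: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Drop flagged assay endpoints; report removal counts per flag.

    Returns ``(retained, removals)`` where removals is a Series indexed
    by flag name (a record can count under several flags).
    """
    flags = [c for c in FLAG_COLUMNS if c in acc.columns]
    if not flags:
        return acc.reset_index(drop=True), pd.Series(dtype=int)
    removals = acc[flags].sum()
    keep = ~acc[flags].any(axis=1)
    return acc.loc[keep].reset_index(drop=True), removals.astype(int)


def acc_in_ugL(acc: pd.DataFrame, catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ensure an ``acc_ugL`` column, deriving it from μM via molecular weight.

    μM × MW (g/mol) = μg/L, since 1 μmol/L of a chemical of mass MW g/mol
    weighs MW μg per litre.
    """
    out = acc.copy()
    if "acc_ugL" not in out.columns:
        out["acc_ugL"] = np.nan
    if out["acc_ugL"].isna().any():
        if catalog is None:
            raise ValueError("acc_ugL missing and no catalog with molecular weights supplied")
        mw = dict(zip(catalog["analyte_id"], catalog["molecular_weight"]))
        need = out["acc_ugL"].isna()
        out.loc[need, "acc_ugL"] = out.loc[need, "analyte_id"].map(mw) * out.loc[need, "acc_uM"]
    if out["acc_ugL"].isna().any() or (out["acc_ugL"] <= 0).any():
        bad = out.loc[out["acc_ugL"].isna() | (out["acc_ugL"] <= 0), "analyte_id"].unique()
        raise ValueError(f"non-positive or underivable acc_ugL for {sorted(bad)[:5]}")
    return out


def compute_ear(detections: pd.DataFrame, acc_filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-(detection, endpoint) exposure–activity ratios.

    ``acc_filtered`` must already have passed :func:`filter_endpoints`
    and carry ``acc_ugL``.  Non-organic and non-detected rows are
    excluded.  Returns ``sample_id, analyte_id, endpoint_id,
    concentration, acc_ugL, ear``.
    """
    det = detections
    if "detected" in det.columns:
        det = det.loc[det["detected"]]
    if "analyte_class" in det.columns:
        det = det.loc[det["analyte_class"].isin(ORGANIC_CLASSES)]
    merged = det.merge(
        acc_filtered[["analyte_id", "endpoint_id", "acc_ugL"]], on="analyte_id", how="inner")
    merged["ear"] = merged["concentration"] / merged["acc_ugL"]
    cols = ["sample_id", "analyte_id", "endpoint_id", "concentration", "acc_ugL", "ear"]
    return merged[cols].reset_index(drop=True)


def chemical_ear(ear_per_endpoint: pd.DataFrame) -> pd.DataFrame:
    """Max-endpoint chemical-level EAR per (sample, analyte)."""
    if ear_per_endpoint.empty:
        return pd.DataFrame(columns=["sample_id", "analyte_id", "ear"])
    out = (ear_per_endpoint.groupby(["sample_id", "analyte_id"], as_index=False)["ear"].max())
    return out


def summarize_sample_ear(
    ear_per_endpoint: pd.DataFrame,
    samples: pd.DataFrame,
    aggregation: str = "max_endpoint",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample ∑EAR summary and driver contributions.

    Under ``max_endpoint`` (default) each chemical contributes its
    maximum endpoint EAR; under ``per_endpoint`` the per-sample total is
    the maximum over endpoints of the within-endpoint chemical sum, and
    contributions are reported for the maximizing endpoint.

    Returns ``(summary, contributions)``; summary has one row per sample
    with ``sum_ear, exceeds_0p001, exceeds_1p0``.
    """
    from .benchmarks import _summarize_quotients

    if aggregation == "max_endpoint":
        chem = chemical_ear(ear_per_endpoint)
    elif aggregation == "per_endpoint":
        if ear_per_endpoint.empty:
            chem = pd.DataFrame(columns=["sample_id", "analyte_id", "ear"])
        else:
            by_ep = ear_per_endpoint.groupby(["sample_id", "endpoint_id"])["ear"].sum()
            best_ep = by_ep.groupby("sample_id").idxmax()
            pairs = set(best_ep)
            mask = list(zip(ear_per_endpoint["sample_id"], ear_per_endpoint["endpoint_id"]))
            chem = ear_per_endpoint.loc[[m in pairs for m in mask],
                                        ["sample_id", "analyte_id", "ear"]]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    chem = chem.copy()
    chem["included"] = chem["ear"] >= EAR_INCLUSION_MIN
    return _summarize_quotients(
        chem, samples, "ear", "sum_ear", (EAR_SCREENING_LEVEL, EAR_ELEVATED_LEVEL))


def ear_coverage(detections: pd.DataFrame, acc_filtered: pd.DataFrame) -> pd.DataFrame:
    """Detected organic analytes with vs without retained ACC endpoints."""
    det = detections.loc[detections["detected"]] if "detected" in detections.columns else detections
    det = det.loc[det["analyte_class"].isin(ORGANIC_CLASSES)]
    have = set(acc_filtered["analyte_id"])
    per = det.groupby("analyte_id").size().reset_index(name="n_detections")
    per["has_acc"] = per["analyte_id"].isin(have)
    return per
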