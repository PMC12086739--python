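"""Apical human-health benchmark screening: TQ and per-sample ∑TQ.

For each detected analyte the most protective (lowest-concentration)
human-health drinking-water benchmark is selected from the available
candidates (MCLG, MCL, SOQ, DWHA, WHO guideline, state level, HBSL,
HHBP).  Maximum-contaminant-level goals of zero — set for contaminants
with no safe dose, e.g. arsenic, lead, uranium, several disinfection
byproducts and volatile organics, and PFOS/PFOA — cannot serve as a
quotient denominator and are replaced by configurable substitution
values: 0.1 μg/L for metals, DBP and VOC classes, 0.0001 μg/L for
PFOS/PFOA.

The toxicity quotient TQ = concentration / effective benchmark is summed
per sample under the non-interactive concentration-addition mixture
model to give the hazard-index-style cumulative ∑TQ.  Detections with
TQ below 1e-5 are screened out of the assessment; ∑TQ is compared with
the 0.1 screening level of concern and the elevated-risk level of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import Dataset, ValidationError

BENCHMARK_TYPES = ("MCLG", "MCL", "SOQ", "DWHA", "WHO", "STATE", "HBSL", "HHBP")

#: deterministic tie-break when two candidate benchmarks share the minimum value
TYPE_PRIORITY = {t: i for i, t in enumerate(
    ("MCLG", "MCL", "SOQ", "DWHA", "WHO", "STATE", "HBSL", "HHBP"))}

TQ_INCLUSION_MIN = 1e-5   # per-detection assessment-inclusion screen (TQ >= 1e-5)
SCREENING_LEVEL = 0.1     # ∑TQ screening level of concern (strict >)
ELEVATED_LEVEL = 1.0      # ∑TQ elevated-risk level (strict >)


class ConfigurationError(ValueError):
    """A zero MCLG was selected but no substitution value is configured."""


@dataclass(frozen=True)
class SubstitutionRules:
    """Replacement denominators for zero-valued MCLGs.

    Looked up per analyte first, then per analyte class.  Defaults follow
    the harmonization convention: 0.1 μg/L for the inorganic (geogenic
    metals), DBP and VOC classes; per-analyte overrides (e.g. PFOS and
    PFOA at 0.0001 μg/L) are supplied by configuration.
    """

    by_class: Mapping[str, float] = field(
        default_factory=lambda: {"inorganic": 0.1, "DBP": 0.1, "VOC": 0.1})
    by_analyte: Mapping[str, float] = field(default_factory=dict)

    def lookup(self, analyte_id: str, analyte_class: str | None) -> float | None:
        if analyte_id in self.by_analyte:
            return float(self.by_analyte[analyte_id])
        if analyte_class is not None and analyte_class in self.by_class:
            return float(self.by_class[analyte_class])
        return None

    @classmethod
    def from_dict(cls, d: Mapping) -> "SubstitutionRules":
        return cls(by_class=dict(d.get("by_class", {})), by_analyte=dict(d.get("by_analyte", {})))

    @classmethod
    def from_yaml(cls, path) -> "SubstitutionRules":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump({"by_class": dict(self.by_class),
                            "by_analyte": dict(self.by_analyte)}, fh)


@dataclass(frozen=True)
class ResolvedBenchmark:
    """Effective positive TQ denominator for one analyte."""

    analyte_id: str
    effective_value: float  # μg/L, > 0
    source_type: str
    substitution_applied: bool

    def __post_init__(self) -> None:
        if not self.effective_value > 0:
            raise ValidationError(
                f"{self.analyte_id}: effective benchmark must be positive, "
                f"got {self.effective_value}")


def resolve_benchmark(
    analyte_id: str,
    candidates: pd.DataFrame,
    substitution_rules: SubstitutionRules,
    analyte_class: str | None = None,
) -> ResolvedBenchmark:
    """Select the most protective benchmark and apply zero-MCLG substitution.

    ``candidates`` holds columns ``benchmark_type`` and ``value`` (μg/L)
    for this analyte.  The minimum-valued candidate wins; equal minima
    break by fixed type priority.  If the winner is an MCLG of zero, the
    configured substitution value becomes the effective denominator.
    """
    cand = candidates.loc[candidates["analyte_id"] == analyte_id] \
        if "analyte_id" in candidates.columns else candidates
    if cand.empty:
        raise ValueError(f"{analyte_id}: no benchmark candidates (exclude from ∑TQ)")
    bad = cand.loc[(cand["value"] < 0) | ((cand["value"] == 0) & (cand["benchmark_type"] != "MCLG"))]
    if not bad.empty:
        raise ValidationError(
            f"{analyte_id}: zero/negative benchmark value only permitted for MCLG")
    ranked = cand.assign(_prio=cand["benchmark_type"].map(TYPE_PRIORITY)) \
        .sort_values(["value", "_prio"], kind="mergesort")
    top = ranked.iloc[0]
    if top["value"] == 0.0:
        sub = substitution_rules.lookup(analyte_id, analyte_class)
        if sub is None:
            raise ConfigurationError(
                f"{analyte_id}: MCLG of zero selected but no substitution value configured")
        return ResolvedBenchmark(analyte_id, float(sub), str(top["benchmark_type"]), True)
    return ResolvedBenchmark(analyte_id, float(top["value"]), str(top["benchmark_type"]), False)


def resolve_benchmarks(
    benchmarks: pd.DataFrame,
    substitution_rules: SubstitutionRules,
    catalog: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Resolve every analyte present in the benchmark table.

    Returns columns ``analyte_id, effective_value, source_type,
    substitution_applied``.  ``catalog`` (analyte_id → analyte_class) is
    used for class-keyed substitution rules.
    """
    classes: dict[str, str] = {}
    if catalog is not None:
        classes = dict(zip(catalog["analyte_id"], catalog["analyte_class"]))
    rows = []
    for aid, grp in benchmarks.groupby("analyte_id", sort=True):
        rb = resolve_benchmark(aid, grp, substitution_rules, classes.get(aid))
        rows.append((rb.analyte_id, rb.effective_value, rb.source_type, rb.substitution_applied))
    return pd.DataFrame(
        rows, columns=["analyte_id", "effective_value", "source_type", "substitution_applied"])


def compute_tq(detections: pd.DataFrame, resolved: pd.DataFrame) -> pd.DataFrame:
    """Per-detection toxicity quotients.

    ``detections`` must contain detected rows only (or carries a
    ``detected`` column used to filter).  Analytes without a resolved
    benchmark are dropped here and accounted for by
    :func:`benchmark_coverage`.  Microbial indicator rows never enter.

    Returns ``sample_id, analyte_id, concentration, effective_value, tq,
    included`` with ``included = (tq >= 1e-5)``.
    """
    det = detections
    if "detected" in det.columns:
        det = det.loc[det["detected"]]
    if "analyte_class" in det.columns:
        det = det.loc[det["analyte_class"] != "microbial"]
    merged = det.merge(resolved[["analyte_id", "effective_value"]], on="analyte_id", how="inner")
    merged["tq"] = merged["concentration"] / merged["effective_value"]
    merged["included"] = merged["tq"] >= TQ_INCLUSION_MIN
    cols = ["sample_id", "analyte_id", "concentration", "effective_value", "tq", "included"]
    return merged[cols].reset_index(drop=True)


def _summarize_quotients(
    q: pd.DataFrame,
    samples: pd.DataFrame,
    value_col: str,
    sum_col: str,
    thresholds: tuple[float, float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared per-sample concentration-addition roll-up for TQ/EAR-style quotients."""
    lo, hi = thresholds
    inc = q.loc[q["included"]] if "included" in q.columns else q
    sums = inc.groupby("sample_id")[value_col].sum()
    over1 = q.loc[q[value_col] > 1].groupby("sample_id")[value_col].count() \
        if len(q) else pd.Series(dtype=int)
    out = samples[["sample_id", "supply_class"]].copy()
    out[sum_col] = out["sample_id"].map(sums).fillna(0.0)
    out[f"n_{value_col}_over_1"] = out["sample_id"].map(over1).fillna(0).astype(int)
    out[f"exceeds_{_slug(lo)}"] = out[sum_col] > lo
    out[f"exceeds_{_slug(hi)}"] = out[sum_col] > hi

    contrib = inc.merge(out[["sample_id", sum_col]], on="sample_id")
    contrib = contrib.loc[contrib[sum_col] > 0].copy()
    contrib["contribution_fraction"] = contrib[value_col] / contrib[sum_col]
    contrib = contrib.sort_values(
        ["sample_id", "contribution_fraction"], ascending=[True, False], kind="mergesort")
    contrib["rank"] = contrib.groupby("sample_id").cumcount() + 1
    contrib_cols = ["sample_id", "analyte_id", value_col, "contribution_fraction", "rank"]
    return out.reset_index(drop=True), contrib[contrib_cols].reset_index(drop=True)


def _slug(x: float) -> str:
    return str(x).replace(".", "p").replace("0p", "0p")


def summarize_sample_tq(
    tq: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample ∑TQ summary plus the driver-ranking contribution table.

    Returns ``(summary, contributions)``:

    * summary — one row per sample (including detection-free samples with
      ∑TQ = 0): ``sample_id, supply_class, sum_tq, n_tq_over_1,
      exceeds_0p1, exceeds_1p0``.
    * contributions — long table of included detections with their
      contribution fraction tqᵢ/∑TQ, ranked descending within sample.
    """
    return _summarize_quotients(tq, samples, "tq", "sum_tq", (SCREENING_LEVEL, ELEVATED_LEVEL))


def individual_exceedance_table(ds: Dataset, regulatory: pd.DataFrame) -> pd.DataFrame:
    """Compare each detection against enforceable/regulatory levels.

    One row per (detection, applicable benchmark record); ``exceeds`` is
    a strict comparison ``concentration > value``, except that a zero
    MCLG is exceeded by any detection at all.
    """
    det = ds.detected_only()
    det = det.loc[det["analyte_class"] != "microbial"]
    merged = det.merge(
        regulatory[["analyte_id", "benchmark_type", "value"]], on="analyte_id", how="inner")
    merged["exceeds"] = np.where(
        merged["value"] == 0, True, merged["concentration"] > merged["value"])
    cols = ["sample_id", "analyte_id", "concentration", "benchmark_type", "value", "exceeds"]
    return merged[cols].reset_index(drop=True)


def benchmark_coverage(ds: Dataset, resolved: pd.DataFrame) -> pd.DataFrame:
    """Per analyte-class coverage: detected analytes vs those with a usable benchmark."""
    det = ds.detected_only()
    det = det.loc[det["analyte_class"] != "microbial"]
    have = set(resolved["analyte_id"])
    per = det.groupby(["analyte_class", "analyte_id"]).size().reset_index(name="n_detections")
    per["has_benchmark"] = per["analyte_id"].isin(have)
    cov = per.groupby("analyte_class").agg(
        n_detected_analytes=("analyte_id", "nunique"),
        n_with_benchmark=("has_benchmark", "sum"),
    ).reset_index()
    cov["fraction_with_benchmark"] = np.where(
        cov["n_detected_analytes"] > 0,
        cov["n_with_benchmark"] / cov["n_detected_analytes"], 0.0)
    return cov
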