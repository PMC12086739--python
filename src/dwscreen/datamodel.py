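"""Shared data model and table I/O for drinking-water exposure screening.

The central in-memory containers are pandas DataFrames with documented
column contracts, wrapped where useful by light dataclasses:

* detections — one row per (sample, analyte) measurement, detected or not.
  A non-detect is carried as a row with ``detected == False`` and an absent
  concentration; it contributes zero to every cumulative sum but is counted
  in coverage reporting.
* catalog — the analyte dictionary: identity, class, core-analyte flag and
  molecular weight.
* samples — one row per water sample with its supply class
  (private tapwater, public-supply tapwater, or bottled water).

Concentrations are μg/L throughout (CFU/100 mL for microbial indicator
rows, which are carried descriptively and never screened).  ng/L input is
converted on read via the per-file ``units`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SUPPLY_CLASSES = ("private_tw", "public_tw", "bottled")

ANALYTE_CLASSES = (
    "inorganic",
    "DBP",
    "VOC",
    "PFAS",
    "pesticide",
    "pharmaceutical",
    "other_organic",
    "microbial",
)

#: analyte classes eligible for bioactivity (EAR) screening
ORGANIC_CLASSES = ("DBP", "VOC", "PFAS", "pesticide", "pharmaceutical", "other_organic")

DETECTION_COLUMNS = [
    "study_id",
    "sample_id",
    "supply_class",
    "analyte_id",
    "analyte_name",
    "analyte_class",
    "concentration",
    "reporting_limit",
    "detected",
]

CATALOG_COLUMNS = ["analyte_id", "analyte_name", "analyte_class", "core_flag", "molecular_weight"]


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class FormatError(ValueError):
    """Input file is missing a required column or is otherwise malformed."""


@dataclass(frozen=True)
class AnalyteCatalog:
    """Analyte dictionary keyed by ``analyte_id`` (CAS number or stable slug).

    ``table`` holds one row per analyte with columns
    ``analyte_id, analyte_name, analyte_class, core_flag, molecular_weight``;
    molecular weight (g/mol) may be NaN when unknown.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in CATALOG_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"catalog missing required column(s): {missing}")
        if t["analyte_id"].duplicated().any():
            dupes = sorted(t.loc[t["analyte_id"].duplicated(), "analyte_id"])
            raise ValidationError(f"duplicate analyte_id in catalog: {dupes}")
        bad_class = set(t["analyte_class"]) - set(ANALYTE_CLASSES)
        if bad_class:
            raise ValidationError(f"unknown analyte_class values: {sorted(bad_class)}")
        mw = t["molecular_weight"]
        if ((mw <= 0) & mw.notna()).any():
            raise ValidationError("molecular_weight must be > 0 where present")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def ids(self) -> set[str]:
        return set(self.table["analyte_id"])

    def is_core(self, analyte_id: str) -> bool:
        row = self.table.loc[self.table["analyte_id"] == analyte_id]
        if row.empty:
            raise KeyError(analyte_id)
        return bool(row["core_flag"].iloc[0])

    def molecular_weight(self, analyte_id: str) -> float:
        row = self.table.loc[self.table["analyte_id"] == analyte_id]
        if row.empty:
            raise KeyError(analyte_id)
        return float(row["molecular_weight"].iloc[0])

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnalyteCatalog":
        df = pd.read_csv(path, dtype={"analyte_id": str})
        if "core_flag" in df.columns:
            df["core_flag"] = df["core_flag"].astype(bool)
        if "molecular_weight" not in df.columns:
            df["molecular_weight"] = np.nan
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        write_table(self.table[CATALOG_COLUMNS], path)


@dataclass
class Dataset:
    """A harmonized exposure dataset: detections + catalog + sample roster."""

    detections: pd.DataFrame
    catalog: AnalyteCatalog
    samples: pd.DataFrame  # sample_id, supply_class, study_id

    def __post_init__(self) -> None:
        validate_detections(self.detections, self.catalog)
        s = self.samples
        for col in ("sample_id", "supply_class", "study_id"):
            if col not in s.columns:
                raise FormatError(f"samples table missing column {col!r}")
        if s["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in samples table")
        unknown = set(self.detections["sample_id"]) - set(s["sample_id"])
        if unknown:
            raise ValidationError(f"detections reference unknown sample_id(s): {sorted(unknown)[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def detected_only(self) -> pd.DataFrame:
        """Rows with a quantified concentration (the numerators of TQ/EAR)."""
        return self.detections.loc[self.detections["detected"]].copy()

    def equals(self, other: "Dataset") -> bool:
        a = self.detections.sort_values(["sample_id", "analyte_id"]).reset_index(drop=True)
        b = other.detections.sort_values(["sample_id", "analyte_id"]).reset_index(drop=True)
        sa = self.samples.sort_values("sample_id").reset_index(drop=True)
        sb = other.samples.sort_values("sample_id").reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a[DETECTION_COLUMNS], b[DETECTION_COLUMNS], check_dtype=False)
            pd.testing.assert_frame_equal(sa, sb, check_dtype=False)
            pd.testing.assert_frame_equal(
                self.catalog.table, other.catalog.table, check_dtype=False
            )
        except AssertionError:
            return False
        return True


def validate_detections(df: pd.DataFrame, catalog: AnalyteCatalog | None = None) -> None:
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"detections missing required column(s): {missing}")
    bad_supply = set(df["supply_class"]) - set(SUPPLY_CLASSES)
    if bad_supply:
        raise ValidationError(f"unknown supply_class values: {sorted(bad_supply)}")
    conc = df["concentration"]
    neg = df.index[(conc < 0) & conc.notna()]
    if len(neg):
        raise ValidationError(f"negative concentration at row(s) {list(neg[:5])}")
    rl = df["reporting_limit"]
    if (rl <= 0).any() or rl.isna().any():
        bad = df.index[(rl <= 0) | rl.isna()]
        raise ValidationError(f"reporting_limit must be > 0; bad row(s) {list(bad[:5])}")
    det = df["detected"]
    if det.isna().any():
        raise ValidationError("detected flag must be boolean, not missing")
    if (df.loc[det.astype(bool), "concentration"].isna()).any():
        raise ValidationError("detected rows must carry a concentration")
    if catalog is not None:
        unknown = set(df["analyte_id"]) - catalog.ids
        if unknown:
            raise ValidationError(
                f"detections reference analyte_id(s) absent from catalog: {sorted(unknown)}"
            )


def read_detections(path: str | Path, catalog: AnalyteCatalog) -> Dataset:
    """Read a long-format detections CSV into a :class:`Dataset`.

    Expected columns: ``study_id, sample_id, supply_class, analyte_id,
    analyte_name, analyte_class, concentration, units, reporting_limit,
    detected``.  ``units`` may be ``ug/L`` or ``ng/L``; ng/L values
    (concentration and reporting limit) are converted to μg/L on read.
    Rows whose ``analyte_id`` is not in the catalog are rejected with a
    collected error report.
    """
    df = pd.read_csv(path, dtype={"analyte_id": str, "sample_id": str, "study_id": str})
    required = [c for c in DETECTION_COLUMNS if c != "detected"] + ["detected"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    df["detected"] = df["detected"].astype(bool)
    if "units" in df.columns:
        units = df["units"].fillna("ug/L")
        unknown_units = set(units) - {"ug/L", "ng/L"}
        if unknown_units:
            raise FormatError(f"{path}: unsupported units {sorted(unknown_units)}")
        ng = units == "ng/L"
        df.loc[ng, "concentration"] = df.loc[ng, "concentration"] / 1000.0
        df.loc[ng, "reporting_limit"] = df.loc[ng, "reporting_limit"] / 1000.0
        df = df.drop(columns=["units"])
    unknown = sorted(set(df["analyte_id"]) - catalog.ids)
    if unknown:
        raise ValidationError(
            f"{path}: {len(unknown)} analyte_id(s) not in catalog: {unknown[:10]}"
        )
    validate_detections(df, catalog)
    samples = (
        df[["sample_id", "supply_class", "study_id"]]
        .drop_duplicates("sample_id")
        .reset_index(drop=True)
    )
    return Dataset(detections=df[DETECTION_COLUMNS].copy(), catalog=catalog, samples=samples)


def write_detections(ds: Dataset, path: str | Path) -> None:
    out = ds.detections.copy()
    out.insert(out.columns.get_loc("concentration") + 1, "units", "ug/L")
    write_table(out, path)


def constrain_to_core(ds: Dataset) -> Dataset:
    """Restrict detections to core analytes shared across all studies.

    The sample roster is unchanged: samples whose detections are all
    non-core remain in the dataset with zero detections, so per-sample
    sums for them are zero rather than missing.  Idempotent.
    """
    core = ds.catalog.table.loc[ds.catalog.table["core_flag"], "analyte_id"]
    kept = ds.detections.loc[ds.detections["analyte_id"].isin(set(core))].reset_index(drop=True)
    return Dataset(detections=kept, catalog=ds.catalog, samples=ds.samples.copy())


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as CSV with stable column order, full float precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, **kwargs)


def read_benchmarks(path: str | Path) -> pd.DataFrame:
    """Read ``benchmarks.csv``: analyte_id, benchmark_type, value, units, enforceable."""
    df = pd.read_csv(path, dtype={"analyte_id": str})
    for col in ("analyte_id", "benchmark_type", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if "enforceable" not in df.columns:
        df["enforceable"] = False
    return df


def read_acc(path: str | Path) -> pd.DataFrame:
    """Read ``acc.csv``: analyte_id, endpoint_id, acc_uM, acc_ugL and flag columns."""
    df = pd.read_csv(path, dtype={"analyte_id": str, "endpoint_id": str})
    for col in ("analyte_id", "endpoint_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if "acc_uM" not in df.columns and "acc_ugL" not in df.columns:
        raise FormatError(f"{path}: need at least one of acc_uM, acc_ugL")
    for flag in ("flag_nonspecific", "flag_baseline", "flag_unreliable"):
        if flag not in df.columns:
            df[flag] = False
        df[flag] = df[flag].astype(bool)
    return df


def read_tk_params(path: str | Path) -> pd.DataFrame:
    """Read ``tk_params.csv``: analyte_id, molecular_weight, fraction_unbound, intrinsic_clearance."""
    df = pd.read_csv(path, dtype={"analyte_id": str})
    for col in ("analyte_id", "molecular_weight", "fraction_unbound", "intrinsic_clearance"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df
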