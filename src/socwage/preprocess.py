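"""Raw survey microdata -> cleaned master modelling table.

The master table behind the wage models is built from raw wage records by
applying, in order: a complete-case restriction on the modelling variables
(wage, age, sex, occupation), the working-age filter (16-65 for men, 16-60
for women, bounds inclusive), an employment filter (people out of work
carry no occupation code), price standardisation of wages to a reference
year with a consumer price index, a deterministic skewness-guided outlier
trim, and a log transform.  Counts of rows dropped at each stage are kept
so that the accounting invariant (drops + retained == input) always holds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .soc import ClassificationTable, MalformedCodeError, Tier, parse_code

__all__ = [
    "CPITable",
    "TrimPolicy",
    "MasterDataset",
    "ColumnMap",
    "UnknownYearError",
    "DegenerateDistributionError",
    "EmptyResultError",
    "standardise_wage",
    "working_age_filter",
    "employment_filter",
    "trim_outliers",
    "build_master",
    "split_by_year",
]

# Working-age bounds (inclusive) used throughout: pension-age earnings
# cannot be predicted from occupation, so older workers are excluded.
AGE_BOUNDS = {"male": (16, 65), "female": (16, 60)}


class UnknownYearError(KeyError):
    """Raised when a survey year is absent from the CPI table."""


class DegenerateDistributionError(ValueError):
    """Raised when outlier trimming would leave fewer than 10 wages."""


class EmptyResultError(ValueError):
    """Raised when every input record is filtered out."""


@dataclass(frozen=True)
class CPITable:
    """Annual consumer price index used to deflate wages to reference-year prices."""

    index: Mapping[int, float]
    reference_year: int

    def __post_init__(self) -> None:
        if self.reference_year not in self.index:
            raise ValueError(
                f"reference year {self.reference_year} missing from CPI table"
            )
        for year, value in self.index.items():
            if not value > 0:
                raise ValueError(f"CPI index for {year} must be positive, got {value}")

    @classmethod
    def from_file(cls, path: str | Path, reference_year: int,
                  sep: str = ",") -> "CPITable":
        """Read a two-column (year, index) delimited file with a header row."""
        with open(path, encoding="utf-8") as fh:
            lines = [ln.strip() for ln in fh
                     if ln.strip() and not ln.startswith("#")]
        mapping = {}
        for ln in lines[1:]:
            year_s, value_s = ln.split(sep)[:2]
            mapping[int(year_s)] = float(value_s)
        return cls(index=mapping, reference_year=reference_year)

    def to_file(self, path: str | Path, sep: str = ",") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"year{sep}index\n")
            for year in sorted(self.index):
                fh.write(f"{year}{sep}{self.index[year]!r}\n")


def standardise_wage(wage: float, year: int, cpi: CPITable) -> float:
    """Rescale a wage observed in ``year`` to reference-year price levels.

    Multiplicative CPI deflation: wage * index(reference) / index(year).
    """
    if year not in cpi.index:
        raise UnknownYearError(f"year {year} not in CPI table")
    return wage * cpi.index[cpi.reference_year] / cpi.index[year]


def working_age_filter(age: int, sex: str) -> bool:
    """True iff the person is of working age: 16-65 (men), 16-60 (women)."""
    lo, hi = AGE_BOUNDS[sex]
    return lo <= age <= hi


def employment_filter(employed_last_week) -> bool:
    """True iff employed in the week before the survey; missing counts as not."""
    if employed_last_week is None or (isinstance(employed_last_week, float)
                                      and np.isnan(employed_last_week)):
        return False
    return bool(employed_last_week)


@dataclass(frozen=True)
class TrimPolicy:
    """Deterministic two-stage outlier rule for the wage distribution.

    Stage 1 drops wages outside the [lower_q, upper_q] empirical quantiles.
    Stage 2: if the sample skewness of the retained log wages still exceeds
    ``skew_threshold`` in absolute value, the most extreme remaining value
    (largest |log wage - median log wage|, median recomputed after each
    removal) is removed iteratively, capped at ``max_extra_frac`` of the
    rows that survived stage 1.
    """

    lower_q: float = 0.001
    upper_q: float = 0.999
    skew_threshold: float = 1.0
    max_extra_frac: float = 0.01


def trim_outliers(wages, policy: TrimPolicy = TrimPolicy()) -> np.ndarray:
    """Return a deterministic boolean keep-mask over ``wages``."""
    w = np.asarray(wages, dtype=float)
    if w.size == 0:
        raise ValueError("empty wage vector")
    if np.any(w <= 0):
        raise ValueError("wages must be strictly positive")
    lo, hi = np.quantile(w, [policy.lower_q, policy.upper_q])
    mask = (w >= lo) & (w <= hi)
    logw = np.log(w)
    cap = int(np.floor(policy.max_extra_frac * mask.sum()))
    removed = 0
    while removed < cap and mask.sum() > 1:
        kept = logw[mask]
        if abs(stats.skew(kept)) <= policy.skew_threshold:
            break
        med = np.median(kept)
        dev = np.where(mask, np.abs(logw - med), -np.inf)
        mask[int(np.argmax(dev))] = False
        removed += 1
    if mask.sum() < 10:
        raise DegenerateDistributionError(
            f"fewer than 10 wages remain after trimming ({int(mask.sum())})"
        )
    return mask


@dataclass(frozen=True)
class ColumnMap:
    """Names of the raw-input columns holding each modelling variable."""

    person_id: str = "person_id"
    age: str = "age"
    sex: str = "sex"
    soc: str = "soc"
    wage: str = "wage"
    year: str = "year"
    employed: str = "employed"


#: Modelling columns of a master table.
MASTER_COLUMNS = ["person_id", "age", "sex", "male", "minor_code", "unit_code",
                  "minor_id", "unit_id", "wage", "log_wage", "year"]


@dataclass
class MasterDataset:
    """Cleaned modelling table plus provenance counts of dropped rows.

    ``frame`` holds one row per retained worker with columns
    age, sex, male (0/1 indicator), minor_code/unit_code (occupation),
    dense minor_id/unit_id, wage (reference-year GBP/week) and log_wage.
    """

    frame: pd.DataFrame
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_modelling_frame(cls, df: pd.DataFrame,
                             drop_counts: dict[str, int] | None = None
                             ) -> "MasterDataset":
        """Build from a frame with age, sex, unit_code and log_wage columns.

        Used by tests and callers that already hold clean modelling data;
        derives male indicator, minor codes, dense group ids and wage.
        """
        df = df.copy()
        if "male" not in df:
            df["male"] = (df["sex"].astype(str).str.strip().str.lower()
                          == "male").astype(np.int8)
        if "sex" not in df:
            df["sex"] = np.where(df["male"] == 1, "male", "female")
        df["unit_code"] = df["unit_code"].astype(str)
        if "minor_code" not in df:
            df["minor_code"] = df["unit_code"].str[:3]
        if "wage" not in df:
            df["wage"] = np.exp(df["log_wage"].astype(float))
        table = ClassificationTable.from_codes(df["unit_code"].unique())
        gi = table.group_index()
        df["minor_id"] = [gi[u][0] for u in df["unit_code"]]
        df["unit_id"] = [gi[u][1] for u in df["unit_code"]]
        if "person_id" not in df:
            df["person_id"] = [f"R{i:07d}" for i in range(len(df))]
        if "year" not in df:
            df["year"] = -1
        return cls(frame=df.reset_index(drop=True),
                   drop_counts=dict(drop_counts or {}))

    def to_files(self, csv_path: str | Path, sidecar_path: str | Path | None = None,
                 header_lines: list[str] | None = None) -> None:
        with open(csv_path, "w", encoding="utf-8") as fh:
            for ln in header_lines or []:
                fh.write(ln if ln.endswith("\n") else ln + "\n")
            self.frame.to_csv(fh, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w", encoding="utf-8") as fh:
                json.dump({"drop_counts": self.drop_counts, "n": len(self)},
                          fh, indent=2)
                fh.write("\n")

    @classmethod
    def from_files(cls, csv_path: str | Path,
                   sidecar_path: str | Path | None = None) -> "MasterDataset":
        frame = pd.read_csv(csv_path, comment="#",
                            dtype={"minor_code": str, "unit_code": str})
        drops: dict[str, int] = {}
        if sidecar_path is not None and Path(sidecar_path).exists():
            with open(sidecar_path, encoding="utf-8") as fh:
                drops = json.load(fh).get("drop_counts", {})
        return cls(frame=frame, drop_counts=drops)


def _normalise_sex(series: pd.Series) -> pd.Series:
    s = series.astype("string").str.strip().str.lower()
    return s.where(s.isin(["male", "female"]))


def build_master(records: pd.DataFrame, cpi: CPITable,
                 table: ClassificationTable | None = None,
                 policy: TrimPolicy = TrimPolicy(),
                 columns: ColumnMap = ColumnMap()) -> MasterDataset:
    """Apply the full cleaning pipeline to raw wage records.

    Stage order: complete-case drop -> working-age filter -> employment
    filter -> CPI standardisation -> outlier trim -> log transform ->
    group-index join.  If ``table`` is None the classification is derived
    from the unit codes present in the data.
    """
    for col in [columns.age, columns.sex, columns.soc, columns.wage,
                columns.year]:
        if col not in records.columns:
            raise KeyError(f"missing required column: {col!r}")

    df = pd.DataFrame({
        "person_id": (records[columns.person_id].astype(str)
                      if columns.person_id in records
                      else [f"R{i:07d}" for i in range(len(records))]),
        "age": pd.to_numeric(records[columns.age], errors="coerce"),
        "sex": _normalise_sex(records[columns.sex]),
        "soc_raw": records[columns.soc],
        "wage_raw": pd.to_numeric(records[columns.wage], errors="coerce"),
        "year": pd.to_numeric(records[columns.year], errors="coerce"),
        "employed": (records[columns.employed]
                     if columns.employed in records else True),
    })
    n_input = len(df)
    drops: dict[str, int] = {}

    # Complete-case restriction on the modelling variables.  Unparseable
    # occupation strings and non-positive wages are treated as missing.
    def _parse_unit(raw):
        try:
            return parse_code(raw).code
        except MalformedCodeError:
            return None

    soc = df["soc_raw"].map(lambda r: None if pd.isna(r) else _parse_unit(r))
    complete = (df["age"].notna() & df["sex"].notna() & soc.notna()
                & df["wage_raw"].notna() & (df["wage_raw"] > 0)
                & df["year"].notna())
    drops["missing"] = int((~complete).sum())
    df = df[complete].assign(soc=soc[complete])

    # The master model needs unit-tier (4-digit) codes.
    is_unit = df["soc"].str.len() == 4
    drops["non_unit_soc"] = int((~is_unit).sum())
    df = df[is_unit]

    keep = [working_age_filter(int(a), s)
            for a, s in zip(df["age"], df["sex"])]
    keep = np.asarray(keep, dtype=bool)
    drops["working_age"] = int((~keep).sum())
    df = df[keep]

    keep = np.asarray([employment_filter(e) for e in df["employed"]], dtype=bool)
    drops["not_employed"] = int((~keep).sum())
    df = df[keep]

    if table is not None:
        known = df["soc"].isin(set(table.unit_codes))
        drops["unknown_soc"] = int((~known).sum())
        df = df[known]

    if df.empty:
        raise EmptyResultError("no records survive filtering")

    std_wage = np.array([standardise_wage(w, int(y), cpi)
                         for w, y in zip(df["wage_raw"], df["year"])])
    keep = trim_outliers(std_wage, policy)
    drops["outlier"] = int((~keep).sum())
    df = df[keep]
    std_wage = std_wage[keep]

    if table is None:
        table = ClassificationTable.from_codes(df["soc"].unique())
    gi = table.group_index()
    out = pd.DataFrame({
        "person_id": df["person_id"].to_numpy(),
        "age": df["age"].astype(int).to_numpy(),
        "sex": df["sex"].astype(str).to_numpy(),
        "male": (df["sex"] == "male").astype(np.int8).to_numpy(),
        "minor_code": [u[:3] for u in df["soc"]],
        "unit_code": df["soc"].astype(str).to_numpy(),
        "minor_id": [gi[u][0] for u in df["soc"]],
        "unit_id": [gi[u][1] for u in df["soc"]],
        "wage": std_wage,
        "log_wage": np.log(std_wage),
        "year": df["year"].astype(int).to_numpy(),
    })
    assert sum(drops.values()) + len(out) == n_input
    return MasterDataset(frame=out.reset_index(drop=True), drop_counts=drops)


def split_by_year(records: pd.DataFrame, holdout_year: int,
                  columns: ColumnMap = ColumnMap()
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split raw records into (training, holdout) by survey year.

    Mirrors the design in which one survey year is withheld from model
    fitting and used for internal validation.
    """
    year = pd.to_numeric(records[columns.year], errors="coerce")
    hold = year == holdout_year
    return records[~hold].copy(), records[hold].copy()
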