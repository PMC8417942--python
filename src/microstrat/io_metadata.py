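"""Input handling and cohort preparation.

Reads genus-level relative-abundance tables and per-sample host metadata
(country, study, age, sex, BMI), applies the cohort inclusion rules
(minimum per-country sample count, WHO BMI binning), produces dummy-coded
indicator matrices for enrichment analysis, and summarizes the cohort as a
per-country demographic table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

BMI_CATEGORIES = ["underweight", "normal", "overweight", "obese"]
SEX_LEVELS = ["Female", "Male"]
MISSING = "Missing"

#: WHO BMI cut points; intervals are half-open [lo, hi).
BMI_EDGES = [18.5, 25.0, 30.0]

METADATA_COLUMNS = ["sample_id", "country", "study_id", "age", "sex", "bmi"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class AbundanceTable:
    """Samples x taxa matrix of non-negative abundances.

    Rows are stool samples, columns genus-level taxa. Values may be raw
    counts or relative abundances; :func:`normalize_relative` converts to
    per-sample relative abundances.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        for name, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValidationError(f"duplicate {name} identifier: {i!r}")
                seen.add(i)
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative abundance at sample {self.sample_ids[r]!r}, "
                f"taxon {self.taxon_ids[c]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.taxon_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceTable":
        return cls(
            sample_ids=[str(s) for s in frame.index],
            taxon_ids=[str(t) for t in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def subset_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        """Restrict to the given samples, preserving the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample identifiers: {missing[:5]}")
        rows = [index[s] for s in sample_ids]
        return AbundanceTable(
            sample_ids=list(sample_ids),
            taxon_ids=list(self.taxon_ids),
            values=self.values[rows],
        )


def load_abundance(path) -> AbundanceTable:
    """Read a tab-separated abundance matrix.

    First row holds taxon names, first column sample identifiers. Values
    are kept as stored — raw counts are not rescaled here.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    table = AbundanceTable(
        sample_ids=[str(s) for s in frame.index],
        taxon_ids=[str(t) for t in frame.columns],
        values=frame.to_numpy(dtype=float),
    )
    return table


def write_abundance(table: AbundanceTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scale each sample so nonzero rows sum to 1.

    All-zero rows (a sample with no measured taxa) are left unchanged and
    reported via a warning; downstream distance computation rejects them.
    Idempotent on already-normalized tables.
    """
    totals = table.values.sum(axis=1)
    zero = totals == 0
    if np.any(zero):
        ids = [table.sample_ids[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"{len(ids)} all-zero sample row(s) left unnormalized: {ids[:5]}",
            stacklevel=2,
        )
    scaled = table.values.copy()
    nz = ~zero
    scaled[nz] = scaled[nz] / totals[nz, None]
    return AbundanceTable(
        sample_ids=list(table.sample_ids),
        taxon_ids=list(table.taxon_ids),
        values=scaled,
    )


def bin_bmi(bmi_value: float | None) -> str:
    """Map a BMI value (kg/m^2) to its WHO category.

    Half-open intervals: underweight [0, 18.5), normal [18.5, 25),
    overweight [25, 30), obese [30, inf). Missing input maps to "Missing".
    """
    if bmi_value is None or (isinstance(bmi_value, float) and np.isnan(bmi_value)):
        return MISSING
    value = float(bmi_value)
    if value <= 0:
        raise ValidationError(f"BMI must be positive, got {value}")
    if value < BMI_EDGES[0]:
        return "underweight"
    if value < BMI_EDGES[1]:
        return "normal"
    if value < BMI_EDGES[2]:
        return "overweight"
    return "obese"


def _clean_sex(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return MISSING
    text = str(value).strip().capitalize()
    if text in SEX_LEVELS:
        return text
    if text in ("", "Nan", "Na", "Missing", "None"):
        return MISSING
    raise ValidationError(f"unrecognized sex value: {value!r}")


def load_metadata(path) -> pd.DataFrame:
    """Read per-sample host metadata from a tab-separated file.

    Required columns: sample_id, country, study_id, age, sex, bmi.
    Returns a DataFrame indexed by sample_id with columns country,
    study_id, age (float, NaN when missing), sex (Female/Male/Missing),
    bmi_value (float, NaN when missing) and bmi_category derived via
    :func:`bin_bmi`.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValidationError(f"metadata file missing columns: {missing_cols}")
    if raw["sample_id"].duplicated().any():
        dup = raw.loc[raw["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample identifier: {dup!r}")
    meta = pd.DataFrame(
        {
            "country": raw["country"].astype(str).to_numpy(),
            "study_id": raw["study_id"].astype(str).to_numpy(),
            "age": pd.to_numeric(raw["age"], errors="coerce").to_numpy(),
            "sex": [_clean_sex(v) for v in raw["sex"]],
            "bmi_value": pd.to_numeric(raw["bmi"], errors="coerce").to_numpy(),
        },
        index=pd.Index(raw["sample_id"].to_numpy(), name="sample_id"),
    )
    if (meta["age"].dropna() < 0).any():
        raise ValidationError("negative age encountered")
    meta["bmi_category"] = [bin_bmi(v) for v in meta["bmi_value"]]
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.reset_index()[
        ["sample_id", "country", "study_id", "age", "sex", "bmi_value"]
    ].rename(columns={"bmi_value": "bmi"})
    out.to_csv(path, sep="\t", index=False)


def filter_countries(meta: pd.DataFrame, min_n: int = 20) -> pd.DataFrame:
    """Drop samples from countries represented by fewer than ``min_n`` samples.

    The boundary is inclusive: a country with exactly ``min_n`` samples is
    retained ("fewer than" is excluded).
    """
    if min_n < 1:
        raise ValidationError(f"min_n must be >= 1, got {min_n}")
    counts = meta["country"].value_counts()
    keep = counts[counts >= min_n].index
    out = meta[meta["country"].isin(keep)]
    if out.empty:
        raise ValidationError("no country passes filter")
    return out


def dummy_code(meta: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """One-hot indicator matrix over the observed non-missing levels.

    Columns are a (variable, level) MultiIndex. A sample with a missing
    value for a variable gets all-zero indicators for that variable, so it
    stays in the network but contributes no enrichment signal for it.
    """
    known = {"country": "country", "sex": "sex", "bmi_category": "bmi_category"}
    frames = {}
    for var in variables:
        if var not in known:
            raise ValidationError(f"unknown dummy variable: {var!r}")
        col = meta[known[var]].astype(str)
        levels = sorted(lv for lv in col.unique() if lv != MISSING)
        block = pd.DataFrame(
            {(var, lv): (col == lv).astype(int) for lv in levels}, index=meta.index
        )
        frames[var] = block
    if not frames:
        return pd.DataFrame(index=meta.index)
    out = pd.concat(frames.values(), axis=1)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["variable", "level"])
    return out


def _round1(x: float) -> float:
    return float(np.round(x, 1))


def cohort_summary(meta: pd.DataFrame) -> pd.DataFrame:
    """Per-country and pooled demographic summary.

    Rows: n, age mean/SD (1 decimal, computed over non-missing ages), sex
    level counts and BMI category counts (both including Missing).
    Columns: one per country plus a pooled "Total".
    """
    if meta.empty:
        raise ValidationError("metadata is empty")
    countries = sorted(meta["country"].unique())
    rows = (
        ["n", "age_mean", "age_sd"]
        + [f"sex_{lv}" for lv in SEX_LEVELS + [MISSING]]
        + [f"bmi_{cat}" for cat in BMI_CATEGORIES + [MISSING]]
    )
    out = pd.DataFrame(index=rows, columns=countries + ["Total"], dtype=float)
    groups = [(c, meta[meta["country"] == c]) for c in countries] + [("Total", meta)]
    for name, grp in groups:
        ages = grp["age"].dropna()
        out.loc["n", name] = len(grp)
        out.loc["age_mean", name] = _round1(ages.mean()) if len(ages) else np.nan
        out.loc["age_sd", name] = (
            _round1(ages.std(ddof=1)) if len(ages) > 1 else np.nan
        )
        for lv in SEX_LEVELS + [MISSING]:
            out.loc[f"sex_{lv}", name] = int((grp["sex"] == lv).sum())
        for cat in BMI_CATEGORIES + [MISSING]:
            out.loc[f"bmi_{cat}", name] = int((grp["bmi_category"] == cat).sum())
    return out


def pooled_mean_sd(
    n: np.ndarray, mean: np.ndarray, sd: np.ndarray
) -> tuple[float, float]:
    """Pool per-group (n, mean, sd ddof=1) summaries into overall mean and SD.

    Exact identity: the pooled sum of squares is the within-group part
    sum((n_i - 1) s_i^2) plus the between-group part sum(n_i (m_i - m)^2),
    divided by N - 1. Matches recomputing mean/std over the concatenated
    raw samples.
    """
    n = np.asarray(n, dtype=float)
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    total = n.sum()
    if total <= 1:
        raise ValidationError("pooling requires more than one observation")
    grand = float((n * mean).sum() / total)
    ss = float(((n - 1) * sd**2).sum() + (n * (mean - grand) ** 2).sum())
    return grand, float(np.sqrt(ss / (total - 1)))


def load_cohort_reference() -> pd.DataFrame:
    """Published per-country demographic summary of the GMrepo-derived
    healthy-adult cohort (12 countries), used as the arithmetic input for
    cohort-level aggregation checks."""
    with resources.files("microstrat.data").joinpath(
        "gmrepo_cohort_summary.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="country")


def aggregate_reference(ref: pd.DataFrame) -> dict[str, float]:
    """Aggregate a per-country summary table into pooled cohort totals.

    Returns the grand sample total, per-level sex and BMI totals, and the
    pooled age mean/SD (1 decimal) from the per-country (n, mean, sd)
    triples.
    """
    pooled_mean, pooled_sd = pooled_mean_sd(
        ref["n"].to_numpy(), ref["age_mean"].to_numpy(), ref["age_sd"].to_numpy()
    )
    out: dict[str, float] = {
        "total_samples": float(ref["n"].sum()),
        "age_mean_pooled": _round1(pooled_mean),
        "age_sd_pooled": _round1(pooled_sd),
    }
    for col in ref.columns:
        if col.startswith(("sex_", "bmi_")):
            out[f"total_{col}"] = float(ref[col].sum())
    return out
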