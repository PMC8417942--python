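"""Synthetic multi-country microbiome cohorts.

Emulates the statistical structure of curated population gut-microbiome
repositories assembled from many independent studies: strongly unbalanced
country groups, study-specific taxon panels (each study measures only a
subset of taxa, so off-panel taxa are structural zeros shared by all of
that study's samples), compositional abundances, and host metadata (age,
sex, BMI with missingness) drawn from per-country distributions.

Compositions are Dirichlet draws with a long-tailed per-taxon
concentration vector, which produces the sparse, few-dominant-genera rows
typical of genus tables. Planted country-taxon associations multiply the
concentration of the target taxon for samples of the target country before
drawing, so every draw remains a valid composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from microstrat.io_metadata import (
    MISSING,
    AbundanceTable,
    ValidationError,
    bin_bmi,
    load_cohort_reference,
)

#: BMI value range sampled within each category (kg/m^2).
_BMI_RANGES = {
    "underweight": (16.0, 18.5),
    "normal": (18.5, 25.0),
    "overweight": (25.0, 30.0),
    "obese": (30.0, 40.0),
}
_BMI_ORDER = ["underweight", "normal", "overweight", "obese", MISSING]


def default_concentration(n_taxa: int, scale: float = 5.0) -> np.ndarray:
    """Long-tailed Dirichlet concentration: alpha_j = scale / (1 + j).

    A handful of abundant genera and a long sparse tail. The default scale
    puts the median between-subject Bray-Curtis distance around 0.5-0.6
    and leaves roughly a quarter of entries near zero at 60 taxa — the
    regime of curated genus-level tables from healthy adults.
    """
    return scale / (1.0 + np.arange(n_taxa))


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort.

    planted_effects entries are (country, taxon, effect) with effect >= 1
    multiplying the taxon's Dirichlet concentration for that country's
    samples.
    """

    n_countries: int
    samples_per_country: list[int]
    n_taxa: int
    n_studies: int
    panel_fraction: float = 1.0
    base_concentration: np.ndarray | None = None
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    age_params: dict[str, tuple[float, float]] | None = None
    sex_balance: dict[str, float] | None = None
    bmi_params: dict[str, dict[str, float]] | None = None
    country_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_country) != self.n_countries:
            raise ValidationError(
                "samples_per_country length must equal n_countries"
            )
        if not (0 < self.panel_fraction <= 1):
            raise ValidationError("panel_fraction must lie in (0, 1]")
        if not (self.n_countries <= self.n_studies <= 3 * self.n_countries):
            raise ValidationError(
                "n_studies must allow 1-3 country-exclusive studies per country"
            )
        if self.country_names is None:
            self.country_names = [
                f"country{i + 1:02d}" for i in range(self.n_countries)
            ]
        if len(self.country_names) != self.n_countries:
            raise ValidationError("country_names length must equal n_countries")
        if self.base_concentration is None:
            self.base_concentration = default_concentration(self.n_taxa)
        self.base_concentration = np.asarray(self.base_concentration, dtype=float)
        if self.base_concentration.shape != (self.n_taxa,):
            raise ValidationError("base_concentration must have length n_taxa")
        if np.any(self.base_concentration <= 0):
            raise ValidationError("base_concentration must be positive")
        if self.age_params is None:
            self.age_params = {c: (40.0, 15.0) for c in self.country_names}
        if self.sex_balance is None:
            self.sex_balance = {c: 0.5 for c in self.country_names}
        if self.bmi_params is None:
            self.bmi_params = {
                c: {
                    "underweight": 0.02,
                    "normal": 0.55,
                    "overweight": 0.25,
                    "obese": 0.08,
                    MISSING: 0.10,
                }
                for c in self.country_names
            }
        for c, probs in self.bmi_params.items():
            total = sum(probs.get(k, 0.0) for k in _BMI_ORDER)
            if not np.isclose(total, 1.0, atol=1e-8):
                raise ValidationError(f"BMI category probabilities for {c} sum to {total}")
        for country, taxon, effect in self.planted_effects:
            if country not in self.country_names:
                raise ValidationError(f"planted effect references unknown country {country!r}")
            if not taxon.startswith("taxon") or not self._taxon_index_ok(taxon):
                raise ValidationError(f"planted effect references unknown taxon {taxon!r}")
            if effect < 1:
                raise ValidationError("planted effect size must be >= 1")

    def _taxon_index_ok(self, taxon: str) -> bool:
        try:
            return 0 <= int(taxon.removeprefix("taxon")) < self.n_taxa
        except ValueError:
            return False

    @property
    def taxon_names(self) -> list[str]:
        return [f"taxon{j}" for j in range(self.n_taxa)]

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["base_concentration"] = [float(x) for x in self.base_concentration]
        data["planted_effects"] = [list(e) for e in self.planted_effects]
        data["age_params"] = {c: list(v) for c, v in self.age_params.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["planted_effects"] = [tuple(e) for e in data.get("planted_effects", [])]
        if data.get("age_params"):
            data["age_params"] = {c: tuple(v) for c, v in data["age_params"].items()}
        if data.get("base_concentration") is not None:
            data["base_concentration"] = np.asarray(data["base_concentration"])
        return cls(**data)


def _assign_studies(spec: SyntheticSpec, rng: np.random.Generator) -> dict[str, list[int]]:
    """Country-exclusive study allocation: every country gets 1-3 studies.

    Mirrors how curated repositories are assembled — studies recruit within
    one country, so study-panel artefacts align with country labels.
    """
    studies = {c: [i] for i, c in enumerate(spec.country_names)}
    extra = spec.n_studies - spec.n_countries
    eligible = list(spec.country_names)
    next_id = spec.n_countries
    for _ in range(extra):
        eligible = [c for c in eligible if len(studies[c]) < 3]
        c = eligible[rng.integers(len(eligible))]
        studies[c].append(next_id)
        next_id += 1
    return studies


def _study_panels(spec: SyntheticSpec, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Fixed taxon panel per study: a random panel_fraction subset of taxa."""
    size = max(1, int(round(spec.panel_fraction * spec.n_taxa)))
    panels = {}
    for s in range(spec.n_studies):
        if size >= spec.n_taxa:
            panels[s] = np.ones(spec.n_taxa, dtype=bool)
        else:
            mask = np.zeros(spec.n_taxa, dtype=bool)
            mask[rng.choice(spec.n_taxa, size=size, replace=False)] = True
            panels[s] = mask
    return panels


def _draw_metadata(
    spec: SyntheticSpec,
    country: str,
    sample_id: str,
    study: int,
    rng: np.random.Generator,
) -> dict:
    mean, sd = spec.age_params[country]
    age = float(np.round(max(18.0, rng.normal(mean, sd)), 1))
    sex = "Female" if rng.random() < spec.sex_balance[country] else "Male"
    probs = [spec.bmi_params[country].get(k, 0.0) for k in _BMI_ORDER]
    cat = _BMI_ORDER[rng.choice(len(_BMI_ORDER), p=np.asarray(probs) / sum(probs))]
    if cat == MISSING:
        bmi = np.nan
    else:
        lo, hi = _BMI_RANGES[cat]
        bmi = float(np.round(rng.uniform(lo, hi - 1e-6), 1))
        cat = bin_bmi(bmi)  # rounding may not cross a cut point, but keep consistent
    return {
        "sample_id": sample_id,
        "country": country,
        "study_id": f"study{study:02d}",
        "age": age,
        "sex": sex,
        "bmi_value": bmi,
        "bmi_category": cat,
    }


def generate_dataset(spec: SyntheticSpec) -> tuple[AbundanceTable, pd.DataFrame]:
    """Draw a full synthetic cohort: abundance table plus metadata.

    Per sample: pick one of the country's studies, draw a Dirichlet
    composition from the base concentration (with planted country effects
    multiplied in), zero out taxa off the study's panel, and renormalize.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    studies = _assign_studies(spec, rng)
    panels = _study_panels(spec, rng)
    effects: dict[str, np.ndarray] = {}
    for country, taxon, effect in spec.planted_effects:
        vec = effects.setdefault(country, np.ones(spec.n_taxa))
        vec[int(taxon.removeprefix("taxon"))] *= effect

    rows, meta_rows, sample_ids = [], [], []
    counter = 0
    for country, n in zip(spec.country_names, spec.samples_per_country):
        alpha = spec.base_concentration * effects.get(country, 1.0)
        for _ in range(n):
            sid = f"S{counter:05d}"
            counter += 1
            study = studies[country][rng.integers(len(studies[country]))]
            comp = rng.dirichlet(alpha)
            comp = comp * panels[study]
            total = comp.sum()
            if total == 0:
                raise ValidationError(f"study panel left sample {sid} empty")
            rows.append(comp / total)
            sample_ids.append(sid)
            meta_rows.append(_draw_metadata(spec, country, sid, study, rng))

    table = AbundanceTable(
        sample_ids=sample_ids, taxon_ids=spec.taxon_names, values=np.array(rows)
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, meta


def null_dataset(spec: SyntheticSpec) -> tuple[AbundanceTable, pd.DataFrame]:
    """Cohort with country labels exchangeable w.r.t. abundances.

    Compositions and study panels are drawn identically for every sample
    (studies assigned uniformly, independent of country), then country
    labels and country-conditional metadata are attached independently of
    the compositions. Used for type-I-error calibration of the enrichment
    stage.
    """
    if spec.planted_effects:
        raise ValidationError("null_dataset requires empty planted_effects")
    rng = np.random.default_rng(spec.seed)
    panels = _study_panels(spec, rng)

    n_total = int(sum(spec.samples_per_country))
    sample_ids = [f"S{i:05d}" for i in range(n_total)]
    rows, studies_drawn = [], []
    for sid in sample_ids:
        study = int(rng.integers(spec.n_studies))
        comp = rng.dirichlet(spec.base_concentration)
        comp = comp * panels[study]
        total = comp.sum()
        if total == 0:
            raise ValidationError(f"study panel left sample {sid} empty")
        rows.append(comp / total)
        studies_drawn.append(study)

    labels = np.repeat(
        np.arange(spec.n_countries),
        np.asarray(spec.samples_per_country, dtype=int),
    )
    rng.shuffle(labels)
    meta_rows = []
    for sid, study, lab in zip(sample_ids, studies_drawn, labels):
        country = spec.country_names[lab]
        meta_rows.append(_draw_metadata(spec, country, sid, study, rng))

    table = AbundanceTable(
        sample_ids=sample_ids, taxon_ids=spec.taxon_names, values=np.array(rows)
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, meta


def blob_dataset(
    k: int,
    n_per_blob: int,
    n_taxa: int,
    seed: int = 0,
    concentration: float = 20.0,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """k well-separated compositional blobs on disjoint taxon blocks.

    Each blob's samples draw from a Dirichlet concentrated on its own block
    of taxa, so between-blob Bray-Curtis distances approach 1 while
    within-blob distances stay small — ground truth for cluster-count
    checks against zero-dimensional persistence.
    """
    if n_taxa < 2 * k:
        raise ValidationError("need at least 2 taxa per blob")
    rng = np.random.default_rng(seed)
    block = n_taxa // k
    rows, labels = [], []
    for b in range(k):
        alpha = np.full(n_taxa, 1e-3)
        lo = b * block
        hi = n_taxa if b == k - 1 else lo + block
        alpha[lo:hi] = concentration / (hi - lo)
        for _ in range(n_per_blob):
            rows.append(rng.dirichlet(alpha))
            labels.append(f"blob{b}")
    sample_ids = [f"B{i:05d}" for i in range(len(rows))]
    table = AbundanceTable(
        sample_ids=sample_ids,
        taxon_ids=[f"taxon{j}" for j in range(n_taxa)],
        values=np.array(rows),
    )
    meta = pd.DataFrame(
        {
            "country": labels,
            "study_id": "study00",
            "age": 40.0,
            "sex": "Female",
            "bmi_value": 22.0,
            "bmi_category": "normal",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return table, meta


def cohort_spec(
    n_taxa: int = 120,
    scale: float = 1.0,
    panel_fraction: float = 0.6,
    seed: int = 0,
    planted_effects: list[tuple[str, str, float]] | None = None,
) -> SyntheticSpec:
    """Spec mirroring the published GMrepo-derived cohort shape.

    Twelve countries with the published unbalanced sample counts (scaled by
    ``scale``, minimum 5 per country), per-country age means/SDs, sex
    ratios and BMI category frequencies taken from the published summary;
    19 studies; study panels covering ``panel_fraction`` of taxa.
    """
    ref = load_cohort_reference()
    countries = list(ref.index)
    n = [max(5, int(round(scale * v))) for v in ref["n"]]
    age = {c: (float(ref.loc[c, "age_mean"]), float(ref.loc[c, "age_sd"])) for c in countries}
    sex = {}
    bmi = {}
    for c in countries:
        f, m = ref.loc[c, "sex_Female"], ref.loc[c, "sex_Male"]
        sex[c] = float(f) / max(1.0, float(f + m))
        tot = float(ref.loc[c, "n"])
        bmi[c] = {
            "underweight": float(ref.loc[c, "bmi_underweight"]) / tot,
            "normal": float(ref.loc[c, "bmi_normal"]) / tot,
            "overweight": float(ref.loc[c, "bmi_overweight"]) / tot,
            "obese": float(ref.loc[c, "bmi_obese"]) / tot,
            MISSING: float(ref.loc[c, "bmi_Missing"]) / tot,
        }
        bmi[c][MISSING] += 1.0 - sum(bmi[c].values())  # absorb rounding
    return SyntheticSpec(
        n_countries=len(countries),
        samples_per_country=n,
        n_taxa=n_taxa,
        n_studies=19,
        panel_fraction=panel_fraction,
        planted_effects=planted_effects or [],
        age_params=age,
        sex_balance=sex,
        bmi_params=bmi,
        country_names=countries,
        seed=seed,
    )
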