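"""End-to-end orchestration: data -> network -> enrichment -> co-enrichment.

Runs the stages in their fixed order (country filter, normalization,
Bray-Curtis distances, MDS lens, cover + DBSCAN + nerve, SAFE, pairwise
co-enrichment, stratification) and writes every artefact plus a manifest
with all parameters, derived seeds, and sample/node accounting, so a run
is reproducible byte-for-byte from the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import microstrat
from microstrat.io_metadata import (
    AbundanceTable,
    ValidationError,
    cohort_summary,
    dummy_code,
    filter_countries,
    load_abundance,
    load_metadata,
    normalize_relative,
)
from microstrat.geometry import h0_persistence, mds_lens, pairwise_distances
from microstrat.mapper import (
    DEFAULT_EPS_THRESHOLD,
    DEFAULT_MIN_SAMPLES,
    DEFAULT_OVERLAP,
    DEFAULT_RESOLUTION,
    cover_ratio,
    mapper_network,
    parameter_sweep,
    write_network,
)
from microstrat.safe import (
    DEFAULT_ALPHA,
    DEFAULT_NEIGHBORHOOD_PERCENTILE,
    DEFAULT_PERMUTATIONS,
    neighborhoods,
    node_distances,
    node_values,
    rank_variables,
    safe_long_table,
    safe_scores,
)
from microstrat.coenrichment import (
    DEFAULT_COENRICHMENT_PERCENTILE,
    coenrichment_matrix,
    stratify_nodes,
    threshold_binarize,
)
from microstrat.synthetic import SyntheticSpec, generate_dataset


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, defaulting to the published final
    settings (resolution 85, overlap 0.85, eps threshold 0.95, minimum 5
    neighbours, 5,000 permutations, 0.5th-percentile thresholds)."""

    abundance_path: str | None = None
    metadata_path: str | None = None
    synthetic_spec_path: str | None = None
    output_dir: str = "results/run"
    min_country_n: int = 20
    seed: int = 0
    resolution: int = DEFAULT_RESOLUTION
    overlap: float = DEFAULT_OVERLAP
    eps_threshold: float = DEFAULT_EPS_THRESHOLD
    min_samples: int = DEFAULT_MIN_SAMPLES
    n_permutations: int = DEFAULT_PERMUTATIONS
    neighborhood_percentile: float = DEFAULT_NEIGHBORHOOD_PERCENTILE
    node_alpha: float = DEFAULT_ALPHA
    coenrichment_percentile: float = DEFAULT_COENRICHMENT_PERCENTILE
    max_taxa: int | None = None
    write_distances: bool = False
    permutation_scheme: str = "samples"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValidationError("overlap must lie in [0, 1)")
        if self.resolution < 1:
            raise ValidationError("resolution must be >= 1")
        if not (0 < self.eps_threshold <= 1):
            raise ValidationError("eps_threshold must lie in (0, 1]")
        if not (0 < self.node_alpha < 1):
            raise ValidationError("node_alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.permutation_scheme not in ("samples", "nodes"):
            raise ValidationError("permutation_scheme must be 'samples' or 'nodes'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _stage_seed(seed: int, key: int) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    state = np.random.SeedSequence(entropy=seed, spawn_key=(key,)).generate_state(1)
    return int(state[0] % (2**31))


def _load_inputs(config: PipelineConfig) -> tuple[AbundanceTable, pd.DataFrame]:
    if config.synthetic_spec_path is not None:
        spec = SyntheticSpec.from_yaml(config.synthetic_spec_path)
        return generate_dataset(spec)
    if config.abundance_path is None or config.metadata_path is None:
        raise ValidationError(
            "config needs either synthetic_spec_path or abundance_path + metadata_path"
        )
    for path in (config.abundance_path, config.metadata_path):
        if not Path(path).exists():
            raise ValidationError(f"input file not found: {path}")
    return load_abundance(config.abundance_path), load_metadata(config.metadata_path)


def build_variables(
    table: AbundanceTable, meta: pd.DataFrame, max_taxa: int | None = None
) -> dict[str, dict[str, float]]:
    """Per-sample value maps for every enrichment variable: dummy-coded
    country/sex/BMI levels, age, and (optionally the ``max_taxa`` most
    abundant) taxa."""
    variables: dict[str, dict[str, float]] = {}
    dummies = dummy_code(meta, ["country", "sex", "bmi_category"])
    for var, level in dummies.columns:
        variables[f"{var}={level}"] = dummies[(var, level)].to_dict()
    variables["age"] = meta["age"].to_dict()
    frame = table.to_frame()
    taxa = list(frame.columns)
    if max_taxa is not None and len(taxa) > max_taxa:
        taxa = list(frame.mean(axis=0).sort_values(ascending=False).index[:max_taxa])
    for taxon in taxa:
        variables[taxon] = frame[taxon].to_dict()
    return variables


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artefact bundle; returns the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    table, meta = _load_inputs(config)
    n_input = table.n_samples
    meta = filter_countries(meta, config.min_country_n)
    table = table.subset_samples(list(meta.index))
    table = normalize_relative(table)

    cohort_summary(meta).to_csv(outdir / "cohort_summary.tsv", sep="\t")

    D = pairwise_distances(table)
    if config.write_distances:
        D.write(outdir / "distances.tsv")
    lens = mds_lens(D, seed=_stage_seed(config.seed, 0))
    diagram = h0_persistence(D)
    diagram.write(outdir / "h0_diagram.tsv")

    network = mapper_network(
        D,
        lens,
        resolution=config.resolution,
        overlap=config.overlap,
        eps_threshold=config.eps_threshold,
        min_samples=config.min_samples,
    )
    if not network.nodes:
        raise ValidationError(
            "mapper stage produced an empty network; lower min_samples or resolution"
        )
    write_network(network, outdir / "network.graphml", outdir / "network_members.json")

    dist = node_distances(network)
    nbh = neighborhoods(network, config.neighborhood_percentile, dist=dist)
    variables = build_variables(table, meta, config.max_taxa)
    results = []
    for k, (name, mapping) in enumerate(sorted(variables.items())):
        attr = node_values(network, mapping, name)
        results.append(
            safe_scores(
                network,
                attr,
                nbh,
                n_permutations=config.n_permutations,
                seed=_stage_seed(config.seed, 1 + k),
                permute=config.permutation_scheme,
            )
        )
    safe_long_table(results, config.node_alpha).to_csv(
        outdir / "safe_long.tsv", sep="\t", index=False
    )
    ranking = rank_variables(results, config.node_alpha)
    ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False)

    p_matrix = coenrichment_matrix(results, len(network.nodes), config.node_alpha)
    coe = threshold_binarize(p_matrix, config.coenrichment_percentile)
    coe.p_matrix.to_csv(outdir / "coenrichment_p.tsv", sep="\t")
    coe.binary_matrix.to_csv(outdir / "coenrichment_binary.tsv", sep="\t")
    stratify_nodes(results, config.node_alpha).to_csv(
        outdir / "stratification.tsv", sep="\t"
    )

    retained = len(network.retained_samples)
    manifest = {
        "config": asdict(config),
        "stage_seeds": {"mds": _stage_seed(config.seed, 0)},
        "versions": {
            "microstrat": microstrat.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "n_samples_input": n_input,
            "n_samples_after_country_filter": int(len(meta)),
            "n_samples_retained": retained,
            "n_samples_dropped": int(len(meta)) - retained,
            "cover_ratio": cover_ratio(network, len(meta)),
            "n_nodes": len(network.nodes),
            "n_edges": len(network.edges),
            "n_components": network.n_components(),
            "n_variables": len(variables),
            "neighborhood_threshold": nbh.threshold,
            "coenrichment_threshold": coe.threshold,
        },
        "outputs": sorted(
            p.name
            for p in outdir.iterdir()
            if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_sweep(
    config: PipelineConfig, resolutions: list[int], overlaps: list[float]
) -> pd.DataFrame:
    """Tabular resolution/overlap sweep on the configured input data."""
    table, meta = _load_inputs(config)
    meta = filter_countries(meta, config.min_country_n)
    table = normalize_relative(table.subset_samples(list(meta.index)))
    D = pairwise_distances(table)
    lens = mds_lens(D, seed=_stage_seed(config.seed, 0))
    return parameter_sweep(
        D,
        lens,
        resolutions,
        overlaps,
        eps_threshold=config.eps_threshold,
        min_samples=config.min_samples,
    )
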