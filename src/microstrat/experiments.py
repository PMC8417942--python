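"""Reusable simulation studies: null calibration, planted-effect recovery,
and the blob-structure consistency check.

These are the package's standard power/calibration experiments; the
analysis scripts and the acceptance machinery both run them through this
module so the study conditions are defined in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from microstrat.coenrichment import coenrichment_matrix, threshold_binarize
from microstrat.geometry import (
    expected_clusters,
    h0_persistence,
    mds_lens,
    pairwise_distances,
)
from microstrat.mapper import mapper_network
from microstrat.pipeline import build_variables
from microstrat.safe import (
    neighborhoods,
    node_values,
    rank_variables,
    safe_scores,
)
from microstrat.synthetic import (
    SyntheticSpec,
    blob_dataset,
    generate_dataset,
    null_dataset,
)

#: Study conditions for the planted-effect recovery experiment: two
#: countries of 50 samples, a x5 concentration effect on a mid-abundance
#: genus, a 60-taxon table, and a cover scaled to the ~100-sample problem.
RECOVERY = {
    "n_per_country": 50,
    "n_taxa": 60,
    "planted_taxon": "taxon4",
    "effect": 5.0,
    "resolution": 7,
    "overlap": 0.85,
    "n_permutations": 999,
}

#: Study conditions for the end-to-end type-I calibration experiment.
CALIBRATION = {
    "n_per_country": 50,
    "n_taxa": 30,
    "resolution": 6,
    "overlap": 0.85,
    "n_permutations": 999,
    "alpha": 0.05,
}


@dataclass
class RecoveryOutcome:
    planted_ranked_first: bool
    planted_pair_significant: bool


def recovery_trial(seed: int, planted: bool = True) -> RecoveryOutcome | None:
    """One end-to-end run of the planted-effect recovery experiment.

    Generates the two-country cohort (with or without the planted
    country-taxon effect), builds the Mapper network, runs SAFE for every
    variable (country/sex/BMI dummies, age, all taxa), ranks countries by
    SAFE enriched score, and binarizes the pairwise co-enrichment matrix
    at the 0.5th percentile. Returns None if the network came out empty.
    """
    cfg = RECOVERY
    effects = (
        [("country01", cfg["planted_taxon"], cfg["effect"])] if planted else []
    )
    spec = SyntheticSpec(
        n_countries=2,
        samples_per_country=[cfg["n_per_country"]] * 2,
        n_taxa=cfg["n_taxa"],
        n_studies=2,
        planted_effects=effects,
        seed=seed,
    )
    table, meta = generate_dataset(spec)
    D = pairwise_distances(table)
    lens = mds_lens(D, seed=seed)
    net = mapper_network(
        D, lens, resolution=cfg["resolution"], overlap=cfg["overlap"]
    )
    if not net.nodes:
        return None
    nbh = neighborhoods(net)
    variables = build_variables(table, meta)
    results = []
    for k, (name, mapping) in enumerate(sorted(variables.items())):
        attr = node_values(net, mapping, name)
        results.append(
            safe_scores(
                net, attr, nbh, n_permutations=cfg["n_permutations"], seed=1000 + k
            )
        )
    ranking = rank_variables(results)
    countries = ranking[ranking["variable"].str.startswith("country=")]
    ranked_first = countries.iloc[0]["variable"] == "country=country01"
    p_matrix = coenrichment_matrix(results, len(net.nodes))
    coe = threshold_binarize(p_matrix, 0.5)
    pair = bool(
        coe.binary_matrix.loc["country=country01", cfg["planted_taxon"]] == 1
    )
    return RecoveryOutcome(planted_ranked_first=ranked_first, planted_pair_significant=pair)


def recovery_rates(seeds: list[int], planted: bool = True) -> dict[str, float]:
    """Fraction of runs in which the planted country ranks first and in
    which the planted (country, taxon) pair is binarized-significant."""
    outcomes = [recovery_trial(s, planted=planted) for s in seeds]
    outcomes = [o for o in outcomes if o is not None]
    n = len(outcomes)
    return {
        "rank_rate": sum(o.planted_ranked_first for o in outcomes) / n,
        "pair_rate": sum(o.planted_pair_significant for o in outcomes) / n,
        "n_runs": n,
    }


def calibration_rejection_rate(seeds: list[int]) -> dict[str, float]:
    """End-to-end type-I calibration of SAFE.

    For each seed: draw a null cohort (country labels exchangeable with
    respect to composition), build the network, score the continuous age
    variable, and record the fraction of nodes with p < alpha. Averaged
    over seeds this should sit at alpha for a calibrated permutation test.
    """
    cfg = CALIBRATION
    rates = []
    for seed in seeds:
        spec = SyntheticSpec(
            n_countries=2,
            samples_per_country=[cfg["n_per_country"]] * 2,
            n_taxa=cfg["n_taxa"],
            n_studies=2,
            seed=seed,
        )
        table, meta = null_dataset(spec)
        D = pairwise_distances(table)
        lens = mds_lens(D, seed=seed)
        net = mapper_network(
            D, lens, resolution=cfg["resolution"], overlap=cfg["overlap"]
        )
        if not net.nodes:
            continue
        nbh = neighborhoods(net)
        attr = node_values(net, meta["age"].to_dict(), "age")
        res = safe_scores(
            net, attr, nbh, n_permutations=cfg["n_permutations"], seed=10000 + seed
        )
        rates.append(float(np.mean(res.p_values < cfg["alpha"])))
    return {"rejection_rate": float(np.mean(rates)), "n_runs": len(rates)}


def blob_structure_check(
    k: int = 3, n_per_blob: int = 60, n_taxa: int = 30, seed: int = 2
) -> dict[str, int]:
    """Cluster-count consistency between the Mapper network and the H0
    persistence diagram on ground-truth compositional blobs."""
    table, _ = blob_dataset(k, n_per_blob, n_taxa, seed=seed)
    D = pairwise_distances(table)
    lens = mds_lens(D, seed=seed)
    diagram = h0_persistence(D)
    net = mapper_network(D, lens, resolution=8, overlap=0.5)
    return {
        "true_blobs": k,
        "h0_clusters": expected_clusters(diagram),
        "network_components": net.n_components(),
    }
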