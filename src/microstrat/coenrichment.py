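"""Pairwise co-enrichment and network stratification.

Two variables are co-enriched when their significantly enriched node sets
overlap more than chance expects. The overlap is tested with a one-sided
Fisher exact (hypergeometric) test over the network's nodes; the matrix of
pairwise p-values is then thresholded at a low nearest-rank percentile of
its entries and binarized — a deliberately strict cut that stands in for
multiplicity control over the many pairs. Stratification colours each node
by the enriched variable with the highest SAFE score there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from microstrat.io_metadata import ValidationError
from microstrat.safe import DEFAULT_ALPHA, SAFEResult, enriched_nodes

DEFAULT_COENRICHMENT_PERCENTILE = 0.5


@dataclass
class CoenrichmentResult:
    variables: list[str]
    p_matrix: pd.DataFrame
    threshold: float
    binary_matrix: pd.DataFrame


def coenrichment_p(a: SAFEResult, b: SAFEResult, n_nodes: int, alpha: float = DEFAULT_ALPHA) -> float:
    """One-sided Fisher exact p for overlap of two enriched node sets.

    2x2 table over the network's nodes: (both, a only, b only, neither),
    alternative 'greater'. An empty enriched set on either side carries no
    evidence and returns 1.
    """
    set_a = enriched_nodes(a, alpha)
    set_b = enriched_nodes(b, alpha)
    if not set_a or not set_b:
        return 1.0
    both = len(set_a & set_b)
    only_a = len(set_a) - both
    only_b = len(set_b) - both
    neither = n_nodes - both - only_a - only_b
    if neither < 0:
        raise ValidationError("enriched sets exceed the stated node count")
    _, p = fisher_exact([[both, only_a], [only_b, neither]], alternative="greater")
    return float(min(p, 1.0))


def coenrichment_matrix(
    results: list[SAFEResult], n_nodes: int, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Symmetric matrix of pairwise co-enrichment p-values (diagonal 1,
    self-pairs are not tested)."""
    names = [r.variable for r in results]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate variable names in SAFE results")
    n = len(results)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = coenrichment_p(results[i], results[j], n_nodes, alpha)
            mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=names, columns=names)


def _nearest_rank(sorted_values: np.ndarray, percentile: float) -> float:
    m = len(sorted_values)
    rank = int(np.ceil(percentile / 100.0 * m)) - 1
    return float(sorted_values[min(max(rank, 0), m - 1)])


def threshold_binarize(
    p_matrix: pd.DataFrame, percentile: float = DEFAULT_COENRICHMENT_PERCENTILE
) -> CoenrichmentResult:
    """Binarize the p-value matrix at its nearest-rank ``percentile``.

    The threshold is taken over the upper-triangle p-values and applied
    inclusively (p <= threshold passes). If all p-values are identical,
    every pair passes — the documented degenerate behaviour.
    """
    variables = list(p_matrix.columns)
    n = len(variables)
    if n == 0:
        empty = pd.DataFrame(index=[], columns=[], dtype=float)
        return CoenrichmentResult(variables=[], p_matrix=empty, threshold=np.nan, binary_matrix=empty.astype(int))
    values = p_matrix.to_numpy()
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValidationError("p-value matrix must be symmetric")
    iu = np.triu_indices(n, k=1)
    if iu[0].size == 0:
        threshold = np.nan
        binary = np.zeros((n, n), dtype=int)
    else:
        threshold = _nearest_rank(np.sort(values[iu]), percentile)
        binary = (values <= threshold).astype(int)
        np.fill_diagonal(binary, 0)
    return CoenrichmentResult(
        variables=variables,
        p_matrix=p_matrix.copy(),
        threshold=float(threshold),
        binary_matrix=pd.DataFrame(binary, index=variables, columns=variables),
    )


def stratify_nodes(
    results: list[SAFEResult], alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Most-enriched variable per node.

    Among the variables whose enriched node set contains the node, the one
    with the maximal SAFE score wins (ties broken lexicographically by
    variable name); nodes enriched for nothing get winner None ("grey").
    Returns a DataFrame indexed by node with columns winner, score.
    """
    if not results:
        raise ValidationError("no SAFE results to stratify")
    node_ids = results[0].node_ids
    for res in results[1:]:
        if res.node_ids != node_ids:
            raise ValidationError("SAFE results come from different networks")
    winners: list[str | None] = []
    scores: list[float] = []
    per_var = [
        (res.variable, enriched_nodes(res, alpha), dict(zip(res.node_ids, res.scores)))
        for res in sorted(results, key=lambda r: r.variable)
    ]
    for nid in node_ids:
        best: tuple[float, str] | None = None
        for name, enriched, score_map in per_var:
            if nid in enriched:
                cand = (float(score_map[nid]), name)
                # higher score wins; on exact tie the lexicographically
                # first name wins (per_var is sorted by name)
                if best is None or cand[0] > best[0]:
                    best = cand
        winners.append(best[1] if best else None)
        scores.append(best[0] if best else np.nan)
    return pd.DataFrame({"winner": winners, "score": scores}, index=pd.Index(node_ids, name="node"))


def plot_coenrichment_heatmap(result: CoenrichmentResult, path) -> None:
    """Optional heatmap export of -log10 co-enrichment p-values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with np.errstate(divide="ignore"):
        logp = -np.log10(result.p_matrix.to_numpy())
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(logp, cmap="viridis")
    ax.set_xticks(range(len(result.variables)))
    ax.set_xticklabels(result.variables, rotation=90, fontsize=6)
    ax.set_yticks(range(len(result.variables)))
    ax.set_yticklabels(result.variables, fontsize=6)
    fig.colorbar(im, ax=ax, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
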