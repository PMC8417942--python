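"""Distances, lens, and zero-dimensional persistence.

Bray-Curtis dissimilarities between relative-abundance profiles, the
two-component metric-MDS lens used to cover the data for Mapper, and the
H0 persistence diagram (single-linkage merge heights) used as an
independent estimate of the number of robust clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from microstrat.io_metadata import AbundanceTable, ValidationError


@dataclass
class DistanceMatrix:
    """Square symmetric Bray-Curtis matrix over samples, entries in [0, 1]."""

    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix must be square over sample_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValidationError("Bray-Curtis distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class Lens:
    """Two-dimensional embedding of the samples plus final stress."""

    sample_ids: list[str]
    coords: np.ndarray = field(repr=False)
    stress: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sample_ids), 2):
            raise ValidationError("lens must have exactly two components")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("lens coordinates must be finite")


@dataclass
class PersistenceDiagramH0:
    """H0 barcode: births all 0, finite deaths are single-linkage merge
    heights, plus one infinite bar for the surviving component."""

    finite_deaths: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        self.finite_deaths = np.sort(np.asarray(self.finite_deaths, dtype=float))
        if len(self.finite_deaths) != self.n_points - 1:
            raise ValidationError("H0 diagram must have n-1 finite bars")

    @property
    def bars(self) -> list[tuple[float, float]]:
        return [(0.0, float(d)) for d in self.finite_deaths] + [(0.0, np.inf)]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("birth\tdeath\n")
            for birth, death in self.bars:
                token = "inf" if np.isinf(death) else f"{death:.10g}"
                fh.write(f"{birth:.10g}\t{token}\n")


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """BC(x, y) = 1 - 2 sum(min(x_i, y_i)) / (sum x + sum y).

    Defined for non-negative vectors of equal length; undefined (raises)
    when both are all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("abundances must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def pairwise_distances(table: AbundanceTable) -> DistanceMatrix:
    """Square-form Bray-Curtis distance matrix over all sample pairs."""
    if table.n_samples < 2:
        raise ValidationError("need at least 2 samples for pairwise distances")
    zero = np.flatnonzero(table.values.sum(axis=1) == 0)
    if zero.size:
        raise ValidationError(
            f"all-zero sample(s) make Bray-Curtis undefined: "
            f"{[table.sample_ids[i] for i in zero[:5]]}"
        )
    condensed = pdist(table.values, metric="braycurtis")
    values = squareform(np.clip(condensed, 0.0, 1.0))
    return DistanceMatrix(sample_ids=list(table.sample_ids), values=values)


def _classical_init(d2: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) scaling of squared distances into 2-D."""
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:2]
    lam = np.clip(eigval[order], 0.0, None)
    coords = eigvec[:, order] * np.sqrt(lam)
    if coords.shape[1] < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    return coords


def mds_lens(
    D: DistanceMatrix,
    seed: int = 0,
    max_iter: int = 300,
    eps: float = 1e-6,
) -> Lens:
    """Two-component metric-MDS lens over a precomputed distance matrix.

    Stress-majorization (SMACOF) from a classical-scaling start, so the
    result is deterministic; ``seed`` only feeds the SMACOF internals.
    The reported stress is the final raw stress.
    """
    if D.n == 1:
        return Lens(sample_ids=list(D.sample_ids), coords=np.zeros((1, 2)), stress=0.0)
    init = _classical_init(D.values**2)
    coords, stress = smacof(
        D.values,
        metric=True,
        n_components=2,
        init=init,
        n_init=1,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=False,
    )
    return Lens(sample_ids=list(D.sample_ids), coords=coords, stress=float(stress))


def h0_persistence(D: DistanceMatrix) -> PersistenceDiagramH0:
    """H0 persistence of the metric point cloud.

    Components are born at scale 0 and die at the single-linkage merge
    heights, i.e. the minimum-spanning-tree edge weights; one component
    survives to infinity.
    """
    if D.n == 1:
        return PersistenceDiagramH0(finite_deaths=np.empty(0), n_points=1)
    merges = linkage(squareform(D.values, checks=False), method="single")[:, 2]
    return PersistenceDiagramH0(finite_deaths=merges, n_points=D.n)


def expected_clusters(diagram: PersistenceDiagramH0) -> int:
    """Number of high-persistence H0 bars via the largest-gap heuristic.

    Sort the finite deaths; the largest gap between consecutive deaths
    separates within-cluster merges from between-cluster merges. The bars
    above the gap plus the infinite bar are the robust clusters.
    """
    deaths = diagram.finite_deaths
    if deaths.size == 0:
        return 1
    gaps = np.diff(deaths)
    if gaps.size == 0 or gaps.max() <= 0:
        return 1
    cut = int(np.argmax(gaps))
    return int(deaths.size - cut - 1) + 1
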