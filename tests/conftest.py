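import numpy as np
import pandas as pd
import pytest

from microstrat.geometry import DistanceMatrix, Lens
from microstrat.mapper import TDANetwork, Node


@pytest.fixture
def tiny_metadata() -> pd.DataFrame:
    """Nine samples, three countries, with missing age/sex/BMI cases."""
    rows = [
        ("s1", "A", "st1", 30.0, "Female", 17.0),
        ("s2", "A", "st1", 40.0, "Male", 22.0),
        ("s3", "A", "st1", 50.0, "Female", 27.0),
        ("s4", "B", "st2", 35.0, "Male", 31.0),
        ("s5", "B", "st2", np.nan, "Female", np.nan),
        ("s6", "B", "st2", 45.0, "Missing", 24.0),
        ("s7", "C", "st3", 60.0, "Male", 19.0),
        ("s8", "C", "st3", 62.0, "Female", 29.9),
        ("s9", "C", "st3", 64.0, "Male", 30.0),
    ]
    from microstrat.io_metadata import bin_bmi

    meta = pd.DataFrame(
        rows, columns=["sample_id", "country", "study_id", "age", "sex", "bmi_value"]
    ).set_index("sample_id")
    meta["bmi_category"] = [bin_bmi(v) for v in meta["bmi_value"]]
    return meta


def path_network(n: int = 3) -> TDANetwork:
    """Path graph A-B-C-... as a TDANetwork; node i shares sample f"s{i}" with
    node i+1."""
    nodes = {}
    for i in range(n):
        members = {f"s{i}", f"s{i + 1}"}
        nodes[i] = Node(members=frozenset(members), bin_index=(i, 0), centroid=(float(i), 0.0))
    edges = {(i, i + 1) for i in range(n - 1)}
    return TDANetwork(nodes=nodes, edges=edges, params={})


@pytest.fixture
def small_distance_matrix() -> DistanceMatrix:
    rng = np.random.default_rng(7)
    pts = rng.random((12, 4))
    pts = pts / pts.sum(axis=1, keepdims=True)
    from microstrat.io_metadata import AbundanceTable
    from microstrat.geometry import pairwise_distances

    table = AbundanceTable(
        sample_ids=[f"s{i}" for i in range(12)],
        taxon_ids=[f"t{j}" for j in range(4)],
        values=pts,
    )
    return pairwise_distances(table)
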