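import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from pgpbcomp.clustering import ClusterAssignment
from pgpbcomp.synthetic import SimConfig, simulate_cohort

# Habitat-by-cluster strain counts of the published 573-strain cohort:
# rows are the four k-medoid clusters, columns LA / SA / OA.
PUBLISHED_CLUSTER_COUNTS = {
    1: {"LA": 174, "SA": 95, "OA": 16},
    2: {"LA": 4, "SA": 34, "OA": 40},
    3: {"LA": 9, "SA": 66, "OA": 33},
    4: {"LA": 8, "SA": 88, "OA": 6},
}

# Published pan-genome partition: 163 core / 37,784 accessory /
# 21,240 strain-specific families out of 59,187.
PUBLISHED_PARTITION = (163, 37_784, 21_240)

# Published majority-habitat concordance counts out of 573 strains.
PUBLISHED_CONCORDANT = {"LA": 168, "SA": 251, "OA": 81}


def assignment_from_counts(
    counts: dict[int, dict[str, int]],
) -> tuple[ClusterAssignment, dict[str, str]]:
    """Materialize a ClusterAssignment from per-cluster habitat counts."""
    labels: list[str] = []
    cluster_of: dict[str, int] = {}
    habitats: dict[str, str] = {}
    i = 0
    for c, row in counts.items():
        for h, n in row.items():
            for _ in range(n):
                i += 1
                sid = f"s{i:04d}"
                labels.append(sid)
                cluster_of[sid] = c
                habitats[sid] = h
    medoids = {}
    for c in counts:
        medoids[c] = next(s for s in labels if cluster_of[s] == c)
    assignment = ClusterAssignment(labels, cluster_of, medoids, len(counts), 0.0)
    return assignment, habitats


def euclidean_dm(
    points: np.ndarray, prefix: str = "s", ids: list[str] | None = None
) -> DistanceMatrix:
    if ids is None:
        ids = [f"{prefix}{i:03d}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(np.atleast_2d(points))), ids)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(
        n_strains_per_habitat={"LA": 12, "SA": 15, "OA": 8},
        n_core=20,
        n_accessory=30,
        n_specific=15,
        n_redundant_pairs=2,
        seed=3,
    )
    return simulate_cohort(cfg)
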