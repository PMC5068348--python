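"""Alpha diversity, dissimilarity metrics, and species accumulation.

Distances are returned as :class:`skbio.DistanceMatrix` objects (square,
symmetric, hollow, labeled), serialized as labeled square delimited text
(the ``lsmat`` format), which enforces strict symmetry on read.

Metrics follow the community-ecology conventions:

* Sorensen–Czekanowski binary dissimilarity ``1 - 2a / (2a + b + c)`` on
  presence/absence data, where ``a`` counts shared species and ``b``/``c``
  the species unique to each sample.  Algebraically identical to
  Bray–Curtis computed on binarized abundances.
* Bray–Curtis ``sum|x - y| / sum(x + y)`` on abundances.
* Euclidean distance for environmental variables, by default after
  z-standardizing each variable (units are heterogeneous).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import braycurtis as _sp_braycurtis
from scipy.spatial.distance import pdist, squareform
from scipy.stats import entropy as _entropy
from skbio import DistanceMatrix

from .community_data import CommunityMatrix, EnvironmentTable

__all__ = [
    "DistanceMatrix",
    "AccumulationCurve",
    "shannon_diversity",
    "species_richness",
    "sorensen_binary",
    "bray_curtis",
    "distance_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
    "species_accumulation",
]


def shannon_diversity(counts, base: float | None = None) -> float:
    """Shannon diversity index H' of one sample's abundance vector.

    H' = -sum p_i log p_i over species with positive counts, p_i being
    relative abundances.  Natural log (nats) by default.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    if x.sum() == 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    return float(_entropy(x, base=base))


def species_richness(counts) -> int:
    """Number of species with count > 0."""
    x = np.asarray(counts, dtype=float)
    return int((x > 0).sum())


def sorensen_binary(x, y) -> float:
    """Sorensen–Czekanowski binary dissimilarity between two samples.

    With a = shared presences, b and c = presences unique to each sample:
    ``1 - 2a / (2a + b + c)``.  Inputs are binarized internally.
    """
    bx = np.asarray(x, dtype=float) > 0
    by = np.asarray(y, dtype=float) > 0
    if not bx.any() or not by.any():
        raise ValueError("Sorensen dissimilarity undefined for empty samples")
    a = float(np.sum(bx & by))
    return 1.0 - 2.0 * a / (bx.sum() + by.sum())


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity sum|x-y| / sum(x+y)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.sum() == 0 or yv.sum() == 0:
        raise ValueError("Bray-Curtis dissimilarity undefined for empty samples")
    return float(_sp_braycurtis(xv, yv))


def distance_matrix(
    data: CommunityMatrix | EnvironmentTable,
    metric: str,
    standardize: bool = True,
) -> DistanceMatrix:
    """All pairwise dissimilarities among samples.

    ``metric`` is one of ``sorensen`` (binarizes internally),
    ``bray_curtis``, or ``euclidean``.  For ``euclidean`` (environment
    tables) variables are z-standardized first unless ``standardize=False``;
    constant variables are dropped from the computation.
    """
    if isinstance(data, EnvironmentTable):
        values = data.values.to_numpy(dtype=float)
        ids = data.sample_ids
    else:
        values = data.values()
        ids = data.sample_ids

    if metric in ("sorensen", "bray_curtis"):
        empties = [ids[i] for i in np.flatnonzero(values.sum(axis=1) == 0)]
        if empties:
            raise ValueError(
                f"all-zero sample(s) {empties} not allowed under {metric}; "
                "drop empty samples first"
            )
        if metric == "sorensen":
            values = (values > 0).astype(float)
        condensed = pdist(values, metric="braycurtis")
    elif metric == "euclidean":
        if standardize:
            mu = values.mean(axis=0)
            sd = values.std(axis=0, ddof=0)
            keep = sd > 0
            values = (values[:, keep] - mu[keep]) / sd[keep]
        condensed = pdist(values, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in ids])


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path), format="lsmat")


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.write(str(path), format="lsmat")


@dataclass
class AccumulationCurve:
    """Sample-based species accumulation curve.

    ``mean_richness[k-1]`` / ``sd_richness[k-1]`` give the mean and sd of
    cumulative species richness after k samples, over random orderings of
    the samples.
    """

    n_samples: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    n_orderings: int


def species_accumulation(
    cm: CommunityMatrix, n_orderings: int = 1000, seed: int = 0
) -> AccumulationCurve:
    """Randomized sample-order accumulation curve.

    For each k = 1..N, the mean and sd of cumulative richness over
    ``n_orderings`` random permutations of sample order.  The mean at k = N
    equals total observed richness regardless of ordering.
    """
    presence = (cm.values() > 0)
    n = presence.shape[0]
    rng = np.random.default_rng(seed)
    curves = np.empty((n_orderings, n))
    for r in range(n_orderings):
        order = rng.permutation(n)
        cum = np.logical_or.accumulate(presence[order], axis=0)
        curves[r] = cum.sum(axis=1)
    return AccumulationCurve(
        n_samples=np.arange(1, n + 1),
        mean_richness=curves.mean(axis=0),
        sd_richness=curves.std(axis=0, ddof=0),
        n_orderings=n_orderings,
    )
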