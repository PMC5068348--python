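"""Null-deviation analysis: how far does observed beta-diversity sit from
the beta-diversity of randomly assembled communities?

The null model assembles each sample *in silico* from the regional species
pool while holding two things fixed: the sample's observed richness (alpha)
and the pool itself (gamma).  Species are drawn without replacement with
probability proportional to their regional occurrence frequency (or
equiprobably).  The resulting randomized assemblages therefore differ from
the data only in *which* species co-occur — any departure of observed
beta-diversity from the null expectation reflects structure beyond what
alpha- and gamma-diversity alone impose.

The headline statistic is the null deviation

    ND = (beta_obs - beta_null) / beta_null

computed per group of samples, where beta is the mean pairwise
Sorensen–Czekanowski dissimilarity within the group and beta_null is the
mean over many (default 10,000) randomized assemblages.  |ND| near 0
suggests stochastic assembly; |ND| approaching 1 suggests deterministic
(niche-structured) assembly.

Weighted sampling without replacement uses exponential sort keys
(Efraimidis–Spirakis): taking the k smallest of Exp(1)/w_i is distributed
identically to k sequential draws with weight renormalization after each
draw, and vectorizes over thousands of randomizations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .community_data import CommunityMatrix
from .diversity import sorensen_binary  # noqa: F401  (re-exported convenience)

__all__ = [
    "NullModelConfig",
    "NullDeviationResult",
    "DegenerateNullError",
    "occurrence_frequencies",
    "randomize_assemblage",
    "group_beta_diversity",
    "per_sample_beta",
    "null_deviation_group",
    "replicate_null_deviation",
    "results_to_frame",
]


class DegenerateNullError(ValueError):
    """The null distribution of beta is degenerate (beta_null = 0)."""


@dataclass(frozen=True)
class NullModelConfig:
    """Settings for randomized-assemblage generation.

    Parameters
    ----------
    n_randomizations:
        Number of random assemblages over which beta_null is averaged.
    selection_weights:
        ``"occurrence_frequency"`` (species drawn proportionally to the
        fraction of samples they occupy regionally) or ``"equiprobable"``.
    seed:
        Seed for the randomization stream; recorded in every result.
    metric:
        Dissimilarity for beta; ``"sorensen"`` is the headline choice.
    """

    n_randomizations: int = 10_000
    selection_weights: str = "occurrence_frequency"
    seed: int = 0
    metric: str = "sorensen"

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.selection_weights not in ("occurrence_frequency", "equiprobable"):
            raise ValueError(f"unknown weighting {self.selection_weights!r}")
        if self.metric != "sorensen":
            raise ValueError("only the sorensen metric is supported for beta_null")


@dataclass
class NullDeviationResult:
    group: str
    beta_obs: float
    beta_null_mean: float
    beta_null_sd: float
    null_deviation: float
    n_randomizations: int
    seed: int
    replicate: int = 0


def occurrence_frequencies(cm: CommunityMatrix) -> pd.Series:
    """Regional occurrence frequency of every species.

    weight_i = (number of samples where species i is present) / (number of
    samples).  Species with weight 0 (observed nowhere) are excluded from
    the regional pool by all null-model operations.
    """
    presence = cm.counts > 0
    return presence.sum(axis=0) / cm.n_samples


def _pool_weights(cm: CommunityMatrix, config: NullModelConfig) -> pd.Series:
    freq = occurrence_frequencies(cm)
    pool = freq[freq > 0]
    if config.selection_weights == "equiprobable":
        pool = pd.Series(1.0, index=pool.index)
    return pool


def _weighted_subsets(
    richness: np.ndarray, weights: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_draws, n_samples, pool_size) boolean presence arrays.

    Each sample independently receives exactly its observed richness of
    species, drawn without replacement with probability proportional to
    ``weights`` (exponential-key equivalent of sequential renormalized
    draws).
    """
    n = len(richness)
    size = len(weights)
    out = np.zeros((n_draws, n, size), dtype=bool)
    draw_rows = np.arange(n_draws)
    for j, k in enumerate(richness):
        k = int(k)
        if k > size:
            raise ValueError(
                f"sample richness {k} exceeds regional pool size {size}"
            )
        if k == size:
            out[:, j, :] = True
            continue
        keys = rng.exponential(size=(n_draws, size)) / weights
        chosen = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[np.repeat(draw_rows, k), j, chosen.ravel()] = True
    return out


def _mean_pairwise_sorensen_batch(
    presence: np.ndarray, richness: np.ndarray
) -> np.ndarray:
    """Mean pairwise Sorensen dissimilarity for each draw in a batch.

    ``presence`` is (n_draws, n, S) boolean with fixed per-sample richness;
    the pairwise dissimilarity is 1 - 2a_ij / (k_i + k_j) where a_ij is the
    shared-species count.
    """
    p = presence.astype(np.float32)
    shared = np.matmul(p, np.transpose(p, (0, 2, 1)))
    k = richness.astype(np.float64)
    denom = k[:, None] + k[None, :]
    d = 1.0 - 2.0 * shared / denom
    iu = np.triu_indices(len(richness), k=1)
    return d[:, iu[0], iu[1]].mean(axis=1)


def randomize_assemblage(
    cm: CommunityMatrix,
    config: NullModelConfig,
    rng: np.random.Generator | None = None,
) -> CommunityMatrix:
    """One randomized presence/absence assemblage of the whole matrix.

    Per-sample richness and the regional pool are preserved exactly; only
    species identities are randomized.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = _pool_weights(cm, config)
    presence_obs = cm.values() > 0
    richness = presence_obs.sum(axis=1)
    if (richness == 0).any():
        empty = [cm.sample_ids[i] for i in np.flatnonzero(richness == 0)]
        raise ValueError(f"empty sample(s) {empty} cannot be randomized")
    drawn = _weighted_subsets(richness, weights.to_numpy(), 1, rng)[0]
    out = pd.DataFrame(
        0, index=cm.counts.index, columns=cm.counts.columns, dtype=int
    )
    out.loc[:, weights.index] = drawn.astype(int)
    return CommunityMatrix(out, cm.metadata.copy())


def group_beta_diversity(
    cm: CommunityMatrix, group: str, group_key: str = "group", metric: str = "sorensen"
) -> float:
    """Mean pairwise dissimilarity among the samples of one group."""
    ids = cm.groups(group_key).get(group)
    if ids is None:
        raise KeyError(f"no group {group!r} under metadata key {group_key!r}")
    if len(ids) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples")
    sub = cm.select_samples(ids)
    from .diversity import distance_matrix

    dm = distance_matrix(sub, metric=metric)
    return float(dm.condensed_form().mean())


def per_sample_beta(
    cm: CommunityMatrix, group: str, group_key: str = "group", metric: str = "sorensen"
) -> pd.Series:
    """Diagnostic: each sample's mean dissimilarity to its group-mates."""
    ids = cm.groups(group_key).get(group)
    if ids is None or len(ids) < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples")
    from .diversity import distance_matrix

    dm = distance_matrix(cm.select_samples(ids), metric=metric)
    data = dm.data
    n = data.shape[0]
    means = data.sum(axis=1) / (n - 1)
    return pd.Series(means, index=[str(i) for i in ids])


def null_deviation_group(
    cm: CommunityMatrix,
    group: str,
    config: NullModelConfig,
    group_key: str = "group",
) -> NullDeviationResult:
    """Null deviation (beta_obs - beta_null)/beta_null for one group.

    beta_obs is the mean pairwise Sorensen dissimilarity among the group's
    samples; beta_null averages the same quantity over
    ``config.n_randomizations`` randomized assemblages drawn from the
    regional pool of the full matrix.  Reproducible under a fixed seed.
    """
    ids = cm.groups(group_key).get(group)
    if ids is None:
        raise KeyError(f"no group {group!r} under metadata key {group_key!r}")
    if len(ids) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 samples")

    weights = _pool_weights(cm, config)
    sub = cm.select_samples(ids)
    presence = sub.values() > 0
    richness = presence.sum(axis=1)
    if (richness == 0).any():
        empty = [ids[i] for i in np.flatnonzero(richness == 0)]
        raise ValueError(f"empty sample(s) {empty} in group {group!r}")

    beta_obs = group_beta_diversity(cm, group, group_key=group_key, metric=config.metric)

    rng = np.random.default_rng(config.seed)
    w = weights.to_numpy(dtype=float)
    # batch the randomizations to bound memory on large pools
    batch = max(1, min(config.n_randomizations, 5000))
    betas = np.empty(config.n_randomizations)
    done = 0
    while done < config.n_randomizations:
        m = min(batch, config.n_randomizations - done)
        drawn = _weighted_subsets(richness, w, m, rng)
        betas[done : done + m] = _mean_pairwise_sorensen_batch(drawn, richness)
        done += m

    beta_null_mean = float(betas.mean())
    beta_null_sd = float(betas.std(ddof=1)) if len(betas) > 1 else 0.0
    if beta_null_mean == 0.0:
        raise DegenerateNullError(
            f"beta_null is 0 for group {group!r}: every randomized assemblage "
            "is identical (samples saturate the regional pool)"
        )
    nd = (beta_obs - beta_null_mean) / beta_null_mean
    return NullDeviationResult(
        group=str(group),
        beta_obs=beta_obs,
        beta_null_mean=beta_null_mean,
        beta_null_sd=beta_null_sd,
        null_deviation=nd,
        n_randomizations=config.n_randomizations,
        seed=config.seed,
    )


def replicate_null_deviation(
    cm: CommunityMatrix,
    groups: list | None = None,
    config: NullModelConfig = NullModelConfig(),
    n_replicates: int = 5,
    group_key: str = "group",
) -> list[NullDeviationResult]:
    """Independent replicate null-deviation runs for every group.

    Replicate r uses seed ``config.seed + r`` so replicates are independent
    but individually reproducible.  A single replicate with r = 0 equals a
    direct :func:`null_deviation_group` call at the base seed.
    """
    if groups is None:
        groups = sorted(cm.groups(group_key))
    results = []
    for r in range(n_replicates):
        cfg = replace(config, seed=config.seed + r)
        for group in groups:
            res = null_deviation_group(cm, group, cfg, group_key=group_key)
            res.replicate = r
            results.append(res)
    return results


def results_to_frame(results: list[NullDeviationResult]) -> pd.DataFrame:
    """Long-format table of null-deviation results."""
    return pd.DataFrame(
        {
            "group": [r.group for r in results],
            "replicate": [r.replicate for r in results],
            "beta_obs": [r.beta_obs for r in results],
            "beta_null_mean": [r.beta_null_mean for r in results],
            "beta_null_sd": [r.beta_null_sd for r in results],
            "null_deviation": [r.null_deviation for r in results],
            "n_randomizations": [r.n_randomizations for r in results],
            "seed": [r.seed for r in results],
        }
    )
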