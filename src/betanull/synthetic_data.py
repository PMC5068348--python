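"""Synthetic chronosequence communities under neutral vs. filtered assembly.

The generator emulates a disturbance chronosequence sampled for two
fractions of a ground-dwelling arthropod community: an "aboveground"
fraction (pitfall-trap style: larger regional pool, richer samples) and a
"belowground" fraction (soil-extraction style: smaller pool, sparser
samples), with a few species shared between the pools.

Assembly model
--------------
A regional pool of ``gamma`` species gets lognormal relative abundances
(the canonical species-abundance distribution for arthropod assemblages)
and niche optima uniform on a one-dimensional environment axis [0, 1].
Each sample receives a Poisson-distributed richness (truncated to
[1, gamma]) and its members are drawn without replacement with selection
weight

    w_i  ∝  abundance_i * exp(-F * (optimum_i - env)^2 / (2 * breadth^2))

where ``F`` is the filtering strength and ``breadth`` the niche breadth.
F = 0 is the neutral limit: composition depends only on regional
abundances, so samples differ by dispersal chance alone.  Large F makes
samples at the same environment converge on the species whose optima match
it — the deterministic (environmental-filtering) regime.  Abundances of
the selected species are Poisson around the pool's relative-abundance
profile.

The default scenario mirrors a five-year tree-mortality chronosequence:
5 groups (years), 8 aboveground samples per year (7 in the last),
6 belowground samples per year, pools of 23 and 20 species with 4 shared,
mean within-sample richness ~11 aboveground and ~5 belowground, and a
monotone environment gradient across years with correlated and pure-noise
covariates in the environment table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community_data import CommunityMatrix, EnvironmentTable

__all__ = [
    "RegionalPool",
    "FractionConfig",
    "AssemblyScenario",
    "SyntheticDataset",
    "generate_regional_pool",
    "assemble_neutral",
    "assemble_filtered",
    "generate_chronosequence_dataset",
    "default_scenario",
]


@dataclass
class RegionalPool:
    """Regional species pool: relative abundances and niche optima."""

    species_ids: list[str]
    relative_abundance: np.ndarray
    niche_optima: np.ndarray

    @property
    def gamma(self) -> int:
        return len(self.species_ids)

    def subset(self, indices) -> "RegionalPool":
        idx = np.asarray(indices)
        ab = self.relative_abundance[idx]
        return RegionalPool(
            [self.species_ids[i] for i in idx],
            ab / ab.sum(),
            self.niche_optima[idx],
        )


def generate_regional_pool(
    gamma: int, abundance_shape: float = 1.0, seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> RegionalPool:
    """Lognormal species-abundance distribution with uniform niche optima.

    ``abundance_shape`` is the lognormal sigma: 0 gives an even community,
    larger values increasingly dominance-skewed (~1 is typical for
    arthropod assemblages).
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=abundance_shape, size=gamma)
    optima = rng.uniform(0.0, 1.0, size=gamma)
    return RegionalPool(
        [f"sp{i + 1:02d}" for i in range(gamma)], raw / raw.sum(), optima
    )


def _truncated_poisson_richness(
    mean: float, n: int, gamma: int, rng: np.random.Generator
) -> np.ndarray:
    richness = rng.poisson(mean, size=n)
    return np.clip(richness, 1, gamma)


def _weighted_choice_wor(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    # exponential-key sampling == sequential renormalized weighted draws
    keys = rng.exponential(size=len(weights)) / weights
    return np.argpartition(keys, k - 1)[:k] if k < len(weights) else np.arange(len(weights))


def assemble_filtered(
    pool: RegionalPool,
    n_samples: int,
    richness_mean: float,
    env_value: float,
    filtering_strength: float,
    niche_breadth: float,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    individuals_per_sample: float = 150.0,
    sample_ids: list[str] | None = None,
) -> CommunityMatrix:
    """Assemble samples under Gaussian environmental filtering.

    Selection weight of species i is
    ``abundance_i * exp(-F (optimum_i - env)^2 / (2 breadth^2))``; with
    ``filtering_strength=0`` this reduces exactly to neutral assembly (the
    random stream is identical, so the same seed yields the same output).
    """
    if richness_mean > pool.gamma:
        raise ValueError("richness_mean exceeds pool size")
    if niche_breadth <= 0:
        raise ValueError("niche_breadth must be positive")
    if filtering_strength < 0:
        raise ValueError("filtering_strength must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    gauss = np.exp(
        -filtering_strength
        * (pool.niche_optima - env_value) ** 2
        / (2.0 * niche_breadth ** 2)
    )
    weights = pool.relative_abundance * gauss
    richness = _truncated_poisson_richness(richness_mean, n_samples, pool.gamma, rng)

    counts = np.zeros((n_samples, pool.gamma), dtype=int)
    for s in range(n_samples):
        members = _weighted_choice_wor(weights, int(richness[s]), rng)
        rel = pool.relative_abundance[members]
        lam = individuals_per_sample * rel / rel.sum()
        counts[s, members] = 1 + rng.poisson(lam)
    if sample_ids is None:
        sample_ids = [f"s{i + 1:02d}" for i in range(n_samples)]
    df = pd.DataFrame(counts, index=sample_ids, columns=pool.species_ids)
    return CommunityMatrix(df)


def assemble_neutral(
    pool: RegionalPool,
    n_samples: int,
    richness_mean: float,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    individuals_per_sample: float = 150.0,
    sample_ids: list[str] | None = None,
) -> CommunityMatrix:
    """Neutral assembly: membership by regional abundance alone."""
    return assemble_filtered(
        pool,
        n_samples,
        richness_mean,
        env_value=0.5,  # irrelevant at F = 0
        filtering_strength=0.0,
        niche_breadth=1.0,
        seed=seed,
        rng=rng,
        individuals_per_sample=individuals_per_sample,
        sample_ids=sample_ids,
    )


@dataclass
class FractionConfig:
    """Per-fraction assembly regime within a scenario."""

    name: str
    pool_size: int
    samples_per_group: list[int]
    richness_mean: float
    filtering_strength: float = 0.0
    niche_breadth: float = 0.3


@dataclass
class AssemblyScenario:
    """Full specification of a synthetic chronosequence dataset."""

    n_groups: int = 5
    env_gradient: list[float] = field(
        default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0]
    )
    abundance_shape: float = 1.0
    n_shared_species: int = 4
    env_noise_sd: float = 0.05
    seed: int = 0
    fractions: list[FractionConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.env_gradient) != self.n_groups:
            raise ValueError("env_gradient length must equal n_groups")
        for fr in self.fractions:
            if len(fr.samples_per_group) != self.n_groups:
                raise ValueError(
                    f"fraction {fr.name!r}: samples_per_group length must "
                    "equal n_groups"
                )
            if fr.richness_mean > fr.pool_size:
                raise ValueError(f"fraction {fr.name!r}: richness exceeds pool")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AssemblyScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["fractions"] = [FractionConfig(**f) for f in raw.get("fractions", [])]
        return cls(**raw)


def default_scenario(
    seed: int = 0,
    aboveground_filtering: float = 4.0,
    belowground_filtering: float = 0.0,
    niche_breadth: float = 0.3,
) -> AssemblyScenario:
    """Five-year chronosequence mirroring a paired pitfall/soil design.

    Aboveground: pool 23, samples per year (8,8,8,8,7), mean richness 11,
    filtered by default.  Belowground: pool 20, 6 samples per year, mean
    richness 5, neutral by default.  4 species shared between pools.
    """
    return AssemblyScenario(
        seed=seed,
        fractions=[
            FractionConfig(
                name="aboveground",
                pool_size=23,
                samples_per_group=[8, 8, 8, 8, 7],
                richness_mean=11.0,
                filtering_strength=aboveground_filtering,
                niche_breadth=niche_breadth,
            ),
            FractionConfig(
                name="belowground",
                pool_size=20,
                samples_per_group=[6, 6, 6, 6, 6],
                richness_mean=5.0,
                filtering_strength=belowground_filtering,
                niche_breadth=niche_breadth,
            ),
        ],
    )


@dataclass
class SyntheticDataset:
    community: CommunityMatrix
    environment: EnvironmentTable
    truth: dict


def generate_chronosequence_dataset(scenario: AssemblyScenario) -> SyntheticDataset:
    """Generate community + environment tables for a whole scenario.

    One combined regional pool covers all fractions; each fraction draws
    from a contiguous slice so that ``n_shared_species`` species belong to
    both pools (their union plays the role of total regional richness).
    Every group (chronosequence year) is assembled at its environment
    value under the fraction's regime.  The environment table carries the
    noisy gradient, two covariates correlated with it, and two pure-noise
    covariates.  Fully reproducible from the scenario's seed.
    """
    rng = np.random.default_rng(scenario.seed)
    sizes = [fr.pool_size for fr in scenario.fractions]
    total = sum(sizes) - scenario.n_shared_species * max(0, len(sizes) - 1)
    master = generate_regional_pool(total, scenario.abundance_shape, rng=rng)

    # contiguous, overlapping slices of the master pool
    slices = []
    start = 0
    for fr in scenario.fractions:
        slices.append(np.arange(start, start + fr.pool_size))
        start += fr.pool_size - scenario.n_shared_species

    frames, meta_rows, env_rows = [], [], []
    for fr, idx in zip(scenario.fractions, slices):
        pool = master.subset(idx)
        for g in range(scenario.n_groups):
            n = fr.samples_per_group[g]
            env = scenario.env_gradient[g]
            ids = [f"{fr.name[:2]}_y{g}_s{i + 1}" for i in range(n)]
            cm = assemble_filtered(
                pool,
                n,
                fr.richness_mean,
                env_value=env,
                filtering_strength=fr.filtering_strength,
                niche_breadth=fr.niche_breadth,
                rng=rng,
                sample_ids=ids,
            )
            frames.append(cm.counts)
            for sid in ids:
                meta_rows.append(
                    {"sample": sid, "group": f"year{g}", "fraction": fr.name}
                )
                local_env = env + rng.normal(0.0, scenario.env_noise_sd)
                env_rows.append(
                    {
                        "sample": sid,
                        "gradient": local_env,
                        "veg_cover": 2.0 * local_env
                        + rng.normal(0.0, 0.3),
                        "soil_n": 1.0 + 0.8 * local_env + rng.normal(0.0, 0.2),
                        "moisture": rng.normal(0.5, 0.15),
                        "ph": rng.normal(6.0, 0.4),
                    }
                )

    counts = (
        pd.concat(frames)
        .reindex(columns=master.species_ids)
        .fillna(0)
        .astype(int)
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    env = pd.DataFrame(env_rows).set_index("sample")
    truth = {
        "scenario": asdict(scenario),
        "pool": {
            "species_ids": master.species_ids,
            "relative_abundance": master.relative_abundance.tolist(),
            "niche_optima": master.niche_optima.tolist(),
        },
    }
    return SyntheticDataset(
        community=CommunityMatrix(counts, metadata),
        environment=EnvironmentTable(env),
        truth=truth,
    )
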