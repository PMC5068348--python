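"""End-to-end analysis: transform -> PERMANOVA -> null deviation ->
permutation tests -> Mantel, with a written report bundle.

The stages mirror the standard null-deviation workflow for a grouped,
two-fraction community survey:

1. optional binning of repeated sampling events into one grand sample,
2. per-sample diversity summary (richness, Shannon H'),
3. per-fraction one-way PERMANOVA on log-relativized Bray-Curtis
   distances across groups, with pairwise PERMANOVA only when the one-way
   p < 0.05,
4. replicate null-deviation runs per group x fraction,
5. within-group two-group permutation tests comparing the fractions'
   null-deviation values,
6. Mantel (and per-variable partial Mantel) tests of community Sorensen
   distances against Euclidean environment distances.

Every run records its seed and configuration in a machine-readable
manifest so results are reproducible from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community_data import (
    CommunityMatrix,
    EnvironmentTable,
    bin_temporal_replicates,
    binarize,
    log_relativize,
    read_community_table,
    read_environment_table,
    read_metadata_table,
    write_community_table,
    write_environment_table,
)
from .diversity import distance_matrix, shannon_diversity, species_richness
from .null_deviation import (
    NullModelConfig,
    replicate_null_deviation,
    results_to_frame,
)
from .permutation_tests import (
    mantel_test,
    pairwise_permanova,
    partial_mantel_test,
    permanova_one_way,
    two_group_permutation_test,
)
from .synthetic_data import AssemblyScenario, generate_chronosequence_dataset

__all__ = ["AnalysisConfig", "AnalysisResults", "run_analysis", "write_report"]

PERMANOVA_COLUMNS = ["Community", "Source", "df", "SS", "MSE", "F", "P"]


@dataclass
class AnalysisConfig:
    """All knobs of one analysis run."""

    community_path: str | None = None
    metadata_path: str | None = None
    environment_path: str | None = None
    scenario_path: str | None = None

    group_key: str = "group"
    fraction_key: str = "fraction"
    event_key: str | None = None  # bin over this metadata column if set
    unit_key: str | None = None

    n_randomizations: int = 10_000
    n_replicates: int = 5
    n_permutations: int = 9999
    selection_weights: str = "occurrence_frequency"
    permanova_alpha: float = 0.05

    out_dir: str = "betanull_out"
    seed: int = 0
    make_figure: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class AnalysisResults:
    config: AnalysisConfig
    diversity_summary: pd.DataFrame
    permanova_tables: dict[str, pd.DataFrame]
    pairwise_tables: dict[str, pd.DataFrame]
    null_deviation: pd.DataFrame
    nd_tests: pd.DataFrame
    mantel: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _load_inputs(
    config: AnalysisConfig,
) -> tuple[CommunityMatrix, EnvironmentTable | None]:
    if config.scenario_path:
        scenario = AssemblyScenario.from_yaml(config.scenario_path)
        ds = generate_chronosequence_dataset(scenario)
        return ds.community, ds.environment
    if not config.community_path or not config.metadata_path:
        raise ValueError("need community+metadata paths or a scenario")
    metadata = read_metadata_table(config.metadata_path)
    cm = read_community_table(config.community_path, metadata=metadata)
    env = (
        read_environment_table(config.environment_path)
        if config.environment_path
        else None
    )
    return cm, env


def _diversity_summary(cm: CommunityMatrix) -> pd.DataFrame:
    rows = []
    for sid in cm.sample_ids:
        counts = cm.counts.loc[sid].to_numpy()
        rows.append(
            {
                "sample": sid,
                "richness": species_richness(counts),
                "shannon_h": shannon_diversity(counts) if counts.sum() else np.nan,
                **cm.metadata.loc[sid].to_dict(),
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def _drop_empty(cm: CommunityMatrix) -> CommunityMatrix:
    keep = cm.counts.sum(axis=1) > 0
    return cm.select_samples(list(cm.counts.index[keep]))


def run_analysis(config: AnalysisConfig) -> AnalysisResults:
    """Run the full pipeline; raises with a stage-named message on error."""
    stage = "load"
    try:
        cm, env = _load_inputs(config)
        if config.event_key and config.unit_key:
            stage = "binning"
            cm = bin_temporal_replicates(cm, config.event_key, config.unit_key)
        cm = _drop_empty(cm)

        stage = "diversity"
        diversity = _diversity_summary(cm)

        fractions = (
            sorted(cm.metadata[config.fraction_key].unique())
            if config.fraction_key in cm.metadata.columns
            else [None]
        )

        def fraction_cm(fraction):
            if fraction is None:
                return cm
            ids = cm.metadata.index[cm.metadata[config.fraction_key] == fraction]
            return cm.select_samples(list(ids))

        stage = "permanova"
        permanova_tables: dict[str, pd.DataFrame] = {}
        pairwise_tables: dict[str, pd.DataFrame] = {}
        for fraction in fractions:
            sub = fraction_cm(fraction)
            transformed = log_relativize(sub)
            dm = distance_matrix(transformed, metric="bray_curtis")
            grouping = sub.metadata[config.group_key]
            grouping.index = grouping.index.astype(str)
            res = permanova_one_way(
                dm, grouping, config.n_permutations, config.seed
            )
            name = str(fraction) if fraction is not None else "all"
            permanova_tables[name] = res.to_table(community=name)
            if res.p_value < config.permanova_alpha:
                entries = pairwise_permanova(
                    dm, grouping, config.n_permutations, config.seed
                )
                pairwise_tables[name] = pd.DataFrame(
                    {
                        "group_a": [e.group_a for e in entries],
                        "group_b": [e.group_b for e in entries],
                        "df": [e.result.df_among for e in entries],
                        "F": [e.result.pseudo_F for e in entries],
                        "P": [e.result.p_value for e in entries],
                        "P_adjusted": [e.p_adjusted for e in entries],
                    }
                )

        stage = "null_deviation"
        nd_frames = []
        for fraction in fractions:
            sub = fraction_cm(fraction)
            cfg = NullModelConfig(
                n_randomizations=config.n_randomizations,
                selection_weights=config.selection_weights,
                seed=config.seed,
            )
            results = replicate_null_deviation(
                binarize(sub),
                config=cfg,
                n_replicates=config.n_replicates,
                group_key=config.group_key,
            )
            frame = results_to_frame(results)
            frame.insert(1, "fraction", str(fraction) if fraction else "all")
            nd_frames.append(frame)
        nd_table = pd.concat(nd_frames, ignore_index=True)

        stage = "nd_permutation_tests"
        nd_tests = _nd_fraction_tests(nd_table, config)

        stage = "mantel"
        mantel_table = (
            _mantel_tests(cm, env, fractions, config)
            if env is not None
            else pd.DataFrame(
                columns=["fraction", "test", "controlled", "r", "P", "n_permutations"]
            )
        )

        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "n_samples": cm.n_samples,
            "n_species": cm.n_species,
        }
        return AnalysisResults(
            config=config,
            diversity_summary=diversity,
            permanova_tables=permanova_tables,
            pairwise_tables=pairwise_tables,
            null_deviation=nd_table,
            nd_tests=nd_tests,
            mantel=mantel_table,
            manifest=manifest,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _nd_fraction_tests(nd_table: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Within-group two-sided permutation tests between the two fractions."""
    fractions = sorted(nd_table["fraction"].unique())
    if len(fractions) != 2:
        return pd.DataFrame(
            columns=["group", "fraction_a", "fraction_b", "observed_diff", "P"]
        )
    fa, fb = fractions
    rows = []
    for group, sub in nd_table.groupby("group", sort=True):
        a = sub.loc[sub["fraction"] == fa, "null_deviation"].to_numpy()
        b = sub.loc[sub["fraction"] == fb, "null_deviation"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        res = two_group_permutation_test(
            a, b, n_permutations=config.n_permutations, seed=config.seed
        )
        rows.append(
            {
                "group": group,
                "fraction_a": fa,
                "fraction_b": fb,
                "observed_diff": res.observed_diff,
                "P": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
    return pd.DataFrame(rows)


def _mantel_tests(
    cm: CommunityMatrix,
    env: EnvironmentTable,
    fractions,
    config: AnalysisConfig,
) -> pd.DataFrame:
    rows = []
    for fraction in fractions:
        if fraction is None:
            sub = cm
        else:
            ids = cm.metadata.index[cm.metadata[config.fraction_key] == fraction]
            sub = cm.select_samples(list(ids))
        env_sub = env.select_samples(sub.sample_ids)
        dx = distance_matrix(sub, metric="sorensen")
        dy = distance_matrix(env_sub, metric="euclidean")
        res = mantel_test(dx, dy, config.n_permutations, config.seed)
        name = str(fraction) if fraction is not None else "all"
        rows.append(
            {
                "fraction": name,
                "test": "mantel",
                "controlled": "",
                "r": res.r,
                "P": res.p_value,
                "n_permutations": res.n_permutations,
            }
        )
        # per-variable partial Mantel: that variable's distances,
        # controlling for the distances of the remaining variables
        for var in env_sub.variables:
            if len(env_sub.variables) < 2:
                break
            only = EnvironmentTable(env_sub.values[[var]])
            rest = EnvironmentTable(env_sub.values.drop(columns=[var]))
            d_var = distance_matrix(only, metric="euclidean")
            d_rest = distance_matrix(rest, metric="euclidean")
            try:
                pres = partial_mantel_test(
                    dx, d_var, d_rest, config.n_permutations, config.seed,
                    controlled="other_variables",
                )
            except ValueError:
                continue
            rows.append(
                {
                    "fraction": name,
                    "test": f"partial_mantel:{var}",
                    "controlled": "other_variables",
                    "r": pres.r,
                    "P": pres.p_value,
                    "n_permutations": pres.n_permutations,
                }
            )
    return pd.DataFrame(rows)


def write_report(results: AnalysisResults, out_dir: str | Path) -> list[Path]:
    """Write the report bundle; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index)
        written.append(path)

    _write(results.diversity_summary, "diversity_summary.csv", index=True)
    if results.permanova_tables:
        _write(
            pd.concat(results.permanova_tables.values(), ignore_index=True)[
                PERMANOVA_COLUMNS
            ],
            "permanova.csv",
        )
    else:
        _write(pd.DataFrame(columns=PERMANOVA_COLUMNS), "permanova.csv")
    for name, table in results.pairwise_tables.items():
        _write(table, f"pairwise_permanova_{name}.csv")
    _write(results.null_deviation, "null_deviation.csv")
    _write(results.nd_tests, "nd_permutation_tests.csv")
    _write(results.mantel, "mantel.csv")

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(results.manifest, fh, indent=2, default=str)
    written.append(manifest_path)

    summary_path = out / "summary.txt"
    with open(summary_path, "w") as fh:
        fh.write(_text_summary(results))
    written.append(summary_path)

    if results.config.make_figure and not results.null_deviation.empty:
        written.append(_nd_figure(results.null_deviation, out / "null_deviation.png"))
    return written


def _text_summary(results: AnalysisResults) -> str:
    lines = [f"betanull {__version__} analysis (seed={results.config.seed})", ""]
    for name, table in results.permanova_tables.items():
        f = table.loc[0, "F"]
        p = table.loc[0, "P"]
        lines.append(f"PERMANOVA [{name}]: F = {f:.3f}, P = {p:.4g}")
    lines.append("")
    if not results.null_deviation.empty:
        nd = (
            results.null_deviation.groupby(["fraction", "group"])["null_deviation"]
            .mean()
            .round(4)
        )
        lines.append("Mean null deviation by fraction x group:")
        lines.extend(f"  {frac} {grp}: {val}" for (frac, grp), val in nd.items())
    lines.append("")
    for _, row in results.nd_tests.iterrows():
        lines.append(
            f"ND test [{row['group']}]: diff = {row['observed_diff']:.4f}, "
            f"P = {row['P']:.4g}"
        )
    lines.append("")
    for _, row in results.mantel.iterrows():
        lines.append(
            f"Mantel [{row['fraction']} {row['test']}]: r = {row['r']:.3f}, "
            f"P = {row['P']:.4g}"
        )
    return "\n".join(lines) + "\n"


def _nd_figure(nd_table: pd.DataFrame, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for fraction, sub in nd_table.groupby("fraction"):
        means = sub.groupby("group")["null_deviation"].mean()
        ax.plot(means.index, means.values, marker="o", label=fraction)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("group")
    ax.set_ylabel("null deviation")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def simulate_to_dir(scenario: AssemblyScenario, out_dir: str | Path) -> list[Path]:
    """Materialize a scenario as the package's delimited formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = generate_chronosequence_dataset(scenario)
    write_community_table(ds.community, out / "community.csv")
    ds.community.metadata.to_csv(out / "metadata.csv")
    write_environment_table(ds.environment, out / "environment.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=2)
    return [
        out / "community.csv",
        out / "metadata.csv",
        out / "environment.csv",
        out / "truth.json",
    ]
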