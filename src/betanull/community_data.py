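"""Site-by-species community matrices and their transformations.

The central container is :class:`CommunityMatrix`: a samples x species table
of non-negative counts (or transformed abundances) together with per-sample
metadata such as chronosequence year ("group") and community fraction
(e.g. aboveground / belowground).  All downstream analyses — dissimilarity
matrices, null models, permutation tests — consume this type.

Transformations provided here:

* :func:`bin_temporal_replicates` — sum repeated sampling events (e.g. early
  and late season collections from the same focal tree) into one grand
  sample per sampling unit.
* :func:`binarize` — reduce abundances to presence/absence.
* :func:`log_relativize` — log10(x + 1) transform followed by relativization
  of each species column by its maximum, the standard pre-treatment before
  abundance-based ordination/PERMANOVA when total abundances differ widely
  among samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CommunityMatrix",
    "EnvironmentTable",
    "CommunityValidationError",
    "read_community_table",
    "write_community_table",
    "read_metadata_table",
    "read_environment_table",
    "write_environment_table",
    "bin_temporal_replicates",
    "binarize",
    "log_relativize",
]


class CommunityValidationError(ValueError):
    """Raised when a community matrix or environment table is malformed."""


def _infer_sep(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _check_unique(labels, kind: str) -> None:
    dupes = pd.Index(labels)[pd.Index(labels).duplicated()].unique().tolist()
    if dupes:
        raise CommunityValidationError(f"duplicate {kind} labels: {dupes}")


@dataclass
class CommunityMatrix:
    """Samples x species abundance table with per-sample metadata.

    Parameters
    ----------
    counts:
        DataFrame indexed by sample id, columns are species ids.  Entries
        must be numeric and non-negative (integers for raw abundances,
        reals after transformation).
    metadata:
        Optional DataFrame indexed by the same sample ids mapping metadata
        keys (e.g. ``group``, ``fraction``, ``event``) to values.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        _check_unique(self.counts.index, "sample")
        _check_unique(self.counts.columns, "species")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = self.counts.map(
                lambda v: not isinstance(v, (int, float, np.number))
            )
            loc = np.argwhere(bad.to_numpy())
            if loc.size:
                i, j = loc[0]
                raise CommunityValidationError(
                    f"non-numeric entry at sample "
                    f"{self.counts.index[i]!r}, species {self.counts.columns[j]!r}"
                )
            self.counts = self.counts.astype(float)
            values = self.counts.to_numpy()
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise CommunityValidationError(
                f"missing value at sample {self.counts.index[i]!r}, "
                f"species {self.counts.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise CommunityValidationError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"species {self.counts.columns[j]!r}"
            )
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.counts.index.copy())
        else:
            if not isinstance(self.metadata, pd.DataFrame):
                self.metadata = pd.DataFrame(self.metadata)
            missing = self.counts.index.difference(self.metadata.index)
            if len(missing):
                raise CommunityValidationError(
                    f"samples missing from metadata: {missing.tolist()}"
                )
            self.metadata = self.metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def with_metadata(self, metadata: pd.DataFrame) -> "CommunityMatrix":
        return CommunityMatrix(self.counts.copy(), metadata)

    def select_samples(self, sample_ids) -> "CommunityMatrix":
        return CommunityMatrix(
            self.counts.loc[list(sample_ids)].copy(),
            self.metadata.loc[list(sample_ids)].copy(),
        )

    def groups(self, key: str) -> dict:
        """Map each level of metadata column *key* to its sample ids."""
        if key not in self.metadata.columns:
            raise KeyError(f"metadata has no column {key!r}")
        return {
            level: list(ids)
            for level, ids in self.metadata.groupby(key, sort=True).groups.items()
        }

    def is_binary(self) -> bool:
        v = self.values()
        return bool(np.isin(v, (0.0, 1.0)).all())


@dataclass
class EnvironmentTable:
    """Samples x environmental-variables table (all numeric, no missing)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        _check_unique(self.values.index, "sample")
        _check_unique(self.values.columns, "variable")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CommunityValidationError("environment table must be numeric")
        if np.isnan(arr).any():
            i, j = np.argwhere(np.isnan(arr))[0]
            raise CommunityValidationError(
                f"missing value at sample {self.values.index[i]!r}, "
                f"variable {self.values.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def variables(self) -> list:
        return list(self.values.columns)

    def select_samples(self, sample_ids) -> "EnvironmentTable":
        return EnvironmentTable(self.values.loc[list(sample_ids)].copy())

    def matches(self, cm: CommunityMatrix) -> bool:
        return set(self.sample_ids) == set(cm.sample_ids)


# ---------------------------------------------------------------------------
# I/O — delimited text (CSV/TSV), UTF-8, header row + leading label column.
# ---------------------------------------------------------------------------

def read_community_table(
    path: str | Path,
    samples_in_rows: bool = True,
    metadata: pd.DataFrame | None = None,
    sep: str | None = None,
) -> CommunityMatrix:
    """Read a delimited site-by-species table.

    The file must have one header row and one leading label column.  With
    ``samples_in_rows=False`` the file is transposed on read (species in
    rows, samples in columns).
    """
    sep = sep or _infer_sep(path)
    df = pd.read_csv(path, index_col=0, sep=sep)
    if not samples_in_rows:
        df = df.T
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise CommunityValidationError(
                f"non-numeric value in species column {col!r}: {exc}"
            ) from exc
    return CommunityMatrix(df, metadata)


def write_community_table(
    cm: CommunityMatrix, path: str | Path, sep: str | None = None
) -> None:
    cm.counts.to_csv(path, sep=sep or _infer_sep(path))


def read_metadata_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, sep=sep or _infer_sep(path))
    _check_unique(df.index, "sample")
    return df


def read_environment_table(path: str | Path, sep: str | None = None) -> EnvironmentTable:
    df = pd.read_csv(path, index_col=0, sep=sep or _infer_sep(path))
    return EnvironmentTable(df)


def write_environment_table(
    env: EnvironmentTable, path: str | Path, sep: str | None = None
) -> None:
    env.values.to_csv(path, sep=sep or _infer_sep(path))


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def bin_temporal_replicates(
    cm: CommunityMatrix, event_label: str, unit_label: str
) -> CommunityMatrix:
    """Sum repeated sampling events into one grand sample per unit.

    Counts for all samples sharing the same *unit_label* value (e.g. focal
    tree) are summed species-wise across sampling events; the event column
    is dropped.  All other metadata must agree within a unit.
    """
    for key in (event_label, unit_label):
        if key not in cm.metadata.columns:
            raise KeyError(f"metadata has no column {key!r}")
    units = cm.metadata[unit_label]
    summed = cm.counts.groupby(units, sort=True).sum()
    summed.index.name = cm.counts.index.name

    other = cm.metadata.drop(columns=[event_label])
    rows = {}
    for unit, sub in other.groupby(unit_label, sort=True):
        nun = sub.drop(columns=[unit_label]).nunique(dropna=False)
        conflicting = nun[nun > 1].index.tolist()
        if conflicting:
            raise CommunityValidationError(
                f"conflicting metadata {conflicting} within unit {unit!r}"
            )
        rows[unit] = sub.drop(columns=[unit_label]).iloc[0]
    meta = pd.DataFrame(rows).T.reindex(summed.index)
    return CommunityMatrix(summed, meta)


def binarize(cm: CommunityMatrix) -> CommunityMatrix:
    """Presence/absence: 1 where count > 0, else 0."""
    binary = (cm.counts > 0).astype(int)
    return CommunityMatrix(binary, cm.metadata.copy())


def log_relativize(
    cm: CommunityMatrix, base: float = 10.0, per_species: bool = True
) -> CommunityMatrix:
    """log(x + 1) transform, then relativize by the maximum abundance.

    Each entry becomes ``log_base(x + 1)``; by default each species column
    is then divided by that column's maximum transformed value (general
    relativization by column maximum), so every non-empty column peaks at
    1.0.  With ``per_species=False`` a single global maximum is used
    instead.  Columns whose maximum is 0 stay all-zero.
    """
    logged = np.log1p(cm.values()) / np.log(base)
    if per_species:
        colmax = logged.max(axis=0)
        scale = np.where(colmax > 0, colmax, 1.0)
        rel = logged / scale
    else:
        gmax = logged.max()
        rel = logged / gmax if gmax > 0 else logged
    out = pd.DataFrame(rel, index=cm.counts.index, columns=cm.counts.columns)
    return CommunityMatrix(out, cm.metadata.copy())
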