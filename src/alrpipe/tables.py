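"""Core table types shared across the pipeline.

Two data containers move through every stage: :class:`CountTable` holds the
raw (or filtered) sample-by-feature count matrix together with the
two-population sample labels, and :class:`ALRTable` holds the log-ratio
transformed real matrix with its reference-feature identity and scaling
state.  Both serialize to plain tab-delimited text.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

FEATURE_KINDS = ("KEGG", "COG", "phylum", "family", "genus", "species", "synthetic")


class TableError(ValueError):
    """Raised when a table violates its structural invariants."""


@dataclass
class CountTable:
    """Samples x features non-negative integer counts with population labels.

    Parameters
    ----------
    sample_ids : sequence of str
        One identifier per row of ``counts``.
    feature_ids : sequence of str
        One identifier per column of ``counts``.
    counts : ndarray of shape (n_samples, n_features)
        Non-negative integer matrix.
    population : sequence of str
        Per-sample label; exactly two distinct levels must be present.
    feature_kind : str
        One of ``KEGG, COG, phylum, family, genus, species, synthetic``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray
    population: np.ndarray
    feature_kind: str = "synthetic"

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        self.feature_ids = list(map(str, self.feature_ids))
        self.counts = np.asarray(self.counts)
        self.population = np.asarray(self.population, dtype=object)
        if self.counts.ndim != 2:
            raise TableError("counts must be a 2-D matrix")
        n, p = self.counts.shape
        if n != len(self.sample_ids):
            raise TableError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if p != len(self.feature_ids):
            raise TableError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(self.population) != n:
            raise TableError("population labels must match sample count")
        if np.any(self.counts < 0):
            raise TableError("counts must be non-negative")
        if self.feature_kind not in FEATURE_KINDS:
            raise TableError(f"unknown feature_kind {self.feature_kind!r}")
        if len(self.population_levels()) != 2:
            raise TableError("exactly two population levels are required")

    # -- structure helpers -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def population_levels(self) -> list[str]:
        """The two population labels in sorted order."""
        return sorted(set(map(str, self.population)))

    def group_masks(self) -> dict[str, np.ndarray]:
        return {lvl: np.asarray([str(x) == lvl for x in self.population])
                for lvl in self.population_levels()}

    def select_samples(self, mask: np.ndarray) -> "CountTable":
        mask = np.asarray(mask)
        return CountTable(
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            feature_ids=list(self.feature_ids),
            counts=self.counts[mask],
            population=self.population[mask],
            feature_kind=self.feature_kind,
        )

    def select_features(self, mask_or_ids) -> "CountTable":
        if isinstance(mask_or_ids, (list, tuple)) and mask_or_ids and isinstance(mask_or_ids[0], str):
            keep = [self.feature_ids.index(f) for f in mask_or_ids]
        else:
            keep = np.flatnonzero(np.asarray(mask_or_ids))
        return CountTable(
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[i] for i in keep],
            counts=self.counts[:, keep],
            feature_kind=self.feature_kind,
            population=self.population,
        )

    # -- I/O ---------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.feature_ids)

    def write(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        """Write counts and sample metadata as tab-delimited text."""
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(counts_path, sep="\t")
        meta = pd.DataFrame({"sample_id": self.sample_ids,
                             "population": list(map(str, self.population))})
        meta.to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path: str | Path, metadata_path: str | Path,
             feature_kind: str = "synthetic") -> "CountTable":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t")
        meta = meta.set_index("sample_id").loc[df.index]
        return cls(
            sample_ids=list(df.index.astype(str)),
            feature_ids=list(df.columns.astype(str)),
            counts=df.to_numpy(),
            population=meta["population"].astype(str).to_numpy(),
            feature_kind=feature_kind,
        )


@dataclass
class ALRTable:
    """Log-ratio transformed real matrix (reference column removed).

    ``values[i, j] = ln(x[i, j]) - ln(x[i, ref])``; the reference feature is
    not among ``feature_ids``.  When ``scaled`` is True the recorded
    ``scale_means``/``scale_sds`` allow exact back-transformation.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    reference_id: str
    population: np.ndarray
    scaled: bool = False
    scale_means: np.ndarray | None = None
    scale_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.population = np.asarray(self.population, dtype=object)
        if self.reference_id in self.feature_ids:
            raise TableError("reference feature must not appear among ALR columns")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise TableError("values shape does not match id lists")
        if self.scaled and (self.scale_means is None or self.scale_sds is None):
            raise TableError("scaled table must record scale_means and scale_sds")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def population_levels(self) -> list[str]:
        return sorted(set(map(str, self.population)))

    def select_features(self, feature_ids: Sequence[str]) -> "ALRTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return dataclasses.replace(
            self,
            feature_ids=[self.feature_ids[i] for i in idx],
            values=self.values[:, idx],
            scale_means=None if self.scale_means is None else self.scale_means[idx],
            scale_sds=None if self.scale_sds is None else self.scale_sds[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def write(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
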