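"""Core containers: expression matrices and sample annotation.

An :class:`OmicsMatrix` is a feature-by-sample table of expression values
(RNA counts, FPKM, or protein intensities) with explicit missing-value
support (NaN internally, ``NA`` on disk) and a scale tag declaring whether
values are linear, counts, or log2. A :class:`SampleAnnotation` carries the
per-animal covariates: diet group, week, proteomics batch, and the ordinal
liver fibrosis score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: Recognised value scales for an OmicsMatrix.
SCALES = ("linear", "counts", "log2")


@dataclass
class OmicsMatrix:
    """Feature x sample expression matrix.

    Parameters
    ----------
    values
        DataFrame with feature ids as index and sample ids as columns.
        Missing values are NaN; no sentinel numbers.
    scale
        One of ``"linear"``, ``"counts"``, ``"log2"``.
    kind
        Free-text label of the matrix ("liver_rna", "liver_protein",
        "plasma_protein", ...), carried through the pipeline for reporting.
    """

    values: pd.DataFrame
    scale: str = "linear"
    kind: str = ""

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.values = self.values.astype(float)

    # -- convenience accessors -------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing-value mask (True where missing)."""
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        """New matrix with same scale/kind but different values."""
        return replace(self, values=values)

    def log2(self, pseudocount: float = 0.0) -> "OmicsMatrix":
        """Return a log2-transformed copy of a linear/count matrix."""
        if self.scale == "log2":
            return self
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log2(self.values + pseudocount)
        vals[self.values + pseudocount <= 0] = np.nan
        out = OmicsMatrix(vals, scale="log2", kind=self.kind)
        return out

    # -- I/O -------------------------------------------------------------------
    def to_tsv(self, path: str | Path, feature_col: str = "feature_id") -> None:
        df = self.values.copy()
        df.index.name = feature_col
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")

    @classmethod
    def from_tsv(
        cls, path: str | Path, scale: str = "linear", kind: str = ""
    ) -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        return cls(df, scale=scale, kind=kind)


@dataclass
class SampleAnnotation:
    """Per-sample covariates keyed by sample id.

    Columns: ``group`` (diet arm), ``week`` (time point), ``batch``
    (proteomics run), ``fibrosis_score`` (ordinal histology grade >= 0).
    """

    table: pd.DataFrame

    REQUIRED = ("group", "week", "batch", "fibrosis_score")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in annotation")
        if (self.table["fibrosis_score"] < 0).any():
            raise ValueError("fibrosis_score must be >= 0")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def subset(self, samples: Iterable[str]) -> "SampleAnnotation":
        samples = list(samples)
        unknown = [s for s in samples if s not in self.table.index]
        if unknown:
            raise KeyError(f"samples not in annotation: {unknown[:5]}")
        return SampleAnnotation(self.table.loc[samples])

    def group_samples(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def check_covers(self, m: OmicsMatrix) -> None:
        """Raise if any matrix sample lacks an annotation row."""
        unknown = [s for s in m.samples if s not in self.table.index]
        if unknown:
            raise KeyError(f"matrix samples missing from annotation: {unknown[:5]}")

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleAnnotation":
        return cls(pd.read_csv(path, sep="\t", index_col="sample_id"))
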