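"""Reading and writing the tabular formats used throughout the pipeline.

All tables are plain TSV: tab separated, UTF-8, header row, first column the
gene/probe identifier, the string ``NA`` denoting a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Controlled vocabulary of cardiac region labels.
REGIONS = frozenset({"LA", "RA", "LV", "RV", "V", "SA", "PV", "PA", "LAA"})

LINEAR = "linear"
LOG2 = "log2"

_METADATA_COLUMNS = ("species", "region", "individual_id", "platform_id")


@dataclass
class ExpressionMatrix:
    """A gene-by-sample expression matrix with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe) id with one column per sample.
        May contain NaN before :func:`cardiospm.preprocess.drop_incomplete_rows`
        is applied; must be finite otherwise.
    scale
        ``"linear"`` (non-negative intensities / TPM) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = LOG2

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite")
        if self.scale == LINEAR:
            with np.errstate(invalid="ignore"):
                if (arr < 0).any():
                    g, s = np.argwhere(arr < 0)[0]
                    raise ValueError(
                        "negative linear-scale value at gene "
                        f"{self.values.index[g]!r}, sample {self.values.columns[s]!r}"
                    )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.scale if scale is None else scale)


@dataclass
class CountTable:
    """Raw gene counts plus gene lengths (bp), the inputs to TPM."""

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        lengths = self.gene_lengths.reindex(self.counts.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][0]
            raise ValueError(f"no length for gene {missing!r}")
        if (lengths <= 0).any():
            bad = lengths.index[lengths <= 0][0]
            raise ValueError(f"non-positive length for gene {bad!r}")
        self.gene_lengths = lengths.astype(float)


def read_expression_tsv(path: str | Path, scale: str = LOG2) -> ExpressionMatrix:
    """Read a genes-by-samples expression TSV (``NA`` = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return ExpressionMatrix(df.astype(float), scale)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV and validate it.

    Requires columns ``sample_id``, ``species``, ``region``, ``individual_id``
    and ``platform_id``; returns a DataFrame indexed by ``sample_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_metadata(df)


def validate_sample_metadata(df: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample metadata missing columns {missing}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    if df[list(_METADATA_COLUMNS)].isna().any().any():
        raise ValueError("sample metadata contains missing fields")
    bad = set(df["region"]) - REGIONS
    if bad:
        raise ValueError(f"unknown region label(s) {sorted(bad)}; allowed: {sorted(REGIONS)}")
    return df


def write_sample_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_probe_map(path: str | Path) -> pd.Series:
    """Read a probe-to-gene TSV (columns ``probe_id``, ``gene_id``).

    Many probes may map to one gene, but each probe maps to exactly one gene.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("probe map needs two columns (probe_id, gene_id)")
    probes, genes = df.iloc[:, 0], df.iloc[:, 1]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise ValueError(f"probe {dup!r} maps to more than one gene")
    return pd.Series(genes.to_numpy(), index=pd.Index(probes, name="probe_id"), name="gene_id")


def read_count_table(counts_path: str | Path, lengths_path: str | Path) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountTable(counts, lengths)
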