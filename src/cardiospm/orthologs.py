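"""Cross-species comparison through many-to-many ortholog tables.

Ortholog tables are Biomart-style exports: two columns of gene ids, one row
per ortholog pair, many-to-many permitted.  The x-species is always the
indexing species; when one x gene maps to several y genes, the y values are
averaged.  Averaging makes the mapping asymmetric, so the direction is an
explicit part of every table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class OrthologTable:
    """Pairwise many-to-many ortholog correspondence between two species."""

    x_species: str
    y_species: str
    pairs: pd.DataFrame  # columns x_gene, y_gene

    def __post_init__(self) -> None:
        if list(self.pairs.columns[:2]) != ["x_gene", "y_gene"]:
            self.pairs = self.pairs.iloc[:, :2].set_axis(["x_gene", "y_gene"], axis=1)
        if self.pairs.isna().any().any() or (self.pairs == "").any().any():
            raise ValueError("ortholog table contains empty gene ids")
        if self.pairs.duplicated().any():
            raise ValueError("ortholog table contains duplicate (x_gene, y_gene) rows")

    @classmethod
    def from_tsv(cls, path: str | Path, x_species: str, y_species: str) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError("ortholog TSV needs at least two columns")
        return cls(x_species, y_species, df)

    def to_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)

    def reversed(self) -> "OrthologTable":
        rev = self.pairs.rename(columns={"x_gene": "y_gene", "y_gene": "x_gene"})
        return OrthologTable(self.y_species, self.x_species, rev[["x_gene", "y_gene"]])

    def y_genes_of(self, x_gene: str) -> list[str]:
        return list(self.pairs.loc[self.pairs["x_gene"] == x_gene, "y_gene"])


@dataclass
class MappedProfilePair:
    """x-indexed paired values after ortholog mapping and y-side averaging."""

    x_genes: pd.Index
    x_values: np.ndarray
    y_values: np.ndarray
    n_mapped: int
    n_dropped: int


def map_orthologs(
    x_values: pd.Series, y_values: pd.Series, table: OrthologTable
) -> MappedProfilePair:
    """Pair x-species values with ortholog-averaged y-species values.

    For every x gene with at least one ortholog that has a y value, the
    paired y value is the arithmetic mean over its mapped y genes; x genes
    without any mapped y value are dropped and counted.
    """
    if table.pairs.empty:
        raise ValueError("ortholog table is empty")
    pairs = table.pairs[
        table.pairs["x_gene"].isin(x_values.index)
        & table.pairs["y_gene"].isin(y_values.index)
    ]
    y_mapped = (
        y_values.loc[pairs["y_gene"]]
        .set_axis(pairs["x_gene"])
        .groupby(level=0)
        .mean()
    )
    x_genes = x_values.index.intersection(y_mapped.index)
    n_dropped = len(x_values) - len(x_genes)
    return MappedProfilePair(
        x_genes=x_genes,
        x_values=x_values.loc[x_genes].to_numpy(dtype=float),
        y_values=y_mapped.loc[x_genes].to_numpy(dtype=float),
        n_mapped=len(x_genes),
        n_dropped=n_dropped,
    )


def interspecies_spearman(
    means_x: pd.DataFrame,
    means_y: pd.DataFrame,
    table: OrthologTable,
    region: str,
) -> float:
    """Spearman correlation of a region's expression across two species.

    Pairs the x-species region means with ortholog-averaged y-species means
    and returns the rank correlation (mid-ranks for ties).
    """
    for means, species in ((means_x, table.x_species), (means_y, table.y_species)):
        if region not in means.columns:
            raise ValueError(f"region {region!r} absent from {species} profile")
    mapped = map_orthologs(means_x[region], means_y[region], table)
    if mapped.n_mapped < 3:
        raise ValueError(f"only {mapped.n_mapped} mapped pairs; need >= 3")
    if np.unique(mapped.x_values).size < 2 or np.unique(mapped.y_values).size < 2:
        raise ValueError("zero rank variance in one species; correlation undefined")
    rho, _ = stats.spearmanr(mapped.x_values, mapped.y_values)
    return float(rho)


def _specific_lookup(calls: pd.DataFrame) -> set[tuple[str, str]]:
    sp = calls[calls["is_specific"]]
    return set(zip(sp["gene"], sp["region"]))


def categorize_specific_sets(
    calls_by_species: dict[str, pd.DataFrame],
    tables: list[OrthologTable],
    reference: str = "human",
) -> pd.DataFrame:
    """Classify every specific call as species-common, pairwise or selective.

    For each species' (gene, region) specific call, the other two species
    "agree" when ANY ortholog of the gene (through the relevant pairwise
    table) is specific for the same region there.  Categories:

    - ``common_all``      — both other species agree;
    - ``pairwise(a,b)``   — exactly one other species agrees (the pair is
      sorted alphabetically);
    - ``selective(s)``    — neither agrees.

    A gene with no ortholog in a species cannot be supported by it, so it can
    never be ``common_all`` through that species.  The output partitions each
    species' specific list: one row per specific call, with columns
    ``species, gene, region, category, supporting_species``.  ``reference``
    controls row ordering only (reference species first).
    """
    species = list(calls_by_species)
    if reference not in species:
        raise ValueError(f"reference species {reference!r} has no calls")
    lookup = {s: _specific_lookup(c) for s, c in calls_by_species.items()}
    # ortholog adjacency in both directions, keyed by (from_species, to_species)
    edges: dict[tuple[str, str], pd.DataFrame] = {}
    for t in tables:
        edges[(t.x_species, t.y_species)] = t.pairs
        edges[(t.y_species, t.x_species)] = t.reversed().pairs
    ordered = [reference] + sorted(s for s in species if s != reference)
    rows = []
    for s in ordered:
        others = [o for o in species if o != s]
        grouped = {}
        for o in others:
            key = (s, o)
            if key not in edges:
                raise ValueError(f"no ortholog table linking {s} and {o}")
            grouped[o] = edges[key].groupby("x_gene")["y_gene"].agg(list)
        sp_calls = calls_by_species[s]
        sp_calls = sp_calls[sp_calls["is_specific"]]
        for gene, region in zip(sp_calls["gene"], sp_calls["region"]):
            supporting = []
            for o in others:
                orthologs = grouped[o].get(gene, [])
                if any((y, region) in lookup[o] for y in orthologs):
                    supporting.append(o)
            if len(supporting) == len(others):
                category = "common_all"
            elif supporting:
                pair = ",".join(sorted([s] + supporting))
                category = f"pairwise({pair})"
            else:
                category = f"selective({s})"
            rows.append((s, gene, region, category, ";".join(sorted(supporting))))
    return pd.DataFrame(
        rows, columns=["species", "gene", "region", "category", "supporting_species"]
    )


def annotate_and_rank(
    genes: set[str], spm: pd.DataFrame, region: str, tf_set: set[str], k: int = 5
) -> list[str]:
    """Top-k transcription factors among ``genes``, ranked by SPM in ``region``.

    Ties in SPM are broken lexicographically by gene id.
    """
    tfs = sorted(g for g in genes & tf_set if g in spm.index)
    if not tfs:
        return []
    ranked = sorted(tfs, key=lambda g: (-spm.at[g, region], g))
    return ranked[:k]
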