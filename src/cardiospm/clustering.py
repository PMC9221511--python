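"""Hierarchical clustering of samples and of SPM profiles.

Both clusterings use 1 - Spearman correlation as the distance (range [0, 2])
with average linkage, which is deterministic given the input column order.
Sample clustering groups the columns of one platform's expression matrix;
SPM-profile clustering groups species-region pairs by their specificity
profiles over the reference-species genes that have orthologs in every
species — the cross-platform view in which region signal, not platform,
should dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from .io import ExpressionMatrix
from .orthologs import OrthologTable, map_orthologs


@dataclass
class Dendrogram:
    """An average-linkage merge tree over labelled leaves."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster assignment cutting the tree into ``k`` clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_tree(self) -> TreeNode:
        return TreeNode.from_linkage_matrix(self.linkage, self.labels)

    def to_newick(self, path: str | Path | None = None) -> str:
        newick = str(self.to_tree()).strip()
        if path is not None:
            Path(path).write_text(newick + "\n")
        return newick


def spearman_distance_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """1 - Spearman correlation between the columns of ``df``."""
    if df.shape[1] < 2:
        raise ValueError("need at least two columns to compute distances")
    arr = df.to_numpy(dtype=float)
    constant = np.all(arr == arr[0, :], axis=0)
    if constant.any():
        bad = df.columns[constant][0]
        raise ValueError(f"constant column {bad!r}: Spearman distance undefined")
    rho = stats.spearmanr(arr, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    # symmetrise away floating-point asymmetry before squareform
    dist = (dist + dist.T) / 2.0
    return pd.DataFrame(dist, index=df.columns, columns=df.columns)


def _average_linkage(dist: pd.DataFrame) -> Dendrogram:
    condensed = squareform(dist.to_numpy(), checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage, [str(c) for c in dist.columns])


def cluster_samples(m: ExpressionMatrix) -> Dendrogram:
    """Cluster a platform's samples by 1 - Spearman of expression columns."""
    if m.n_samples < 2:
        raise ValueError("need at least two samples to cluster")
    return _average_linkage(spearman_distance_matrix(m.values))


def build_spm_profile_set(
    spm_by_species: dict[str, pd.DataFrame],
    tables: list[OrthologTable],
    reference: str = "human",
) -> pd.DataFrame:
    """SPM profiles for every species-region pair over a shared gene index.

    Restricts to reference-species genes with at least one ortholog carrying
    an SPM value in every other species; non-reference SPMs are mapped onto
    the reference index with ortholog averaging.  Returns a DataFrame indexed
    by reference gene with one ``species:region`` column per pair (three
    species x three regions = nine profiles in the default design).
    """
    if reference not in spm_by_species:
        raise ValueError(f"no SPM table for reference species {reference!r}")
    ref_spm = spm_by_species[reference]
    by_direction = {(t.x_species, t.y_species): t for t in tables}
    for t in tables:
        by_direction.setdefault((t.y_species, t.x_species), t.reversed())
    columns: dict[str, pd.Series] = {}
    shared = ref_spm.index
    mapped_all: dict[str, pd.DataFrame] = {reference: ref_spm}
    for species, spm in spm_by_species.items():
        if species == reference:
            continue
        key = (reference, species)
        if key not in by_direction:
            raise ValueError(f"no ortholog table linking {reference} and {species}")
        table = by_direction[key]
        mapped_cols = {}
        for region in spm.columns:
            pair = map_orthologs(ref_spm[region], spm[region], table)
            mapped_cols[region] = pd.Series(pair.y_values, index=pair.x_genes)
        mapped = pd.DataFrame(mapped_cols)
        mapped_all[species] = mapped
        shared = shared.intersection(mapped.index)
    if len(shared) == 0:
        raise ValueError("no reference genes with orthologs in every species")
    for species, spm in mapped_all.items():
        for region in spm.columns:
            columns[f"{species}:{region}"] = spm.loc[shared, region]
    return pd.DataFrame(columns, index=shared)


def cluster_spm_profiles(profiles: pd.DataFrame) -> Dendrogram:
    """Cluster species-region SPM profiles by 1 - Spearman distance."""
    if profiles.shape[1] < 2:
        raise ValueError("need at least two profiles to cluster")
    if profiles.shape[0] < 3:
        raise ValueError("profiles too short for rank correlation (need >= 3 genes)")
    return _average_linkage(spearman_distance_matrix(profiles))


def region_purity(dendrogram: Dendrogram, k: int) -> float:
    """Purity of a k-cluster cut with respect to region labels.

    Leaf labels must be ``species:region`` pairs.  Purity is the fraction of
    leaves belonging to the majority region of their cluster — 1.0 means the
    cut separates regions perfectly regardless of species/platform.
    """
    cut = dendrogram.cut(k)
    regions = pd.Series(
        [label.split(":", 1)[1] for label in cut.index], index=cut.index
    )
    correct = 0
    for _, members in regions.groupby(cut):
        correct += members.value_counts().iloc[0]
    return correct / len(regions)
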