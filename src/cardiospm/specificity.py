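"""Region-specificity statistics: SPM, ANOVA gating, permutation threshold.

The specificity measure (SPM) of gene *g* in region *r* is

    SPM_{g,r} = m_{g,r} / ||m_g||_2

where ``m_g`` is the vector of per-region mean log2 expression values.  SPM is
the cosine between the mean-expression vector and the region's coordinate
axis: it lies in [0, 1] for non-negative means, the squares over regions sum
to one, and SPM = 1 means expression confined to that region.  Because SPM is
scale-invariant it is comparable across platforms with different units.

A gene is called region-specific when its SPM exceeds a permutation-derived
null threshold AND its across-region one-way ANOVA Benjamini–Hochberg
adjusted p-value falls below ``alpha``.  The null threshold tau is the 95th
percentile of SPM values recomputed after one uniform random permutation of
the sample-to-region labels per gene, pooled across all genes and regions of
the dataset.

The module exposes the individual operations as functions plus a
statsmodels-style pair :class:`RegionSpecificity` / :class:`RegionSpecificityResults`
wrapping the whole stage.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_REGIONS = ("LA", "V", "SA")
DEFAULT_MERGES = {"LV": "V", "RV": "V"}


@dataclass(frozen=True)
class RegionDesign:
    """Assignment of analysis samples to regions, after merge rules.

    Samples whose (merged) region is outside ``regions`` are excluded from
    the specificity analysis (they may still be used for sample clustering).
    """

    assignments: pd.Series  # sample_id -> region, analysis samples only
    regions: tuple[str, ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        extra = set(self.assignments.unique()) - set(self.regions)
        if extra:
            raise ValueError(f"assignments contain unknown regions {sorted(extra)}")
        if len(self.regions) < 2:
            raise ValueError("need at least two regions for specificity testing")
        counts = self.assignments.value_counts()
        empty = [r for r in self.regions if counts.get(r, 0) == 0]
        if empty:
            raise ValueError(f"region(s) {empty} have no samples")

    @classmethod
    def from_metadata(
        cls,
        metadata: pd.DataFrame,
        regions: tuple[str, ...] = DEFAULT_REGIONS,
        merges: dict[str, str] | None = None,
    ) -> "RegionDesign":
        """Build a design from a sample-metadata table (see :mod:`cardiospm.io`).

        ``merges`` maps raw labels onto analysis regions; by default the left
        and right ventricle are pooled into V.  Samples mapping outside
        ``regions`` (e.g. RA, PV, PA, LAA) are dropped from the design.
        """
        merges = DEFAULT_MERGES if merges is None else merges
        merged = metadata["region"].replace(merges)
        keep = merged.isin(regions)
        return cls(merged[keep], tuple(regions))

    @property
    def sample_ids(self) -> pd.Index:
        return self.assignments.index

    def indicator(self) -> pd.DataFrame:
        """Samples-by-regions 0/1 membership matrix (columns ordered as regions)."""
        ind = pd.get_dummies(self.assignments).astype(float)
        return ind.reindex(columns=list(self.regions), fill_value=0.0)


def region_means(m: ExpressionMatrix, design: RegionDesign) -> pd.DataFrame:
    """Per-gene arithmetic mean expression of each region (genes x regions)."""
    missing = design.sample_ids.difference(m.sample_ids)
    if len(missing):
        raise ValueError(f"design samples absent from matrix: {list(missing)[:5]}")
    values = m.values[design.sample_ids]
    means = values.T.groupby(design.assignments).mean().T
    return means.reindex(columns=list(design.regions))


def compute_spm(means: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """SPM per gene and region from the region-mean matrix.

    Returns ``(spm, excluded_genes)`` where excluded genes are those with an
    all-zero mean vector (SPM undefined at the origin).  Negative means are
    rejected: the statistic is only meaningful for non-negative (log2 of
    pseudocounted) expression.
    """
    arr = means.to_numpy(dtype=float)
    if (arr < 0).any():
        g = means.index[np.argwhere(arr < 0)[0][0]]
        raise ValueError(f"negative region mean for gene {g!r}; SPM requires means >= 0")
    norms = np.sqrt((arr**2).sum(axis=1))
    zero = norms == 0
    excluded = list(means.index[zero])
    if excluded:
        logger.info("excluding %d all-zero genes from SPM", len(excluded))
    spm = means.loc[~zero].div(norms[~zero], axis=0)
    return spm, excluded


def anova_per_gene(m: ExpressionMatrix, design: RegionDesign) -> pd.DataFrame:
    """One-way fixed-effects ANOVA across regions, per gene.

    Returns a DataFrame with columns ``F``, ``p``, ``adj_p`` (BH) and
    ``degenerate``.  Zero total variance (identical values everywhere) gives
    p = 1 with the degenerate flag set; zero within-group variance with
    unequal group means gives p = 0.
    """
    k = len(design.regions)
    n = len(design.sample_ids)
    if n <= k:
        raise ValueError("need more samples than regions for ANOVA")
    values = m.values[design.sample_ids]
    groups = [
        values.loc[:, design.assignments == r].to_numpy() for r in design.regions
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*groups, axis=1)
    # rows with no variance at all: no evidence of regional difference
    total_var = values.var(axis=1, ddof=0).to_numpy()
    degenerate = total_var == 0
    f_stat = np.asarray(f_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    f_stat[degenerate] = 0.0
    p[degenerate] = 1.0
    # zero within-group variance with unequal means -> F = inf -> p = 0
    p[np.isinf(f_stat)] = 0.0
    bad = ~np.isfinite(p)
    if bad.any():  # residual numerical pathologies, treated as uninformative
        p[bad] = 1.0
        f_stat[bad] = np.nan
    out = pd.DataFrame(
        {"F": f_stat, "p": p, "adj_p": bh_adjust(p), "degenerate": degenerate},
        index=m.gene_ids,
    )
    return out


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) over the ascending order
    statistics.  Agrees with statsmodels' ``fdr_bh`` to floating precision.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    scaled = arr[order] * m / np.arange(1, m + 1)
    q = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = q
    return out


@dataclass
class NullSPMDistribution:
    """Pooled permutation-null SPM values and the derived threshold."""

    null_spms: np.ndarray
    tau: float
    seed: int
    percentile: float = 95.0
    tag: str = ""

    def to_json(self, path: str | Path) -> None:
        summary = {
            "tag": self.tag,
            "seed": self.seed,
            "percentile": self.percentile,
            "percentile_convention": "linear interpolation",
            "n_null": int(self.null_spms.size),
            "tau": self.tau,
        }
        Path(path).write_text(json.dumps(summary, indent=2) + "\n")


def permutation_null_threshold(
    m: ExpressionMatrix,
    design: RegionDesign,
    seed: int,
    percentile: float = 95.0,
    tag: str = "",
) -> NullSPMDistribution:
    """Null SPM distribution from one label permutation per gene.

    For each gene independently, the sample-to-region labels are permuted
    uniformly (region sizes preserved by construction), region means and all
    |R| SPM values are recomputed, and the values from every gene and region
    are pooled.  tau is the ``percentile``-th percentile of the pool.
    Deterministic given ``seed``; the generator is consumed in gene order.
    """
    rng = np.random.default_rng(seed)
    values = m.values[design.sample_ids].to_numpy(dtype=float)
    # permuting each gene's values across samples == permuting its labels
    permuted = rng.permuted(values, axis=1)
    ind = design.indicator().to_numpy()
    counts = ind.sum(axis=0)
    means = permuted @ ind / counts
    norms = np.sqrt((means**2).sum(axis=1, keepdims=True))
    keep = norms[:, 0] > 0
    null_spms = (means[keep] / norms[keep]).ravel()
    tau = float(np.percentile(null_spms, percentile))
    return NullSPMDistribution(null_spms, tau, seed, percentile, tag)


def call_specific_genes(
    spm: pd.DataFrame,
    tests: pd.DataFrame,
    null: NullSPMDistribution,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine the SPM threshold and the ANOVA/BH gate into per-gene calls.

    Returns a long DataFrame with one row per (gene, region): columns
    ``SPM``, ``adj_p``, ``tau``, ``is_specific``, ``multi_region``.  A gene
    is specific for region r iff SPM_{g,r} > tau and adj_p_g < alpha.  When
    tau < 1/sqrt(2) more than one region can exceed tau; then only the region
    of maximal SPM is called, flagged ``multi_region``.
    """
    missing = spm.index.difference(tests.index)
    if len(missing):
        raise ValueError(f"genes missing from ANOVA results: {list(missing)[:5]}")
    adj_p = tests.loc[spm.index, "adj_p"]
    exceeds = spm.gt(null.tau).to_numpy()
    passes_p = (adj_p < alpha).to_numpy()
    multi = exceeds.sum(axis=1) > 1
    is_max = spm.eq(spm.max(axis=1), axis=0).to_numpy()
    specific_arr = exceeds & (~multi[:, None] | is_max) & passes_p[:, None]
    specific = pd.DataFrame(specific_arr, index=spm.index, columns=spm.columns)
    rows = []
    for region in spm.columns:
        rows.append(
            pd.DataFrame(
                {
                    "gene": spm.index,
                    "region": region,
                    "SPM": spm[region].to_numpy(),
                    "adj_p": adj_p.to_numpy(),
                    "tau": null.tau,
                    "is_specific": specific[region].to_numpy(),
                    "multi_region": multi & specific[region].to_numpy(),
                }
            )
        )
    calls = pd.concat(rows, ignore_index=True)
    return calls.sort_values(["gene", "region"], kind="mergesort").reset_index(drop=True)


def zscore_spm(spm: pd.DataFrame) -> pd.DataFrame:
    """Standardise SPM within each region column (mean 0, sd 1, ddof=1).

    Used for cross-platform heatmaps where each species-region pair is a
    column.  Zero-variance columns become all-zero with a warning.
    """
    if spm.shape[0] < 2:
        raise ValueError("need at least two genes per column to z-score")
    mean = spm.mean(axis=0)
    sd = spm.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning("zero-variance SPM column(s) %s set to 0", list(spm.columns[zero]))
        sd = sd.replace(0, np.nan)
    z = spm.sub(mean, axis=1).div(sd, axis=1)
    return z.fillna(0.0)


class RegionSpecificity:
    """Region-specificity model for one species/platform dataset.

    Built from a preprocessed (log2-scale, filtered) expression matrix and a
    region design; :meth:`fit` runs region means, SPM, per-gene ANOVA with BH
    adjustment, the permutation-null SPM threshold and the specific-gene
    calls, and returns a :class:`RegionSpecificityResults`.
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        design: RegionDesign,
        alpha: float = 0.05,
        null_percentile: float = 95.0,
        tag: str = "",
    ) -> None:
        if data.scale != "log2":
            raise ValueError("RegionSpecificity expects log2-scale data")
        self.data = data
        self.design = design
        self.alpha = alpha
        self.null_percentile = null_percentile
        self.tag = tag

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        metadata: pd.DataFrame,
        regions: tuple[str, ...] = DEFAULT_REGIONS,
        merges: dict[str, str] | None = None,
        **kwargs,
    ) -> "RegionSpecificity":
        design = RegionDesign.from_metadata(metadata, regions, merges)
        return cls(ExpressionMatrix(values, "log2"), design, **kwargs)

    def fit(self, seed: int) -> "RegionSpecificityResults":
        means = region_means(self.data, self.design)
        spm, excluded = compute_spm(means)
        tests = anova_per_gene(self.data, self.design)
        null = permutation_null_threshold(
            self.data, self.design, seed, self.null_percentile, self.tag
        )
        calls = call_specific_genes(spm, tests, null, self.alpha)
        return RegionSpecificityResults(self, means, spm, excluded, tests, null, calls)


@dataclass
class RegionSpecificityResults:
    """Fitted region-specificity results for one dataset."""

    model: RegionSpecificity
    region_means: pd.DataFrame
    spm: pd.DataFrame
    excluded_genes: list[str]
    anova: pd.DataFrame
    null: NullSPMDistribution
    calls: pd.DataFrame

    @property
    def tau(self) -> float:
        return self.null.tau

    def specific_genes(self, region: str) -> list[str]:
        c = self.calls
        return sorted(c.loc[(c["region"] == region) & c["is_specific"], "gene"])

    def specific_table(self) -> pd.DataFrame:
        return self.calls[self.calls["is_specific"]].reset_index(drop=True)

    def zscore_spm(self) -> pd.DataFrame:
        return zscore_spm(self.spm)

    def summary(self) -> str:
        d = self.model.design
        lines = [
            "Region specificity results" + (f" [{self.model.tag}]" if self.model.tag else ""),
            "=" * 50,
            f"genes analysed:        {self.model.data.n_genes}"
            + (f"  ({len(self.excluded_genes)} excluded, zero mean)" if self.excluded_genes else ""),
            f"samples / regions:     {len(d.sample_ids)} / {', '.join(d.regions)}",
            f"SPM null threshold:    tau = {self.tau:.4f}"
            f"  ({self.null.percentile:g}th pct of {self.null.null_spms.size} null SPMs, seed {self.null.seed})",
            f"ANOVA gate:            BH adj_p < {self.model.alpha:g}"
            f"  ({int((self.anova['adj_p'] < self.model.alpha).sum())} genes pass)",
            "-" * 50,
            "specific genes per region:",
        ]
        for region in d.regions:
            n = int(
                ((self.calls["region"] == region) & self.calls["is_specific"]).sum()
            )
            lines.append(f"  {region:<4} {n}")
        return "\n".join(lines)

    def to_tsv(self, directory: str | Path, prefix: str = "") -> None:
        """Write SPM table, calls table and null summary into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        wide = self.spm.join(self.anova[["F", "p", "adj_p"]])
        wide.to_csv(directory / f"{prefix}spm.tsv", sep="\t", float_format="%.10g")
        self.calls.to_csv(
            directory / f"{prefix}calls.tsv", sep="\t", index=False, float_format="%.10g"
        )
        self.null.to_json(directory / f"{prefix}null.json")
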