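"""Synthetic multi-species, multi-platform cardiac expression datasets.

The generator emulates the structure of the study design the pipeline was
built for: three species measured on three different platforms, heart regions
LA / V / SA (ventricular samples emitted as LV and RV to exercise the merge
rule), a few replicates per region, log2-scale expression with additive
region effects planted on known specific genes, per-platform location/scale
shifts, platform-specific gene dropout, and a many-to-many ortholog graph.
Every planted gene carries a conservation category (``common_all``,
``pairwise(a,b)`` or ``selective(s)``) recorded in :class:`SyntheticTruth`,
so recovery of the whole pipeline can be scored exactly.

One seeded generator per dataset, consumed in a documented order (baselines,
planting, per-species sample values, dropout, ortholog extras); identical
config + seed gives byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import TF_TERM, AnnotationTable
from .io import ExpressionMatrix, write_expression_tsv, write_sample_metadata
from .orthologs import OrthologTable

_PREFIX = {"human": "HSA", "mouse": "MMU", "rat": "RNO"}
_PLATFORM_NAME = {
    "human": "rnaseq_novaseq",
    "mouse": "illumina_beadchip",
    "rat": "agilent_surepint",
}


@dataclass
class PlatformParams:
    """Per-platform distortions applied on the log2 scale."""

    shift: float = 0.0  # additive location offset
    scale: float = 1.0  # multiplicative gain on the biological signal
    dropout: float = 0.05  # probability a gene is absent from the platform


def _default_platforms() -> dict[str, PlatformParams]:
    return {
        "human": PlatformParams(shift=0.0, scale=1.0, dropout=0.03),
        "mouse": PlatformParams(shift=1.5, scale=1.2, dropout=0.05),
        "rat": PlatformParams(shift=-1.0, scale=0.9, dropout=0.05),
    }


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the modelled study: three species on three platforms,
    regions LA/V/SA with 4 replicates each (V emitted as 2 LV + 2 RV),
    log2 baselines ~ N(6, 2), within-region noise sd 0.5, region effect
    4 log2 units, and 50 planted specific genes per region per species
    (20 common to all three species, 10 per species pair, 10 selective).
    """

    species: tuple[str, ...] = ("human", "mouse", "rat")
    regions: tuple[str, ...] = ("LA", "V", "SA")
    replicates: int = 4
    split_ventricle: bool = True
    n_genes: int = 5000
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    sigma: float = 0.5  # within-region noise sd, log2 units
    delta: float = 4.0  # planted region effect, log2 units
    n_common: int = 20  # per region, planted in every species
    n_pairwise: int = 10  # per region, per species pair
    n_selective: int = 10  # per region, per single species
    platforms: dict[str, PlatformParams] = field(default_factory=_default_platforms)
    dropout_planted: bool = False  # True re-creates HCN4-style marker loss
    ortholog_multimap_frac: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.platforms, dict):
            self.platforms = {
                s: (p if isinstance(p, PlatformParams) else PlatformParams(**p))
                for s, p in self.platforms.items()
            }
        for name in ("n_common", "n_pairwise", "n_selective"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.total_planted() and self.delta <= 0:
            raise ValueError("delta must be > 0 when genes are planted")
        if self.total_planted() > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        for s in self.species:
            if s not in self.platforms:
                self.platforms[s] = PlatformParams()

    def n_pairs(self) -> int:
        return len(list(combinations(self.species, 2)))

    def total_planted(self) -> int:
        per_region = (
            self.n_common
            + self.n_pairwise * self.n_pairs()
            + self.n_selective * len(self.species)
        )
        return per_region * len(self.regions)

    def planted_per_species_region(self) -> int:
        """Planted specific genes each species carries per region."""
        return self.n_common + self.n_pairwise * (len(self.species) - 1) + self.n_selective

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


@dataclass
class SyntheticTruth:
    """Planted region/conservation labels, one row per species-gene planting."""

    table: pd.DataFrame  # columns species, gene, region, category

    def planted(self, species: str) -> set[tuple[str, str]]:
        rows = self.table[self.table["species"] == species]
        return set(zip(rows["gene"], rows["region"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus the ground truth."""

    config: SyntheticConfig
    matrices: dict[str, ExpressionMatrix]  # log2 scale, per species
    metadata: dict[str, pd.DataFrame]
    ortholog_tables: list[OrthologTable]
    truth: SyntheticTruth

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for species in self.config.species:
            write_expression_tsv(
                self.matrices[species], directory / f"{species}_expression.tsv"
            )
            write_sample_metadata(
                self.metadata[species], directory / f"{species}_samples.tsv"
            )
        for t in self.ortholog_tables:
            t.to_tsv(directory / f"orthologs_{t.x_species}_{t.y_species}.tsv")
        self.truth.to_tsv(directory / "truth.tsv")
        self.config.to_json(directory / "config.json")


def _gene_id(species: str, index: int) -> str:
    return f"{_PREFIX.get(species, species[:3].upper())}{index:05d}"


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset under ``cfg``; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    species = list(cfg.species)
    regions = list(cfg.regions)

    # 1. shared (orthologous) baselines on the log2 scale
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    baseline = np.clip(baseline, 0.0, None)

    # 2. planted assignment: universe gene index -> (region, member species)
    planted_idx = rng.choice(n, size=cfg.total_planted(), replace=False)
    cursor = 0
    plantings: list[tuple[int, str, tuple[str, ...], str]] = []
    pairs = list(combinations(species, 2))
    for region in regions:
        for _ in range(cfg.n_common):
            plantings.append((planted_idx[cursor], region, tuple(species), "common_all"))
            cursor += 1
        for pair in pairs:
            for _ in range(cfg.n_pairwise):
                cat = f"pairwise({','.join(sorted(pair))})"
                plantings.append((planted_idx[cursor], region, pair, cat))
                cursor += 1
        for s in species:
            for _ in range(cfg.n_selective):
                plantings.append((planted_idx[cursor], region, (s,), f"selective({s})"))
                cursor += 1
    planted_by_species: dict[str, dict[int, str]] = {s: {} for s in species}
    truth_rows = []
    for idx, region, members, category in plantings:
        for s in members:
            planted_by_species[s][idx] = region
            truth_rows.append((s, _gene_id(s, idx), region, category))
    planted_union = {idx for idx, *_ in plantings}

    # 3. per-species samples (species processed in config order)
    matrices: dict[str, ExpressionMatrix] = {}
    metadata: dict[str, pd.DataFrame] = {}
    for s in species:
        p = cfg.platforms[s]
        sample_ids, sample_regions, raw_labels, individuals = [], [], [], []
        for region in regions:
            for rep in range(cfg.replicates):
                if region == "V" and cfg.split_ventricle:
                    raw = "LV" if rep < cfg.replicates / 2 else "RV"
                else:
                    raw = region
                sample_ids.append(f"{s}_{raw}_{rep + 1}")
                raw_labels.append(raw)
                sample_regions.append(region)
                individuals.append(f"{s}_ind{rep + 1}")
        effect = np.zeros((n, len(sample_ids)))
        for idx, region in planted_by_species[s].items():
            effect[idx, :] = [cfg.delta if r == region else 0.0 for r in sample_regions]
        signal = p.shift + p.scale * (baseline[:, None] + effect)
        noise = rng.normal(0.0, cfg.sigma, size=signal.shape)
        values = np.clip(signal + noise, 0.0, None)
        gene_ids = [_gene_id(s, i) for i in range(n)]
        matrices[s] = ExpressionMatrix(
            pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
            "log2",
        )
        metadata[s] = pd.DataFrame(
            {
                "species": s,
                "region": raw_labels,
                "individual_id": individuals,
                "platform_id": _PLATFORM_NAME.get(s, f"{s}_platform"),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )

    # 4. platform dropout (per species, independent per gene)
    for s in species:
        p = cfg.platforms[s]
        if p.dropout <= 0:
            continue
        drop = rng.random(n) < p.dropout
        if not cfg.dropout_planted:
            protected = np.array([i in planted_by_species[s] for i in range(n)])
            drop &= ~protected
        keep_ids = [_gene_id(s, i) for i in range(n) if not drop[i]]
        matrices[s] = matrices[s].with_values(matrices[s].values.loc[keep_ids])
        if cfg.dropout_planted:
            dropped = {i for i in range(n) if drop[i]}
            truth_rows = [
                r
                for r in truth_rows
                if not (r[0] == s and r[1] in {_gene_id(s, i) for i in dropped})
            ]

    # 5. ortholog graph: 1-1 backbone plus extra many-to-many edges
    tables = []
    n_extra = int(round(cfg.ortholog_multimap_frac * n))
    unplanted = np.array(sorted(set(range(n)) - planted_union))
    for x_s, y_s in pairs:
        x = [_gene_id(x_s, i) for i in range(n)]
        y = [_gene_id(y_s, i) for i in range(n)]
        edges = pd.DataFrame({"x_gene": x, "y_gene": y})
        if n_extra and len(unplanted) >= 2:
            # paralog-style 1-to-2 edges, kept off planted genes so the
            # conservation truth stays exact
            xs = rng.choice(unplanted, size=n_extra, replace=False)
            ys = rng.choice(unplanted, size=n_extra, replace=True)
            ys = np.where(ys == xs, (ys + 1) % n, ys)
            extra = pd.DataFrame(
                {
                    "x_gene": [_gene_id(x_s, i) for i in xs],
                    "y_gene": [_gene_id(y_s, i) for i in ys],
                }
            )
            edges = (
                pd.concat([edges, extra], ignore_index=True)
                .drop_duplicates()
                .reset_index(drop=True)
            )
        tables.append(OrthologTable(x_s, y_s, edges))

    truth = SyntheticTruth(
        pd.DataFrame(truth_rows, columns=["species", "gene", "region", "category"])
        .sort_values(["species", "gene", "region"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SyntheticDataset(cfg, matrices, metadata, tables, truth)


def generate_count_table(
    n_genes: int = 200, n_samples: int = 6, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Poisson-lognormal count table + gene lengths, for the TPM path."""
    rng = np.random.default_rng(seed)
    lengths = pd.Series(
        rng.integers(300, 10_000, size=n_genes).astype(float),
        index=pd.Index([f"G{i:05d}" for i in range(n_genes)], name="gene_id"),
        name="length",
    )
    mu = rng.normal(2.0, 1.5, size=n_genes)
    lam = np.exp(mu)[:, None] * (lengths.to_numpy()[:, None] / 1000.0)
    counts = rng.poisson(lam, size=(n_genes, n_samples))
    df = pd.DataFrame(
        counts, index=lengths.index, columns=[f"S{j + 1}" for j in range(n_samples)]
    )
    return df, lengths


def synthetic_annotation(
    dataset: SyntheticDataset, n_random_terms: int = 20, term_size: int = 40, seed: int = 0
) -> AnnotationTable:
    """Term annotation with planted region programs, for the enrichment stage.

    One ``REGION_<r>_PROGRAM`` term per region containing every species'
    planted genes for that region, a ``GO:0003700`` transcription-factor term
    covering a deterministic subset of planted genes, and ``n_random_terms``
    random gene sets as negative controls.
    """
    rng = np.random.default_rng(seed)
    truth = dataset.truth.table
    all_genes = np.array(
        sorted(g for m in dataset.matrices.values() for g in m.gene_ids)
    )
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for region in dataset.config.regions:
        genes = frozenset(truth.loc[truth["region"] == region, "gene"])
        if genes:
            terms[f"REGION_{region}_PROGRAM"] = (f"{region} regional program", genes)
    planted_sorted = sorted(set(truth["gene"]))
    tf_genes = frozenset(planted_sorted[::3]) | frozenset(
        rng.choice(all_genes, size=min(term_size, len(all_genes)), replace=False)
    )
    terms[TF_TERM] = ("DNA-binding transcription factor activity", frozenset(tf_genes))
    for j in range(n_random_terms):
        genes = frozenset(
            rng.choice(all_genes, size=min(term_size, len(all_genes)), replace=False)
        )
        terms[f"RAND:{j:04d}"] = (f"random set {j}", genes)
    return AnnotationTable(terms)


def score_recovery(
    calls_by_species: dict[str, pd.DataFrame],
    categories: pd.DataFrame,
    truth: SyntheticTruth,
) -> dict:
    """Score pipeline output against the planted truth.

    Per species: sensitivity TP/(TP+FN) and observed FDR FP/(TP+FP) of the
    specific-gene calls (FDR reported as 0.0 with an ``fdr_undefined`` flag
    when no calls were made).  Category accuracy is scored over all planted
    (species, gene, region) rows: the predicted category (``not_called`` if
    the pipeline missed the gene) must equal the planted category.
    """
    per_species = {}
    for s, calls in calls_by_species.items():
        called = set(
            zip(
                calls.loc[calls["is_specific"], "gene"],
                calls.loc[calls["is_specific"], "region"],
            )
        )
        planted = truth.planted(s)
        tp = len(called & planted)
        fp = len(called - planted)
        fn = len(planted - called)
        per_species[s] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "sensitivity": tp / (tp + fn) if (tp + fn) else 1.0,
            "fdr": fp / (tp + fp) if (tp + fp) else 0.0,
            "fdr_undefined": (tp + fp) == 0,
        }
    pred = {
        (r.species, r.gene, r.region): r.category
        for r in categories.itertuples(index=False)
    }
    confusion: dict[tuple[str, str], int] = {}
    n_correct = 0
    truth_rows = list(truth.table.itertuples(index=False))
    for row in truth_rows:
        predicted = pred.get((row.species, row.gene, row.region), "not_called")
        confusion[(row.category, predicted)] = confusion.get((row.category, predicted), 0) + 1
        n_correct += predicted == row.category
    accuracy = n_correct / len(truth_rows) if truth_rows else 1.0
    confusion_df = (
        pd.Series(confusion, name="count")
        .rename_axis(["true_category", "predicted_category"])
        .reset_index()
        if confusion
        else pd.DataFrame(columns=["true_category", "predicted_category", "count"])
    )
    return {
        "per_species": per_species,
        "category_accuracy": accuracy,
        "confusion": confusion_df,
    }
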