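"""End-to-end orchestration: simulate/load -> preprocess -> specificity ->
cross-species categories -> clustering -> enrichment.

Every stage is a pure function of (inputs, config, seed); a run writes its
outputs plus a manifest recording the config hash, the seed and per-stage row
counts, so reruns with the same config and seed reproduce every output file
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import preprocess
from .clustering import (
    build_spm_profile_set,
    cluster_samples,
    cluster_spm_profiles,
    region_purity,
)
from .enrichment import AnnotationTable, enrich, tf_filter
from .io import ExpressionMatrix, read_expression_tsv, read_sample_metadata
from .orthologs import OrthologTable, categorize_specific_sets, interspecies_spearman
from .simulate import (
    SyntheticConfig,
    SyntheticDataset,
    generate_dataset,
    score_recovery,
    synthetic_annotation,
)
from .specificity import DEFAULT_MERGES, DEFAULT_REGIONS, RegionDesign, RegionSpecificity

logger = logging.getLogger(__name__)

#: Per-species expression filter thresholds of the modelled study design.
DEFAULT_THRESHOLDS = {"human": 1.0, "rat": 4.0, "mouse": 6.0}


@dataclass
class SpeciesInput:
    """Paths and platform handling for one species' real-data input."""

    expression: str
    metadata: str
    scale: str = "log2"  # "linear" inputs get log2(v+1) first
    normalization: str = "median"  # median | percentile | none
    pseudocount: float = 0.0  # added before log2 on linear inputs


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serialisable)."""

    seed: int = 0
    output_dir: str = "cardiospm_out"
    regions: tuple[str, ...] = DEFAULT_REGIONS
    merges: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MERGES))
    alpha: float = 0.05
    null_percentile: float = 95.0
    reference_species: str = "human"
    expression_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    background: str = "universe"  # "universe" or "custom:<path>"
    annotation: str | None = None  # GMT/long-TSV path; None -> synthetic terms
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    inputs: dict[str, SpeciesInput] | None = None
    ortholog_tables: dict[str, str] | None = None  # "x,y" -> path (real data)

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        if self.inputs is not None:
            self.inputs = {
                s: (v if isinstance(v, SpeciesInput) else SpeciesInput(**v))
                for s, v in self.inputs.items()
            }
        if self.synthetic is None and self.inputs is None:
            raise ValueError("config needs either a synthetic section or inputs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def canonical_json(self) -> str:
        """Canonical JSON of the scientific configuration (output path excluded)."""

        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return str(o)

        payload = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        return json.dumps(payload, default=default, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_inputs(rc: RunConfig):
    if rc.inputs is not None:
        matrices, metadata = {}, {}
        for s, inp in rc.inputs.items():
            m = read_expression_tsv(inp.expression, scale=inp.scale)
            if inp.scale == "linear":
                if inp.pseudocount:
                    m = preprocess.add_pseudocount(m, inp.pseudocount)
                m = preprocess.log2_transform(m)
            m, _ = preprocess.drop_incomplete_rows(m)
            matrices[s] = m
            metadata[s] = read_sample_metadata(inp.metadata)
        tables = []
        for key, path in (rc.ortholog_tables or {}).items():
            x_s, y_s = [t.strip() for t in key.split(",")]
            tables.append(OrthologTable.from_tsv(path, x_s, y_s))
        return matrices, metadata, tables, None
    dataset = generate_dataset(rc.synthetic)
    return dict(dataset.matrices), dict(dataset.metadata), list(dataset.ortholog_tables), dataset


def _normalize(rc: RunConfig, species: str, m: ExpressionMatrix) -> ExpressionMatrix:
    method = "median"
    if rc.inputs is not None and species in rc.inputs:
        method = rc.inputs[species].normalization
    if method == "median":
        m = preprocess.median_align(m)
    elif method == "percentile":
        m = preprocess.percentile_normalize(m)
    elif method != "none":
        raise ValueError(f"unknown normalization {method!r}")
    # alignment shifts can push low values below the log2(x+1) floor of 0;
    # clip back so SPM's non-negativity precondition holds
    return m.with_values(m.values.clip(lower=0.0))


def run_all(rc: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to the run dir)."""
    out = Path(rc.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": rc.config_hash(),
        "seed": rc.seed,
        "stages": {},
    }
    stage = "simulate" if rc.inputs is None else "load"
    try:
        matrices, metadata, tables, dataset = _load_inputs(rc)
        if dataset is not None:
            dataset.write(out / "synthetic")
        manifest["stages"][stage] = {
            "species": sorted(matrices),
            "genes": {s: m.n_genes for s, m in matrices.items()},
            "samples": {s: m.n_samples for s, m in matrices.items()},
        }

        stage = "preprocess"
        processed: dict[str, ExpressionMatrix] = {}
        for s in sorted(matrices):
            m = _normalize(rc, s, matrices[s])
            threshold = rc.expression_thresholds.get(s, 1.0)
            m = preprocess.filter_expressed(m, threshold)
            processed[s] = m
            m.values.to_csv(out / f"{s}_processed.tsv", sep="\t", float_format="%.10g")
        manifest["stages"]["preprocess"] = {
            "genes_after_filter": {s: m.n_genes for s, m in processed.items()}
        }

        stage = "specificity"
        results = {}
        for i, s in enumerate(sorted(processed)):
            design = RegionDesign.from_metadata(metadata[s], rc.regions, rc.merges)
            model = RegionSpecificity(
                processed[s], design, rc.alpha, rc.null_percentile, tag=s
            )
            results[s] = model.fit(seed=rc.seed * 1000 + i)
            results[s].to_tsv(out, prefix=f"{s}_")
        manifest["stages"]["specificity"] = {
            "tau": {s: r.tau for s, r in results.items()},
            "specific_calls": {
                s: int(r.calls["is_specific"].sum()) for s, r in results.items()
            },
        }

        stage = "classify"
        calls_by_species = {s: r.calls for s, r in results.items()}
        categories = categorize_specific_sets(
            calls_by_species, tables, rc.reference_species
        )
        categories.to_csv(out / "categories.tsv", sep="\t", index=False)
        manifest["stages"]["classify"] = {
            "rows": len(categories),
            "by_category": categories["category"].value_counts().to_dict(),
        }

        stage = "compare"
        by_pair = {(t.x_species, t.y_species): t for t in tables}
        correlations = []
        for (x_s, y_s), t in sorted(by_pair.items()):
            if x_s not in results or y_s not in results:
                continue
            for region in rc.regions:
                rho = interspecies_spearman(
                    results[x_s].region_means, results[y_s].region_means, t, region
                )
                correlations.append(
                    {"x_species": x_s, "y_species": y_s, "region": region, "rho": rho}
                )
        (out / "interspecies_spearman.json").write_text(
            json.dumps(correlations, indent=2) + "\n"
        )
        manifest["stages"]["compare"] = {"n_correlations": len(correlations)}

        stage = "cluster"
        for s in sorted(processed):
            cluster_samples(processed[s]).to_newick(out / f"{s}_samples.nwk")
        spm_by_species = {s: r.spm for s, r in results.items()}
        profiles = build_spm_profile_set(spm_by_species, tables, rc.reference_species)
        profiles.to_csv(out / "spm_profiles.tsv", sep="\t", float_format="%.10g")
        profile_tree = cluster_spm_profiles(profiles)
        profile_tree.to_newick(out / "spm_profiles.nwk")
        purity = region_purity(profile_tree, k=len(rc.regions))
        manifest["stages"]["cluster"] = {
            "n_shared_genes": len(profiles),
            "n_profiles": profiles.shape[1],
            "region_purity_at_k": purity,
        }

        stage = "enrich"
        if rc.annotation is not None:
            path = Path(rc.annotation)
            if path.suffix == ".gmt":
                annotation = AnnotationTable.from_gmt(path)
            else:
                annotation = AnnotationTable.from_long_tsv(path)
        elif dataset is not None:
            annotation = synthetic_annotation(dataset, seed=rc.seed)
        else:
            annotation = None
        enrichment_counts = {}
        if annotation is not None:
            enrich_rows = []
            for s, r in results.items():
                if rc.background.startswith("custom:"):
                    background = set(
                        Path(rc.background.split(":", 1)[1]).read_text().split()
                    )
                else:
                    background = set(r.spm.index)
                for region in rc.regions:
                    query = set(r.specific_genes(region)) & background
                    if not query:
                        continue
                    res = enrich(query, background, annotation, rc.alpha)
                    res.insert(0, "region", region)
                    res.insert(0, "species", s)
                    enrich_rows.append(res)
            enrichment = (
                pd.concat(enrich_rows, ignore_index=True)
                if enrich_rows
                else pd.DataFrame()
            )
            enrichment.to_csv(
                out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g"
            )
            enrichment_counts = {
                "rows": len(enrichment),
                "significant": int(enrichment["significant"].sum())
                if len(enrichment)
                else 0,
            }
        manifest["stages"]["enrich"] = enrichment_counts or {"skipped": True}

        if dataset is not None:
            recovery = score_recovery(calls_by_species, categories, dataset.truth)
            recovery["confusion"].to_csv(
                out / "category_confusion.tsv", sep="\t", index=False
            )
            manifest["recovery"] = {
                "per_species": recovery["per_species"],
                "category_accuracy": recovery["category_accuracy"],
            }
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
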