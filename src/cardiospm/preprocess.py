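"""Per-platform normalisation of expression matrices.

Each platform arrives on its own scale (microarray intensity, TPM); the
transforms here bring every dataset to the same log2 form the downstream
statistics expect.  Cross-sample alignment (median alignment for the
Illumina-style arrays, 90-percentile normalisation for Agilent-style arrays)
is done by an additive shift on the log2 scale, which preserves rank order
within every sample and anchors each sample's statistic to the grand median
of the per-sample statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import LINEAR, LOG2, CountTable, ExpressionMatrix

logger = logging.getLogger(__name__)


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(v + 1) transform of a linear-scale matrix."""
    if m.scale != LINEAR:
        raise ValueError("log2_transform expects a linear-scale matrix")
    return m.with_values(np.log2(m.values + 1.0), scale=LOG2)


def add_pseudocount(m: ExpressionMatrix, c: float = 1.0) -> ExpressionMatrix:
    """Add a positive constant to every element (zero-avoidance for RNA-seq)."""
    if not c > 0:
        raise ValueError("pseudocount must be > 0")
    return m.with_values(m.values + c)


def median_align(m: ExpressionMatrix) -> ExpressionMatrix:
    """Shift every sample so its median equals the grand median of sample medians."""
    if m.scale != LOG2:
        raise ValueError("median_align operates on the log2 scale")
    if m.n_samples == 0 or m.n_genes == 0:
        raise ValueError("cannot align an empty matrix")
    medians = m.values.median(axis=0)
    target = float(np.median(medians))
    return m.with_values(m.values - medians + target)


def percentile_normalize(m: ExpressionMatrix, q: float = 90.0) -> ExpressionMatrix:
    """Shift every sample so its q-th percentile equals the grand median of
    per-sample q-th percentiles (linear-interpolation percentile convention)."""
    if not 0 < q < 100:
        raise ValueError("percentile must lie strictly between 0 and 100")
    if m.scale != LOG2:
        raise ValueError("percentile_normalize operates on the log2 scale")
    if m.n_samples == 0 or m.n_genes == 0:
        raise ValueError("cannot normalize an empty matrix")
    pct = np.percentile(m.values.to_numpy(), q, axis=0)
    target = float(np.median(pct))
    return m.with_values(m.values - pct + target)


def drop_incomplete_rows(m: ExpressionMatrix) -> tuple[ExpressionMatrix, int]:
    """Remove genes/probes containing any missing value; returns (matrix, n_removed)."""
    keep = m.values.notna().all(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("dropped %d rows containing missing values", n_removed)
    if not keep.any():
        logger.warning("all rows contained missing values; matrix is empty")
    return m.with_values(m.values.loc[keep]), n_removed


def collapse_probes(m: ExpressionMatrix, probe_map: pd.Series) -> ExpressionMatrix:
    """Collapse probe rows to gene rows, taking the per-sample maximum.

    Probes absent from the map are dropped (and logged): only probes with a
    unique gene assignment enter the analysis.
    """
    if probe_map.empty:
        raise ValueError("probe map is empty")
    mapped = m.values.index.isin(probe_map.index)
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        logger.info("dropped %d probes absent from the probe map", n_unmapped)
    values = m.values.loc[mapped]
    genes = probe_map.reindex(values.index)
    collapsed = values.groupby(genes.to_numpy()).max()
    collapsed.index.name = m.values.index.name
    return m.with_values(collapsed)


def filter_expressed(m: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Keep genes whose value exceeds ``threshold`` (strictly) in >=1 sample.

    Platform-specific defaults in the study design are >1 (human RNA-seq),
    >4 (rat array) and >6 (mouse array), chosen from the observed expression
    distributions.
    """
    if not np.isfinite(threshold) and threshold != -np.inf:
        raise ValueError("threshold must be finite (or -inf for no filtering)")
    keep = (m.values > threshold).any(axis=1)
    return m.with_values(m.values.loc[keep])


def compute_tpm(ct: CountTable) -> ExpressionMatrix:
    """Transcripts-per-million from counts and gene lengths.

    Per sample: rate_g = count_g / (length_g / 1000); TPM_g = 1e6 * rate_g /
    sum(rates).  Each column sums to 1e6 except for all-zero samples, which
    stay all-zero (with a warning).
    """
    rates = ct.counts.div(ct.gene_lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "sample(s) %s have all-zero counts; TPM left at zero",
            list(totals.index[zero]),
        )
    safe = totals.replace(0, np.nan)
    tpm = rates.div(safe, axis=1) * 1e6
    tpm = tpm.fillna(0.0)
    return ExpressionMatrix(tpm, LINEAR)
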