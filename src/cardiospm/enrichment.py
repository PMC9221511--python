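"""Over-representation analysis of specific-gene sets against term annotations.

The test is the one-sided hypergeometric upper tail (equivalently one-sided
Fisher's exact test): with N background genes of which K carry the term and a
query of n background genes with k hits, p = P(X >= k) for X ~
Hypergeometric(N, K, n).  All counts are taken after intersecting the query,
the term sets and the universe with the background, which by default is the
set of genes that entered the region-specific analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .specificity import bh_adjust

#: GO term for DNA-binding transcription factor activity.
TF_TERM = "GO:0003700"


@dataclass
class AnnotationTable:
    """term_id -> (term_name, gene set) annotation."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id!r} has an empty gene set")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "AnnotationTable":
        """Read GMT: term_id <TAB> term_name <TAB> gene1 <TAB> gene2 ..."""
        terms: dict[str, tuple[str, frozenset[str]]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            term_id, name, genes = fields[0], fields[1], fields[2:]
            if term_id in terms:
                raise ValueError(f"duplicate term id {term_id!r}")
            terms[term_id] = (name, frozenset(g for g in genes if g))
        return cls(terms)

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "AnnotationTable":
        """Read a two-column long TSV (term_id, gene_id); term_name = term_id."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        terms = {
            term: (term, frozenset(group.iloc[:, 1]))
            for term, group in df.groupby(df.columns[0])
        }
        return cls(terms)

    def to_gmt(self, path: str | Path) -> None:
        lines = [
            "\t".join([term_id, name, *sorted(genes)])
            for term_id, (name, genes) in sorted(self.terms.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def gene_set(self, term_id: str) -> frozenset[str]:
        if term_id not in self.terms:
            raise KeyError(f"term {term_id!r} absent from annotation")
        return self.terms[term_id][1]


def tf_filter(
    genes: set[str], annotation: AnnotationTable, term: str = TF_TERM
) -> set[str]:
    """Restrict a gene set to DNA-binding transcription factors (GO:0003700)."""
    return set(genes) & set(annotation.gene_set(term))


def enrich(
    query: set[str],
    background: set[str],
    annotation: AnnotationTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in ``query``.

    Returns one row per term with K > 0 in the background, sorted by BH
    adjusted p-value: columns ``term_id, term_name, k, K, n, N, p, adj_p,
    significant``.
    """
    if not background:
        raise ValueError("background gene set is empty")
    query = set(query)
    background = set(background)
    if not query <= background:
        extra = sorted(query - background)[:5]
        raise ValueError(f"query genes outside the background: {extra}")
    N = len(background)
    n = len(query)
    rows = []
    for term_id, (name, genes) in annotation.terms.items():
        term_bg = genes & background
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, name, k, K, n, N, min(p, 1.0)))
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"]
    )
    if len(result):
        result["adj_p"] = bh_adjust(result["p"].to_numpy())
    else:
        result["adj_p"] = []
    result["significant"] = result["adj_p"] < alpha
    result = result.sort_values(
        ["adj_p", "p", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    return result
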