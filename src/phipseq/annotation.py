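"""Offline gene-set over-representation analysis and expression cross-reference.

ORA is a one-sided (upper-tail) hypergeometric test of a gene list against
each set of a GMT collection over an explicit background universe, with
Benjamini-Hochberg adjustment across terms. The background defaults to the
gene symbols of the tiled proteome — what the assay can actually detect —
rather than a whole-genome universe.

Symbol matching is case-insensitive with an alias-map hook, since public
gene lists routinely mix aliases and casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def _norm(symbol: str, aliases: Mapping[str, str]) -> str:
    s = symbol.strip().upper()
    return aliases.get(s, s)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {line_no}: needs term, desc, genes")
        term, _desc, *genes = parts
        genes = [g for g in genes if g]
        if not genes:
            raise ValueError(f"empty gene set {term!r} at GMT line {line_no}")
        sets[term] = set(genes)
    return sets


@dataclass
class GeneSetCollection:
    """Gene sets plus the background universe they are tested against."""

    sets: dict[str, set[str]]
    background: set[str]
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        aliases = {k.upper(): v.upper() for k, v in self.aliases.items()}
        self.aliases = aliases
        self.background = {_norm(g, aliases) for g in self.background}
        normed = {}
        for term, genes in self.sets.items():
            inside = {_norm(g, aliases) for g in genes} & self.background
            if inside:
                normed[term] = inside
        self.sets = normed

    @classmethod
    def from_gmt(
        cls,
        path: str | Path,
        background: Iterable[str],
        aliases: Mapping[str, str] | None = None,
    ) -> "GeneSetCollection":
        return cls(
            sets=read_gmt(path),
            background=set(background),
            aliases=dict(aliases or {}),
        )


def ora(query: Sequence[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each term.

    Genes outside the background are dropped (they are untestable). Rows are
    sorted by raw p; ``p_adj`` is Benjamini-Hochberg across all terms.
    """
    normed = {_norm(g, collection.aliases) for g in query}
    inside = normed & collection.background
    if not inside:
        raise ValueError("query is empty after intersecting with the background")
    n_bg = len(collection.background)
    n_query = len(inside)
    rows = []
    for term, genes in collection.sets.items():
        overlap = inside & genes
        k = len(overlap)
        big_k = len(genes)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_query))
        # odds ratio of the 2x2 (overlap vs the rest of the universe)
        denom = (big_k - k) * (n_query - k)
        numer = k * (n_bg - big_k - n_query + k)
        odds = numer / denom if denom > 0 else float("inf") if numer > 0 else 0.0
        rows.append(
            {
                "term": term,
                "overlap_count": k,
                "set_size": big_k,
                "overlap_genes": ",".join(sorted(overlap)),
                "p": p,
                "odds_ratio": odds,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    return out


DEFAULT_EPITHELIAL_KEYWORDS = ("corneal", "limbal", "conjunctival", "goblet", "epitheli")


def expression_crossref(
    query: Sequence[str],
    expression: pd.DataFrame,
    threshold: float = 0.0,
    epithelial_types: Sequence[str] | None = None,
    gene_column: str = "gene",
) -> pd.DataFrame:
    """Annotate query genes with their expression across cell types.

    ``expression`` is a gene x cell-type table (genes in ``gene_column`` or
    the index). Per gene: whether it is detected at all, the cell type with
    maximal expression, and whether any epithelial cell type (default: any
    column whose name contains an ocular-surface epithelium keyword) exceeds
    the threshold. Genes absent from the table are flagged not detected.
    """
    expr = expression.copy()
    if gene_column in expr.columns:
        expr = expr.set_index(gene_column)
    expr.index = expr.index.astype(str).str.upper()
    cell_types = list(expr.columns)
    if epithelial_types is None:
        epithelial = [
            ct
            for ct in cell_types
            if any(k in ct.lower() for k in DEFAULT_EPITHELIAL_KEYWORDS)
        ]
    else:
        epithelial = [ct for ct in cell_types if ct in set(epithelial_types)]
    rows = []
    found_any = False
    for gene in query:
        g = gene.strip().upper()
        if g not in expr.index:
            rows.append(
                {
                    "gene": gene,
                    "detected": False,
                    "max_cell_type": "not detected",
                    "max_expression": float("nan"),
                    "epithelial": False,
                }
            )
            continue
        found_any = True
        row = expr.loc[g].astype(float)
        detected = bool((row > threshold).any())
        rows.append(
            {
                "gene": gene,
                "detected": detected,
                "max_cell_type": row.idxmax() if detected else "not detected",
                "max_expression": float(row.max()),
                "epithelial": bool((row[epithelial] > threshold).any())
                if epithelial
                else False,
            }
        )
    if not found_any:
        import warnings

        warnings.warn("no query gene found in the expression table", stacklevel=2)
    return pd.DataFrame(rows)
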