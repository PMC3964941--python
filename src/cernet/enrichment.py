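"""Hypergeometric functional enrichment (miRFunction / ceRNAFunction).

Generic GMT-based gene-set enrichment: a query set (the targets of chosen
miRNA families, or the ceRNA partners of a gene) is tested against every
term of an annotation category with the upper-tail hypergeometric test,
corrected with both Bonferroni and Benjamini-Hochberg within the category.

The background universe defaults to the union of the category's term sets;
this choice dominates enrichment p-values, so an explicit universe can
(and usually should) be supplied.  Gene identity is by symbol, uppercased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from cernet.cerna_network import bh_fdr, hypergeom_pvalue
from cernet.target_discovery import InteractionSite, filter_interactions


class GmtParseError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationCategory:
    """One annotation category (e.g. GO-BP, KEGG): term_id -> (name, genes)."""

    category_name: str
    terms: dict[str, tuple[str, frozenset[str]]]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return frozenset(out)


def load_gmt(
    handle: IO[str] | Iterable[str], category_name: str = "GMT"
) -> AnnotationCategory:
    """Parse GMT lines: term_id <tab> description <tab> gene1 <tab> ...

    Gene symbols are uppercased and deduplicated.  Terms with an empty gene
    list are dropped with a warning; a line with fewer than two fields is a
    parse error naming the line.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    n_empty = 0
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise GmtParseError(f"fewer than 2 fields at line {lineno}")
        term_id, description = fields[0], fields[1]
        genes = frozenset(g.upper() for g in fields[2:] if g)
        if not genes:
            n_empty += 1
            continue
        terms[term_id] = (description, genes)
    if n_empty:
        warnings.warn(f"dropped {n_empty} GMT terms with empty gene lists")
    return AnnotationCategory(category_name=category_name, terms=terms)


def enrich(
    query_genes: Iterable[str],
    category: AnnotationCategory,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of a query set.

    For each term: p = P(X >= k) with universe size N_u, term size K_t
    (clipped to the universe), query size n_q and overlap k.  Bonferroni
    multiplies by the number of terms tested in this category; q is BH
    across the category.  Rows are sorted by (p, term_id).
    """
    query = {g.upper() for g in query_genes}
    if not query:
        raise ValueError("query gene set is empty")
    uni = (
        {g.upper() for g in universe} if universe is not None else set(category.universe)
    )
    if not uni:
        raise ValueError("universe is empty")
    dropped = len(query - uni)
    if dropped:
        warnings.warn(f"{dropped} query genes outside the universe were dropped")
    query &= uni
    if not query:
        raise ValueError("no query genes remain inside the universe")

    rows = []
    for term_id in sorted(category.terms):
        name, genes = category.terms[term_id]
        term_genes = genes & uni
        if not term_genes:
            continue
        k = len(query & term_genes)
        p = hypergeom_pvalue(len(uni), len(term_genes), len(query), k)
        rows.append((term_id, name, k, len(term_genes), p))
    if not rows:
        raise ValueError("no terms overlap the universe")
    m = len(rows)
    p_arr = [r[4] for r in rows]
    q_arr = bh_fdr(p_arr)
    df = pd.DataFrame(
        {
            "term_id": [r[0] for r in rows],
            "term_name": [r[1] for r in rows],
            "overlap_count": [r[2] for r in rows],
            "term_size": [r[3] for r in rows],
            "query_size": len(query),
            "universe_size": len(uni),
            "p_value": p_arr,
            "p_bonferroni": [min(1.0, p * m) for p in p_arr],
            "q_value": q_arr,
        }
    )
    return df.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)


def mirfunction_gene_set(
    families: Iterable[str],
    interactions: Sequence[InteractionSite],
    min_experiments: int = 1,
    min_programs: int = 1,
    known_families: Iterable[str] | None = None,
) -> set[str]:
    """Genes targeted by the selected families under the given stringency.

    The union over the selected families of genes with at least one
    interaction site passing the CLIP-support and program-count filters.
    An unknown family raises a KeyError.
    """
    selected = set(families)
    if not selected:
        raise ValueError("no families selected")
    known = (
        set(known_families)
        if known_families is not None
        else {s.family_id for s in interactions}
    )
    missing = selected - known
    if missing:
        raise KeyError(f"unknown families: {sorted(missing)}")
    surviving = filter_interactions(interactions, min_experiments, min_programs)
    return {s.gene_id for s in surviving if s.family_id in selected}


def cernafunction_gene_set(
    gene: str,
    cerna_edges: pd.DataFrame,
    fdr_threshold: float = 0.05,
    profiled_genes: Iterable[str] | None = None,
) -> set[str]:
    """ceRNA partners of a gene with q below the threshold.

    A gene absent from the edge table but present in ``profiled_genes``
    returns the empty set (profiled but edgeless); a gene unknown to both
    raises a KeyError.
    """
    in_edges = (
        (cerna_edges["gene_a"] == gene) | (cerna_edges["gene_b"] == gene)
        if len(cerna_edges)
        else pd.Series(dtype=bool)
    )
    if not in_edges.any():
        if profiled_genes is not None and gene in set(profiled_genes):
            return set()
        raise KeyError(f"gene {gene!r} absent from the edge table")
    sub = cerna_edges[in_edges & (cerna_edges["q_value"] < fdr_threshold)]
    partners = set(sub["gene_a"]) | set(sub["gene_b"])
    partners.discard(gene)
    return partners


def write_enrichment_report(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8e")
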