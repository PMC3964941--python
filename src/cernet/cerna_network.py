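"""Hypergeometric ceRNA-pair inference with Benjamini-Hochberg FDR control.

Two transcripts that share miRNA response elements compete for the shared
miRNAs (the competing-endogenous-RNA hypothesis).  A candidate ceRNA pair
is scored by asking how surprising the number of shared miRNA families is:
with N families in the prediction universe, K of them targeting gene A and
n targeting gene B, the number shared by chance follows a hypergeometric
distribution, and the pair's p-value is the upper tail

    P(X >= c) = sum_{t=c}^{min(K,n)} C(K,t) C(N-K, n-t) / C(N, n).

Each family is counted once per gene regardless of how many binding sites
it has.  P-values are corrected with the Benjamini-Hochberg step-up, either
per query gene (mirroring an interactive query) or globally over all tested
pairs (mirroring database construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from cernet.target_discovery import InteractionSite

EDGE_COLUMNS = ["gene_a", "gene_b", "N", "K", "n", "c", "p_value", "q_value"]


@dataclass(frozen=True)
class GeneFamilyProfile:
    """The set of miRNA families with a surviving interaction on one gene."""

    gene_id: str
    biotype_class: str
    families: frozenset[str]

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError(f"profile for {self.gene_id} has no families")


@dataclass(frozen=True)
class CeRNAPair:
    """A scored ceRNA pair: the four test parameters plus p and q."""

    gene_a: str
    gene_b: str
    N: int
    K: int
    n: int
    c: int
    p_value: float
    q_value: float


def _validate_hypergeom(N: int, K: int, n: int, c: int) -> None:
    if N < 0:
        raise ValueError("requires N >= 0")
    if not 0 <= K <= N:
        raise ValueError(f"requires 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"requires 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= c <= min(K, n):
        raise ValueError(f"requires 0 <= c <= min(K, n), got c={c}, K={K}, n={n}")


def _log_comb(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(a) + 1) - gammaln(np.asarray(b) + 1) - gammaln(
        np.asarray(a) - np.asarray(b) + 1
    )


def hypergeom_pvalue(N: int, K: int, n: int, c: int) -> float:
    """Upper-tail hypergeometric probability P(X >= c).

    Computed in log space via log-gamma binomial coefficients, so the
    result is stable for large parameters and tiny tails.  ``c = 0``
    returns exactly 1.0.
    """
    _validate_hypergeom(N, K, n, c)
    if c == 0:
        return 1.0
    t = np.arange(c, min(K, n) + 1)
    log_terms = _log_comb(K, t) + _log_comb(N - K, n - t) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def hypergeom_pvalue_exact(N: int, K: int, n: int, c: int) -> Fraction:
    """Exact rational P(X >= c) by enumeration (slow verification path)."""
    _validate_hypergeom(N, K, n, c)
    numerator = sum(comb(K, t) * comb(N - K, n - t) for t in range(c, min(K, n) + 1))
    return Fraction(numerator, comb(N, n))


def _pvalues_for_triples(
    N: int, K: np.ndarray, n: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Vectorised tail p-values; computed once per unique (K, n, c) triple."""
    triples = np.column_stack([K, n, c])
    uniq, inverse = np.unique(triples, axis=0, return_inverse=True)
    p_uniq = np.array([hypergeom_pvalue(N, int(k), int(m), int(cc)) for k, m, cc in uniq])
    return p_uniq[inverse]


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, clipped to 1; ties are handled by a
    stable sort, so the output is invariant under input permutation.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def build_family_profiles(
    interactions: Iterable[InteractionSite],
    biotype_of: Mapping[str, str] | None = None,
) -> dict[str, GeneFamilyProfile]:
    """Collapse filtered interaction sites into per-gene family sets.

    Site multiplicity is discarded: a family with ten surviving sites on a
    gene contributes exactly one element to that gene's set.  Genes with no
    surviving site are absent from the result.
    """
    fams: dict[str, set[str]] = {}
    for site in interactions:
        fams.setdefault(site.gene_id, set()).add(site.family_id)
    biotype_of = biotype_of or {}
    return {
        gene: GeneFamilyProfile(
            gene_id=gene,
            biotype_class=biotype_of.get(gene, "other"),
            families=frozenset(families),
        )
        for gene, families in sorted(fams.items())
    }


def _check_universe(profiles: Mapping[str, GeneFamilyProfile], N: int) -> None:
    biggest = max((len(p.families) for p in profiles.values()), default=0)
    if N < biggest:
        raise ValueError(
            f"universe size N={N} smaller than largest profile ({biggest} families)"
        )


def find_cerna_partners(
    gene: str,
    profiles: Mapping[str, GeneFamilyProfile],
    N: int,
    min_common: int = 3,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """ceRNA candidates of one query gene, BH-corrected per query.

    Every other profiled gene sharing at least ``min_common`` families with
    the query is tested; BH runs across all tested candidates of this
    query; rows with q < ``fdr_threshold`` are returned sorted by
    (q, p, gene_b).
    """
    if min_common < 1:
        raise ValueError("min_common must be >= 1")
    if gene not in profiles:
        raise KeyError(f"gene {gene!r} not in profiles")
    _check_universe(profiles, N)
    fam_a = profiles[gene].families
    K = len(fam_a)
    rows = []
    for other, prof in profiles.items():
        if other == gene:
            continue
        c = len(fam_a & prof.families)
        if c >= min_common:
            rows.append((other, len(prof.families), c))
    if not rows:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    genes_b, n_arr, c_arr = zip(*rows)
    p = _pvalues_for_triples(
        N, np.full(len(rows), K), np.array(n_arr), np.array(c_arr)
    )
    q = bh_fdr(p)
    df = pd.DataFrame(
        {
            "gene_a": gene,
            "gene_b": genes_b,
            "N": N,
            "K": K,
            "n": n_arr,
            "c": c_arr,
            "p_value": p,
            "q_value": q,
        }
    )
    df = df[df["q_value"] < fdr_threshold]
    return df.sort_values(["q_value", "p_value", "gene_b"], kind="stable").reset_index(
        drop=True
    )


def build_cerna_network(
    profiles: Mapping[str, GeneFamilyProfile],
    N: int,
    min_common: int = 3,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """ceRNA edge table over all profiled genes, BH-corrected globally.

    All unordered gene pairs sharing at least ``min_common`` families are
    tested once (gene_a < gene_b lexicographically); BH runs over the whole
    tested set; edges with q < ``fdr_threshold`` are returned sorted by
    (q, p, gene_a, gene_b).
    """
    if min_common < 1:
        raise ValueError("min_common must be >= 1")
    _check_universe(profiles, N)
    genes = sorted(profiles)
    if len(genes) < 2:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    families = sorted({f for g in genes for f in profiles[g].families})
    fam_index = {f: i for i, f in enumerate(families)}
    M = np.zeros((len(genes), len(families)), dtype=np.int32)
    for i, g in enumerate(genes):
        for f in profiles[g].families:
            M[i, fam_index[f]] = 1
    C = M @ M.T
    sizes = M.sum(axis=1)
    iu, ju = np.triu_indices(len(genes), k=1)
    mask = C[iu, ju] >= min_common
    iu, ju = iu[mask], ju[mask]
    if iu.size == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    c_arr = C[iu, ju]
    p = _pvalues_for_triples(N, sizes[iu], sizes[ju], c_arr)
    q = bh_fdr(p)
    keep = q < fdr_threshold
    df = pd.DataFrame(
        {
            "gene_a": np.array(genes)[iu[keep]],
            "gene_b": np.array(genes)[ju[keep]],
            "N": N,
            "K": sizes[iu[keep]],
            "n": sizes[ju[keep]],
            "c": c_arr[keep],
            "p_value": p[keep],
            "q_value": q[keep],
        }
    )
    return df.sort_values(
        ["q_value", "p_value", "gene_a", "gene_b"], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# table I/O

def write_profiles(
    profiles: Mapping[str, GeneFamilyProfile], path: str | Path
) -> None:
    """Profile table TSV: gene_id, biotype_class, comma-joined families."""
    with Path(path).open("w") as handle:
        handle.write("gene_id\tbiotype_class\tfamilies\n")
        for gene in sorted(profiles):
            prof = profiles[gene]
            handle.write(
                f"{gene}\t{prof.biotype_class}\t{','.join(sorted(prof.families))}\n"
            )


def read_profiles(path: str | Path) -> dict[str, GeneFamilyProfile]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        row.gene_id: GeneFamilyProfile(
            gene_id=row.gene_id,
            biotype_class=row.biotype_class,
            families=frozenset(row.families.split(",")),
        )
        for row in df.itertuples()
    }


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.8e")


def read_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
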