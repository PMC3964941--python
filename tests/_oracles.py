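"""Independent oracles used across the suite.

These deliberately re-derive results by different means than the package
(regexes with lookarounds for seed sites, O(sites x clusters) scanning for
CLIP support, exact integer enumeration for hypergeometric tails) so that
agreement is a real check, not a tautology.
"""

from __future__ import annotations

import re
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def regex_seed_scan(sequence: str, seed7: str, include_6mer: bool = False):
    """All seed sites of one family by four lookaround regexes.

    Returns a set of (start, end, site_type) in transcript coordinates.
    """
    core = _rc(seed7[:6])          # rc of miRNA positions 2-7
    m8c = _rc(seed7[6])            # transcript base opposite position 8
    seq = sequence.upper()
    sites = set()
    for m in re.finditer(f"(?={re.escape(m8c + core)}A)", seq):
        sites.add((m.start(), m.start() + 8, "8mer"))
    for m in re.finditer(f"(?={re.escape(m8c + core)}(?:[^A]|$))", seq):
        sites.add((m.start(), m.start() + 7, "7mer-m8"))
    for m in re.finditer(f"(?<!{re.escape(m8c)})(?={re.escape(core)}A)", seq):
        sites.add((m.start(), m.start() + 7, "7mer-A1"))
    if include_6mer:
        for m in re.finditer(
            f"(?<!{re.escape(m8c)})(?={re.escape(core)}(?:[^A]|$))", seq
        ):
            sites.add((m.start(), m.start() + 6, "6mer"))
    return sites


def brute_force_support(sites, clusters, min_overlap=1, same_strand_required=True):
    """O(sites x clusters) CLIP support: (n_experiments, total_reads) per site."""
    out = []
    for site in sites:
        iv = site if not hasattr(site, "interval") else site.interval
        exps = set()
        reads = 0
        for c in clusters:
            civ = c.interval
            if civ.chrom != iv.chrom:
                continue
            if same_strand_required and not (
                civ.strand == "." or iv.strand == "." or civ.strand == iv.strand
            ):
                continue
            ov = min(iv.end, civ.end) - max(iv.start, civ.start)
            if ov >= min_overlap:
                exps.add(c.experiment_id)
                reads += c.read_count
        out.append((len(exps), reads))
    return out


def exact_tail(N: int, K: int, n: int, c: int) -> tuple[int, int]:
    """Exact P(X >= c) as an integer (numerator, denominator) pair."""
    num = sum(comb(K, t) * comb(N - K, n - t) for t in range(c, min(K, n) + 1))
    return num, comb(N, n)


def stepup_bh(p):
    """Textbook BH step-up, computed naively from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q
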