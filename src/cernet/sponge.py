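"""miRNA super-sponge detection.

A super-sponge is a transcript carrying many target sites of one miRNA
family — the circRNA CDR1as, with dozens of miR-7 sites, is the canonical
example.  Counting uses deduplicated merged sites, so nested seed matches
are not double counted; both the total and the CLIP-supported site counts
are reported because either may be the relevant stringency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from cernet.target_discovery import InteractionSite


@dataclass(frozen=True)
class SpongeRecord:
    family_id: str
    transcript_id: str
    site_count: int
    clip_supported_site_count: int
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if self.site_count < 1:
            raise ValueError("site_count must be >= 1")
        if not 0 <= self.clip_supported_site_count <= self.site_count:
            raise ValueError("clip_supported_site_count must be in [0, site_count]")


def count_family_sites(
    sites: Iterable[InteractionSite],
    gene_symbols: Mapping[str, str] | None = None,
) -> list[SpongeRecord]:
    """One record per (family, gene) with total and CLIP-supported counts."""
    counts: dict[tuple[str, str], list[int]] = {}
    for s in sites:
        tally = counts.setdefault((s.family_id, s.gene_id), [0, 0])
        tally[0] += 1
        if s.supporting_experiments >= 1:
            tally[1] += 1
    gene_symbols = gene_symbols or {}
    return [
        SpongeRecord(
            family_id=fam,
            transcript_id=gene,
            site_count=total,
            clip_supported_site_count=supported,
            gene_symbol=gene_symbols.get(gene, gene),
        )
        for (fam, gene), (total, supported) in sorted(counts.items())
    ]


def rank_sponges(
    records: Iterable[SpongeRecord], min_sites: int = 5
) -> list[SpongeRecord]:
    """Records with >= min_sites sites, sorted by site count.

    Descending by site_count, then by clip_supported_site_count, then
    ascending by transcript_id.
    """
    if min_sites < 1:
        raise ValueError("min_sites must be >= 1")
    kept = [r for r in records if r.site_count >= min_sites]
    return sorted(
        kept,
        key=lambda r: (-r.site_count, -r.clip_supported_site_count, r.transcript_id),
    )


def write_sponge_report(records: Iterable[SpongeRecord], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        handle.write(
            "family_id\ttranscript_id\tgene_symbol\tsite_count\tclip_supported_site_count\n"
        )
        for r in records:
            handle.write(
                f"{r.family_id}\t{r.transcript_id}\t{r.gene_symbol}\t"
                f"{r.site_count}\t{r.clip_supported_site_count}\n"
            )
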