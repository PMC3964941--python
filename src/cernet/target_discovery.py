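"""miRNA families, seed-site scanning, evidence merging and stringency filters.

miRNAs sharing positions 2-8 of the mature sequence form one family; the
family is the counting unit for all downstream statistics.  The built-in
scanner calls canonical seed-match site types on transcript sequences:

========  =====================================================  ======
type      definition (transcript, 5'->3')                        length
========  =====================================================  ======
8mer      perfect match to miRNA positions 2-8 + 'A' opposite       8
          miRNA position 1 (i.e. immediately 3' of the match)
7mer-m8   perfect match to positions 2-8, no A1                     7
7mer-A1   perfect match to positions 2-7 + the A1 adenosine         7
6mer      perfect match to positions 2-7 only                       6
========  =====================================================  ======

Each occurrence of the seed core (positions 2-7) yields exactly one site,
classified to the highest type the flanking bases allow, so nested matches
are never double counted.  6mer sites are off by default, mirroring strict
seed-pairing stringency.  External program predictions (TargetScan,
miRanda, PITA, PicTar2, RNA22) can be ingested alongside or instead of the
built-in scanner; overlapping sites of one family on one gene are merged
so that "predicted by at least k programs" is evaluated per merged site.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

from cernet.genomic_core import ClipExperiment, GenomicInterval, annotate_clip_support

_RNA = set("ACGU")
_DNA = set("ACGTN")
_DNA_COMP = str.maketrans("ACGTN", "TGCAN")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
DEFAULT_SITE_TYPES = frozenset({"8mer", "7mer-m8", "7mer-A1"})

KNOWN_PROGRAMS = ("TargetScan", "miRanda", "PITA", "PicTar2", "RNA22", "builtin")

BIOTYPE_CLASSES = ("protein_coding", "lncRNA", "sncRNA", "pseudogene", "circRNA", "other")

_BIOTYPE_MAP: dict[str, str] = {
    "protein_coding": "protein_coding",
    # long non-coding
    "processed_transcript": "lncRNA",
    "lincRNA": "lncRNA",
    "3prime_overlapping_ncrna": "lncRNA",
    "antisense": "lncRNA",
    "non_coding": "lncRNA",
    "sense_intronic": "lncRNA",
    "sense_overlapping": "lncRNA",
    # small non-coding
    "snRNA": "sncRNA",
    "snoRNA": "sncRNA",
    "rRNA": "sncRNA",
    "Mt_tRNA": "sncRNA",
    "Mt_rRNA": "sncRNA",
    "misc_RNA": "sncRNA",
    "miRNA": "sncRNA",
    # pseudogenes
    "polymorphic_pseudogene": "pseudogene",
    "pseudogene": "pseudogene",
    "IG_C_pseudogene": "pseudogene",
    "IG_J_pseudogene": "pseudogene",
    "IG_V_pseudogene": "pseudogene",
    "TR_V_pseudogene": "pseudogene",
    "TR_J_pseudogene": "pseudogene",
    # circBase transcripts carry no GENCODE biotype; accept the literal tag
    "circRNA": "circRNA",
}


def classify_biotype(gene_biotype: str) -> str:
    """Map an annotation gene_biotype string to a coarse biotype class."""
    return _BIOTYPE_MAP.get(gene_biotype, "other")


def reverse_complement_dna(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN)."""
    return seq.translate(_DNA_COMP)[::-1]


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA with its family assignment."""

    mirna_id: str
    mature_sequence: str
    family_id: str = ""

    def __post_init__(self) -> None:
        if len(self.mature_sequence) < 8:
            raise ValueError(f"{self.mirna_id}: mature sequence shorter than 8 nt")
        bad = set(self.mature_sequence) - _RNA
        if bad:
            raise ValueError(
                f"{self.mirna_id}: mature sequence must be RNA (A/C/G/U), "
                f"found {sorted(bad)}"
            )

    @property
    def seed7(self) -> str:
        """Positions 2-8 of the mature sequence (1-based), a 7-mer."""
        return self.mature_sequence[1:8]


@dataclass(frozen=True)
class MirnaFamily:
    """A set of miRNAs sharing the seed (mature positions 2-8)."""

    family_id: str
    member_ids: frozenset[str]
    seed7: str

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"family {self.family_id} has no members")
        if len(self.seed7) != 7 or set(self.seed7) - _RNA:
            raise ValueError(f"family {self.family_id}: seed7 must be a 7-mer over ACGU")


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with gene attribution and biotype class."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    biotype_class: str
    sequence: str
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.biotype_class not in BIOTYPE_CLASSES:
            raise ValueError(f"unknown biotype class {self.biotype_class!r}")
        bad = set(self.sequence.upper()) - _DNA
        if bad:
            raise ValueError(
                f"{self.transcript_id}: sequence must be DNA (A/C/G/T/N), "
                f"found {sorted(bad)}"
            )


@dataclass(frozen=True)
class PredictedSite:
    """A single-program (or built-in scanner) target-site call."""

    family_id: str
    gene_id: str
    start: int
    end: int
    site_type: str
    program: str
    chrom: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.program == "builtin" and not 6 <= self.end - self.start <= 8:
            raise ValueError("builtin site length must be in [6, 8] bp")


@dataclass
class InteractionSite:
    """A merged miRNA-family target site with program and CLIP evidence."""

    family_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    programs: frozenset[str] = frozenset()
    supporting_experiments: int = 0
    total_overlapping_read_count: int = 0

    @property
    def program_count(self) -> int:
        return len(self.programs)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def is_clip_supported(self) -> bool:
        return self.supporting_experiments >= 1


def collapse_families(mirnas: Iterable[MirnaRecord]) -> list[MirnaFamily]:
    """Group miRNAs into seed families by family_id.

    miRNAs with an empty family_id become singleton families named after
    the mirna_id, so no catalog entry is silently dropped.  Members of one
    family must share mature positions 2-8 exactly.
    """
    groups: dict[str, list[MirnaRecord]] = {}
    for rec in mirnas:
        fam = rec.family_id or rec.mirna_id
        groups.setdefault(fam, []).append(rec)
    families = []
    for fam_id in sorted(groups):
        members = sorted(groups[fam_id], key=lambda r: r.mirna_id)
        seeds = {m.seed7 for m in members}
        if len(seeds) > 1:
            ids = ", ".join(m.mirna_id for m in members)
            raise ValueError(
                f"family {fam_id}: members differ at mature positions 2-8 ({ids})"
            )
        families.append(
            MirnaFamily(
                family_id=fam_id,
                member_ids=frozenset(m.mirna_id for m in members),
                seed7=members[0].seed7,
            )
        )
    return families


def scan_seed_sites(
    transcript: TranscriptRecord,
    family: MirnaFamily,
    enabled_site_types: frozenset[str] = DEFAULT_SITE_TYPES,
) -> list[PredictedSite]:
    """Call seed-match sites for one family on one transcript.

    The transcript is scanned (sense strand, DNA) for the reverse
    complement of the seed core (miRNA positions 2-7); each occurrence is
    classified by the presence of the position-8 match immediately 5' and
    the A1 adenosine immediately 3' on the transcript.  Only the highest
    class a locus reaches is reported; a site whose class is not in
    ``enabled_site_types`` is dropped.  Coordinates are transcript-space,
    0-based half-open.
    """
    unknown = set(enabled_site_types) - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site types: {sorted(unknown)}")
    seq = transcript.sequence.upper()
    seed = rna_to_dna(family.seed7)
    match6 = reverse_complement_dna(seed[:6])  # rc of positions 2-7
    m8_comp = reverse_complement_dna(seed[6])  # transcript base pairing position 8
    sites: list[PredictedSite] = []
    p = seq.find(match6)
    while p != -1:
        has_m8 = p >= 1 and seq[p - 1] == m8_comp
        has_a1 = p + 6 < len(seq) and seq[p + 6] == "A"
        if has_m8 and has_a1:
            site_type, start, end = "8mer", p - 1, p + 7
        elif has_m8:
            site_type, start, end = "7mer-m8", p - 1, p + 6
        elif has_a1:
            site_type, start, end = "7mer-A1", p, p + 7
        else:
            site_type, start, end = "6mer", p, p + 6
        if site_type in enabled_site_types:
            sites.append(
                PredictedSite(
                    family_id=family.family_id,
                    gene_id=transcript.gene_id,
                    start=start,
                    end=end,
                    site_type=site_type,
                    program="builtin",
                    chrom=transcript.transcript_id,
                    strand="+",
                )
            )
        p = seq.find(match6, p + 1)
    return sites


@dataclass
class PredictionLoad:
    """Result of ingesting external prediction files."""

    sites: list[PredictedSite]
    n_dropped: int = 0
    unknown_programs: list[str] = field(default_factory=list)


def load_program_predictions(
    handle: IO[str] | Iterable[str],
    families: Sequence[MirnaFamily],
) -> PredictionLoad:
    """Ingest a prediction TSV tagged by program.

    Columns: program, mirna_id, gene_id, chrom, start, end, strand.
    miRNA ids are mapped to family ids via the collapsed catalog (family
    ids themselves are also accepted); rows whose miRNA is absent from the
    catalog are dropped and counted.  An unknown program tag triggers a
    warning but the row is kept with its literal tag.
    """
    member_to_family: dict[str, str] = {}
    for fam in families:
        member_to_family[fam.family_id] = fam.family_id
        for member in fam.member_ids:
            member_to_family[member] = fam.family_id
    sites: list[PredictedSite] = []
    n_dropped = 0
    unknown: list[str] = []
    reader = csv.DictReader(handle, delimiter="\t")
    for row in reader:
        program = row["program"]
        if program not in KNOWN_PROGRAMS and program not in unknown:
            unknown.append(program)
            warnings.warn(f"unknown program tag {program!r}; keeping its rows")
        family_id = member_to_family.get(row["mirna_id"])
        if family_id is None:
            n_dropped += 1
            continue
        sites.append(
            PredictedSite(
                family_id=family_id,
                gene_id=row["gene_id"],
                start=int(row["start"]),
                end=int(row["end"]),
                site_type="external",
                program=program,
                chrom=row.get("chrom", "") or "",
                strand=row.get("strand", "+") or "+",
            )
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} prediction rows with unmappable miRNA ids")
    return PredictionLoad(sites=sites, n_dropped=n_dropped, unknown_programs=unknown)


def merge_evidence(sites: Iterable[PredictedSite]) -> list[InteractionSite]:
    """Merge per-program sites into family-gene interaction sites.

    Sites with identical (family_id, gene_id, chrom, strand) whose
    intervals overlap by >=1 bp are merged transitively; the merged
    interval is the union span and programs are the set union.  The result
    is sorted by (family_id, gene_id, chrom, start).
    """
    groups: dict[tuple[str, str, str, str], list[PredictedSite]] = {}
    for s in sites:
        groups.setdefault((s.family_id, s.gene_id, s.chrom, s.strand), []).append(s)
    merged: list[InteractionSite] = []
    for (family_id, gene_id, chrom, strand) in sorted(groups):
        run = sorted(groups[(family_id, gene_id, chrom, strand)], key=lambda s: (s.start, s.end))
        cur_start, cur_end = run[0].start, run[0].end
        cur_programs = {run[0].program}
        for s in run[1:]:
            if s.start < cur_end:  # >=1 bp overlap; adjacency does not merge
                cur_end = max(cur_end, s.end)
                cur_programs.add(s.program)
            else:
                merged.append(
                    InteractionSite(
                        family_id, gene_id, chrom, cur_start, cur_end, strand,
                        frozenset(cur_programs),
                    )
                )
                cur_start, cur_end, cur_programs = s.start, s.end, {s.program}
        merged.append(
            InteractionSite(
                family_id, gene_id, chrom, cur_start, cur_end, strand,
                frozenset(cur_programs),
            )
        )
    return merged


def annotate_interactions(
    interactions: Sequence[InteractionSite],
    experiments: Iterable[ClipExperiment],
    **kwargs,
) -> list[InteractionSite]:
    """Fill CLIP-support fields on interaction sites (returns new records)."""
    supports = annotate_clip_support(interactions, experiments, **kwargs)
    return [
        replace(
            site,
            supporting_experiments=sup.supporting_experiments,
            total_overlapping_read_count=sup.total_overlapping_read_count,
        )
        for site, sup in zip(interactions, supports)
    ]


def filter_interactions(
    sites: Iterable[InteractionSite],
    min_experiments: int = 1,
    min_programs: int = 1,
) -> list[InteractionSite]:
    """Keep sites passing the CLIP-support and program-count stringency.

    A site passes when supporting_experiments >= min_experiments AND
    program_count >= min_programs; the built-in scanner counts as one
    program.  Thresholds of (0, 0) are the identity filter.
    """
    if min_experiments < 0 or min_programs < 0:
        raise ValueError("stringency thresholds must be non-negative")
    return [
        s
        for s in sites
        if s.supporting_experiments >= min_experiments
        and s.program_count >= min_programs
    ]


# ---------------------------------------------------------------------------
# table I/O

_SITE_COLUMNS = [
    "family_id",
    "gene_id",
    "chrom",
    "start",
    "end",
    "strand",
    "programs",
    "supporting_experiments",
    "total_overlapping_read_count",
]


def write_interaction_table(sites: Iterable[InteractionSite], path: str | Path) -> None:
    """Write interaction sites as TSV (programs comma-joined, sorted)."""
    with Path(path).open("w") as handle:
        handle.write("\t".join(_SITE_COLUMNS) + "\n")
        for s in sites:
            handle.write(
                "\t".join(
                    [
                        s.family_id,
                        s.gene_id,
                        s.chrom,
                        str(s.start),
                        str(s.end),
                        s.strand,
                        ",".join(sorted(s.programs)),
                        str(s.supporting_experiments),
                        str(s.total_overlapping_read_count),
                    ]
                )
                + "\n"
            )


def read_interaction_table(path: str | Path) -> list[InteractionSite]:
    with Path(path).open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        return [
            InteractionSite(
                family_id=row["family_id"],
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                programs=frozenset(p for p in row["programs"].split(",") if p),
                supporting_experiments=int(row["supporting_experiments"]),
                total_overlapping_read_count=int(row["total_overlapping_read_count"]),
            )
            for row in reader
        ]


def read_mirna_catalog(path: str | Path) -> list[MirnaRecord]:
    """TSV columns: mirna_id, family_id, mature_sequence."""
    with Path(path).open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        return [
            MirnaRecord(
                mirna_id=row["mirna_id"],
                family_id=row.get("family_id", "") or "",
                mature_sequence=row["mature_sequence"],
            )
            for row in reader
        ]


def read_transcripts(
    fasta_path: str | Path, table_path: str | Path
) -> list[TranscriptRecord]:
    """Join a transcript FASTA with its annotation table.

    Table columns: transcript_id, gene_id, gene_symbol, gene_biotype.
    Transcripts present in only one of the two inputs raise an error.
    """
    from Bio import SeqIO

    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    records: list[TranscriptRecord] = []
    with Path(table_path).open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            tid = row["transcript_id"]
            if tid not in seqs:
                raise ValueError(f"transcript {tid} missing from FASTA")
            records.append(
                TranscriptRecord(
                    transcript_id=tid,
                    gene_id=row["gene_id"],
                    gene_symbol=row.get("gene_symbol", row["gene_id"]),
                    biotype_class=classify_biotype(row["gene_biotype"]),
                    sequence=seqs.pop(tid),
                )
            )
    if seqs:
        raise ValueError(f"FASTA transcripts missing from table: {sorted(seqs)[:5]}")
    return records
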