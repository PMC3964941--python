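"""Strand-aware genomic intervals, BED6 I/O and CLIP-cluster support.

Coordinates are 0-based half-open throughout (BED convention).  CLIP
binding-site clusters are strand-specific — Argonaute binds the transcribed
strand — so overlap requires matching strands by default, with "." acting
as a wildcard.  Support for a site is counted per distinct experiment, not
per cluster: a site covered by five clusters of one HITS-CLIP library has
one supporting experiment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

#: CLIP protocols recognised in experiment metadata.
PROTOCOLS = ("HITS-CLIP", "PAR-CLIP", "iCLIP", "CLASH", "other")


class BedParseError(ValueError):
    """Raised for malformed BED input; the message names the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "requires 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ClipCluster:
    """One CLIP binding-site cluster: the unit of CLIP evidence."""

    interval: GenomicInterval
    cluster_id: str
    read_count: int = 0
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")
        if not self.experiment_id:
            raise ValueError("experiment_id must be non-empty")


@dataclass
class ClipExperiment:
    """A CLIP-seq library with its clusters and provenance metadata."""

    experiment_id: str
    rbp_name: str = "AGO"
    cell_line: str = ""
    protocol: str = "other"
    clusters: list[ClipCluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}, got {self.protocol!r}")
        for c in self.clusters:
            if c.experiment_id != self.experiment_id:
                raise ValueError(
                    f"cluster {c.cluster_id} carries experiment_id "
                    f"{c.experiment_id!r}, expected {self.experiment_id!r}"
                )


@dataclass(frozen=True)
class ClipSupport:
    """Per-site CLIP support across a panel of experiments."""

    supporting_experiments: int
    total_overlapping_read_count: int

    @property
    def is_clip_supported(self) -> bool:
        return self.supporting_experiments >= 1


def parse_bed(lines: Iterable[str], experiment_id: str) -> list[ClipCluster]:
    """Parse BED (>=3 columns) text into ClipClusters.

    Fields 4-6 (name, score, strand) are optional; a missing strand becomes
    "." and a missing score becomes read_count 0.  Comment lines ("#"),
    "track" and "browser" lines, and blank lines are skipped.  Coordinates
    are taken verbatim as 0-based half-open.
    """
    clusters: list[ClipCluster] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedParseError(f"fewer than 3 fields at line {lineno}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"non-integer coordinate at line {lineno}") from exc
        if end <= start:
            raise BedParseError(f"end <= start at line {lineno}")
        name = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
        score = 0
        if len(fields) > 4 and fields[4] not in ("", "."):
            try:
                score = int(round(float(fields[4])))
            except ValueError as exc:
                raise BedParseError(f"non-numeric score at line {lineno}") from exc
        strand = fields[5] if len(fields) > 5 and fields[5] else "."
        clusters.append(
            ClipCluster(
                interval=GenomicInterval(chrom, start, end, strand),
                cluster_id=name,
                read_count=max(score, 0),
                experiment_id=experiment_id,
            )
        )
    return clusters


def write_bed(clusters: Iterable[ClipCluster], handle: IO[str]) -> None:
    """Write clusters as BED6 (chrom, start, end, name, score, strand)."""
    for c in clusters:
        iv = c.interval
        handle.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.cluster_id}\t{c.read_count}\t{iv.strand}\n"
        )


def _strands_compatible(a: str, b: str) -> bool:
    return a == "." or b == "." or a == b


def overlap_length(
    a: GenomicInterval, b: GenomicInterval, same_strand_required: bool = True
) -> int:
    """Overlap in bp between two intervals; 0 if chrom/strand incompatible.

    "Overlaps" in the rest of the package means a return value >= 1;
    half-open adjacency ([0,10) vs [10,20)) does not overlap.
    """
    if a.chrom != b.chrom:
        return 0
    if same_strand_required and not _strands_compatible(a.strand, b.strand):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _interval_of(site) -> GenomicInterval:
    if isinstance(site, GenomicInterval):
        return site
    return site.interval


def _strip_chr(name: str) -> str:
    return name[3:] if name.startswith("chr") else name


def annotate_clip_support(
    sites: Sequence,
    experiments: Iterable[ClipExperiment],
    *,
    min_overlap: int = 1,
    same_strand_required: bool = True,
    normalize_chrom: bool = False,
) -> list[ClipSupport]:
    """Annotate each site with its CLIP support across experiments.

    Parameters
    ----------
    sites
        GenomicIntervals, or any records exposing an ``interval`` attribute.
    experiments
        The CLIP experiment panel; supporting experiments are counted per
        distinct ``experiment_id`` with at least one overlapping cluster.
    min_overlap
        Minimum overlap in bp for a cluster to count (default 1, the
        BEDTools default).
    normalize_chrom
        Strip a leading ``chr`` prefix before comparing sequence names
        (off by default: names are compared as exact strings).

    Returns
    -------
    One :class:`ClipSupport` per site, in input order.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for exp in experiments:
        for c in exp.clusters:
            iv = c.interval
            chrom = _strip_chr(iv.chrom) if normalize_chrom else iv.chrom
            trees.setdefault(chrom, IntervalTree()).addi(iv.start, iv.end, c)

    out: list[ClipSupport] = []
    for site in sites:
        iv = _interval_of(site)
        chrom = _strip_chr(iv.chrom) if normalize_chrom else iv.chrom
        exp_ids: set[str] = set()
        reads = 0
        tree = trees.get(chrom)
        if tree is not None:
            for hit in tree.overlap(iv.start, iv.end):
                c: ClipCluster = hit.data
                if same_strand_required and not _strands_compatible(
                    iv.strand, c.interval.strand
                ):
                    continue
                ov = min(iv.end, c.interval.end) - max(iv.start, c.interval.start)
                if ov >= min_overlap:
                    exp_ids.add(c.experiment_id)
                    reads += c.read_count
        out.append(ClipSupport(len(exp_ids), reads))
    return out


def read_experiment_table(path: str | Path) -> list[ClipExperiment]:
    """Load the experiment metadata sidecar and the BED files it names.

    TSV columns: experiment_id, rbp_name, cell_line, protocol, bed_path.
    Relative bed_path entries resolve against the sidecar's directory.
    """
    path = Path(path)
    experiments: list[ClipExperiment] = []
    with path.open() as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"experiment_id", "rbp_name", "cell_line", "protocol", "bed_path"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"experiment table must have columns {sorted(required)}")
        for row in reader:
            bed_path = Path(row["bed_path"])
            if not bed_path.is_absolute():
                bed_path = path.parent / bed_path
            with bed_path.open() as bed:
                clusters = parse_bed(bed, row["experiment_id"])
            experiments.append(
                ClipExperiment(
                    experiment_id=row["experiment_id"],
                    rbp_name=row["rbp_name"],
                    cell_line=row["cell_line"],
                    protocol=row["protocol"],
                    clusters=clusters,
                )
            )
    return experiments
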