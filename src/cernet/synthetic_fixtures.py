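"""Deterministic synthetic inputs with planted ground truth.

The generator emulates the data a CLIP-supported ceRNA analysis consumes:
a miRNA catalog collapsed into seed families, transcripts carrying planted
8mer seed sites, per-experiment CLIP cluster BED files covering planted
sites with a configurable probability, and (optionally) planted ceRNA
pairs with an exact shared-family count and planted sponge transcripts.

Two properties make the fixtures exact rather than probabilistic:

* family seeds are drawn so that no seed core (positions 2-7) collides
  with another family's core, nor with the unintended 6-nt windows of any
  planted 8-mer target, so scanner attribution is unambiguous;
* background sequence is mutated until it contains no family's seed-core
  complement outside the planted loci, so every scanner call off a planted
  locus is a genuine false positive.

Each transcript is emitted as its own contig (single-exon gene), so
transcript space and genome space coincide and CLIP BED files share the
scanner's coordinate system.  Every emitted file has its own RNG stream
derived from the master seed by a stable label, so adding an output never
perturbs existing ones; identical config and seed give byte-identical
bundles.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from cernet.cerna_network import GeneFamilyProfile
from cernet.genomic_core import ClipCluster, ClipExperiment, GenomicInterval, write_bed
from cernet.target_discovery import (
    MirnaFamily,
    MirnaRecord,
    TranscriptRecord,
    classify_biotype,
    reverse_complement_dna,
    rna_to_dna,
)

_BASES = np.array(list("ACGT"))
_RNA_BASES = np.array(list("ACGU"))

#: gene_biotype strings sampled for background genes, with weights
_BIOTYPE_POOL = ["protein_coding", "lincRNA", "pseudogene", "antisense", "snoRNA"]
_BIOTYPE_WEIGHTS = [0.60, 0.15, 0.10, 0.10, 0.05]

_SITE_LEN = 8
_MIN_GAP = 5  # keeps any 6-nt window from spanning two planted sites
_SLOT = _SITE_LEN + _MIN_GAP


def _rng(seed: int, label: str) -> np.random.Generator:
    """One RNG stream per output, keyed by a stable label."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


@dataclass(frozen=True)
class PlantedPair:
    gene_a: str
    gene_b: str
    n_shared: int


@dataclass(frozen=True)
class PlantedSponge:
    family_id: str
    gene_id: str
    n_sites: int


@dataclass(frozen=True)
class FixtureConfig:
    rng_seed: int = 0
    n_families: int = 150
    n_null_genes: int = 180
    families_per_gene: int = 10
    transcript_length: tuple[int, int] = (500, 1500)
    mirnas_per_family: int = 2
    n_experiments: int = 3
    p_support: float = 1.0
    n_decoy_clusters: int = 20
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_sponges: tuple[PlantedSponge, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_support <= 1.0:
            raise ValueError("p_support must lie in [0, 1]")
        if self.families_per_gene < 1 or self.families_per_gene > self.n_families:
            raise ValueError("families_per_gene must lie in [1, n_families]")
        for pair in self.planted_pairs:
            if not 0 <= pair.n_shared <= self.families_per_gene:
                raise ValueError(
                    f"pair {pair.gene_a}/{pair.gene_b}: n_shared must be "
                    f"<= families_per_gene"
                )
        max_sites = max(
            [self.families_per_gene] + [s.n_sites for s in self.planted_sponges]
        )
        if self.transcript_length[0] < _SLOT * max_sites - _MIN_GAP:
            raise ValueError(
                f"transcripts of length {self.transcript_length[0]} cannot hold "
                f"{max_sites} planted sites"
            )


@dataclass
class FixtureTruth:
    """Planted truth, consistent with the emitted files by construction."""

    sites: pd.DataFrame           # gene, transcript, family, start, end, coverage
    pairs: pd.DataFrame           # gene_a, gene_b, n_shared
    profiles: dict[str, GeneFamilyProfile]
    sponges: pd.DataFrame         # family_id, gene_id, n_sites


@dataclass
class FixtureBundle:
    config: FixtureConfig
    mirnas: list[MirnaRecord]
    families: list[MirnaFamily]
    transcripts: list[TranscriptRecord]
    experiments: list[ClipExperiment]
    truth: FixtureTruth
    paths: dict[str, Path] = field(default_factory=dict)


def planted_pair_specs(n_pairs: int, n_shared: int) -> tuple[PlantedPair, ...]:
    """Convenience roster of planted ceRNA pairs named CPxxA/CPxxB."""
    return tuple(
        PlantedPair(f"CP{i:02d}A", f"CP{i:02d}B", n_shared) for i in range(n_pairs)
    )


# ---------------------------------------------------------------------------
# seed drawing

def _draw_family_seeds(rng: np.random.Generator, n_families: int) -> list[str]:
    """Unique seeds whose planted 8-mers cannot cross-attribute.

    Enforces: distinct seed cores (positions 2-7) as 6-mers; no family's
    planted 8-mer contains another family's core — or its own core twice —
    in the two unintended 6-nt windows.
    """
    cores: set[str] = set()
    windows: set[str] = set()
    seeds: list[str] = []
    attempts = 0
    while len(seeds) < n_families:
        attempts += 1
        if attempts > 200 * n_families:
            raise RuntimeError("could not draw non-colliding family seeds")
        seed7 = "".join(rng.choice(_RNA_BASES, size=7))
        match7 = reverse_complement_dna(rna_to_dna(seed7))
        match8 = match7 + "A"
        core = match8[1:7]  # rc of positions 2-7
        own_windows = [match8[0:6], match8[2:8]]
        if core in cores or core in windows:
            continue
        if any(w in cores or w == core for w in own_windows):
            continue
        cores.add(core)
        windows.update(own_windows)
        seeds.append(seed7)
    return seeds


def _make_catalog(
    config: FixtureConfig,
) -> tuple[list[MirnaRecord], list[MirnaFamily], dict[str, str]]:
    rng = _rng(config.rng_seed, "mirnas")
    seeds = _draw_family_seeds(rng, config.n_families)
    mirnas: list[MirnaRecord] = []
    families: list[MirnaFamily] = []
    seed_of: dict[str, str] = {}
    for i, seed7 in enumerate(seeds):
        fam_id = f"FAM{i:03d}"
        seed_of[fam_id] = seed7
        members = []
        for j in range(config.mirnas_per_family):
            mature = (
                "".join(rng.choice(_RNA_BASES, size=1))
                + seed7
                + "".join(rng.choice(_RNA_BASES, size=14))
            )
            rec = MirnaRecord(
                mirna_id=f"syn-miR-{i}-{chr(ord('a') + j)}",
                mature_sequence=mature,
                family_id=fam_id,
            )
            members.append(rec)
        mirnas.extend(members)
        families.append(
            MirnaFamily(
                family_id=fam_id,
                member_ids=frozenset(m.mirna_id for m in members),
                seed7=seed7,
            )
        )
    return mirnas, families, seed_of


# ---------------------------------------------------------------------------
# gene roster and family assignment

def _assign_families(config: FixtureConfig, family_ids: list[str]) -> dict[str, list[str]]:
    """Per-gene family lists (null genes, planted pairs, sponge genes)."""
    rng = _rng(config.rng_seed, "profiles")
    fam_arr = np.array(family_ids)
    k = config.families_per_gene
    assignment: dict[str, list[str]] = {}
    for i in range(config.n_null_genes):
        gene = f"G{i:04d}"
        assignment[gene] = sorted(rng.choice(fam_arr, size=k, replace=False))
    for pair in config.planted_pairs:
        for gene in (pair.gene_a, pair.gene_b):
            if gene in assignment:
                raise ValueError(f"planted gene name collides: {gene}")
        chosen = rng.choice(fam_arr, size=2 * k - pair.n_shared, replace=False)
        shared = list(chosen[: pair.n_shared])
        extra_a = list(chosen[pair.n_shared : k])
        extra_b = list(chosen[k : 2 * k - pair.n_shared])
        assignment[pair.gene_a] = sorted(shared + extra_a)
        assignment[pair.gene_b] = sorted(shared + extra_b)
    for sponge in config.planted_sponges:
        if sponge.family_id not in set(family_ids):
            raise ValueError(f"unknown sponge family {sponge.family_id}")
        if sponge.gene_id in assignment:
            raise ValueError(f"sponge gene name collides: {sponge.gene_id}")
        assignment[sponge.gene_id] = [sponge.family_id] * sponge.n_sites
    return assignment


# ---------------------------------------------------------------------------
# sequence construction

def _plant_sequence(
    rng: np.random.Generator,
    length: int,
    plants: list[tuple[str, str]],  # (family_id, match8)
    forbidden_cores: set[str],
) -> tuple[str, list[tuple[str, int]]]:
    """Random sequence with the given 8-mers planted and background clean.

    Returns the sequence and (family_id, start) per planted site.  Planted
    sites keep >= 5 bp gaps so no 6-nt window spans two sites; background
    positions are mutated until no forbidden core occurs outside plants.
    """
    m = len(plants)
    span = _SLOT * m - _MIN_GAP if m else 0
    if span > length:
        raise ValueError("planted sites do not fit in the transcript")
    seq = list(rng.choice(_BASES, size=length))
    planted = np.zeros(length, dtype=bool)
    positions: list[tuple[str, int]] = []
    if m:
        offsets = np.sort(rng.integers(0, length - span + 1, size=m))
        order = rng.permutation(m)
        for rank, idx in enumerate(order):
            fam_id, match8 = plants[idx]
            pos = int(offsets[rank]) + _SLOT * rank
            seq[pos : pos + _SITE_LEN] = list(match8)
            planted[pos : pos + _SITE_LEN] = True
            positions.append((fam_id, pos))
        positions.sort(key=lambda t: t[1])
    for _ in range(200):
        offending = []
        for i in range(length - 5):
            if not planted[i : i + 6].all() and "".join(seq[i : i + 6]) in forbidden_cores:
                offending.append(i)
        if not offending:
            break
        for i in offending:
            mutable = [j for j in range(i, i + 6) if not planted[j]]
            j = int(rng.choice(mutable))
            seq[j] = str(rng.choice(_BASES[_BASES != seq[j]]))
    else:
        raise RuntimeError("background clean-up did not converge")
    return "".join(seq), positions


# ---------------------------------------------------------------------------
# main entry points

def simulate_universe(
    config: FixtureConfig, out_dir: str | Path | None = None
) -> FixtureBundle:
    """Generate the full synthetic bundle; optionally write it to disk."""
    mirnas, families, seed_of = _make_catalog(config)
    family_ids = [f.family_id for f in families]
    match8_of = {
        fam: reverse_complement_dna(rna_to_dna(seed)) + "A"
        for fam, seed in seed_of.items()
    }
    forbidden = {m8[1:7] for m8 in match8_of.values()}
    assignment = _assign_families(config, family_ids)
    genes = sorted(assignment)

    bio_rng = _rng(config.rng_seed, "biotypes")
    special = {p.gene_a for p in config.planted_pairs} | {
        p.gene_b for p in config.planted_pairs
    }
    sponge_genes = {s.gene_id for s in config.planted_sponges}
    biotype_of: dict[str, str] = {}
    for gene in genes:
        if gene in special:
            biotype_of[gene] = "protein_coding"
        elif gene in sponge_genes:
            biotype_of[gene] = "circRNA"
        else:
            biotype_of[gene] = str(
                bio_rng.choice(_BIOTYPE_POOL, p=_BIOTYPE_WEIGHTS)
            )

    seq_rng = _rng(config.rng_seed, "sequences")
    lo, hi = config.transcript_length
    transcripts: list[TranscriptRecord] = []
    site_rows: list[dict] = []
    for gene in genes:
        tid = f"{gene}.t1"
        length = int(seq_rng.integers(lo, hi + 1))
        plants = [(fam, match8_of[fam]) for fam in assignment[gene]]
        seq, positions = _plant_sequence(seq_rng, length, plants, forbidden)
        transcripts.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=gene,
                gene_symbol=gene,
                biotype_class=classify_biotype(biotype_of[gene]),
                sequence=seq,
            )
        )
        for fam, pos in positions:
            site_rows.append(
                {
                    "gene_id": gene,
                    "transcript_id": tid,
                    "family_id": fam,
                    "start": pos,
                    "end": pos + _SITE_LEN,
                    "site_type": "8mer",
                }
            )
    sites = pd.DataFrame(site_rows)
    tx_length = {t.transcript_id: len(t.sequence) for t in transcripts}

    exp_ids = [f"EXP{i:02d}" for i in range(config.n_experiments)]
    experiments: list[ClipExperiment] = []
    for exp_id in exp_ids:
        rng = _rng(config.rng_seed, f"clip/{exp_id}")
        clusters: list[ClipCluster] = []
        covered_flags = []
        for row in sites.itertuples():
            covered = bool(rng.random() < config.p_support)
            covered_flags.append(covered)
            if covered:
                fl = int(rng.integers(3, 15))
                fr = int(rng.integers(3, 15))
                start = max(0, row.start - fl)
                end = min(tx_length[row.transcript_id], row.end + fr)
                clusters.append(
                    ClipCluster(
                        interval=GenomicInterval(row.transcript_id, start, end, "+"),
                        cluster_id=f"{exp_id}_c{len(clusters)}",
                        read_count=int(rng.integers(1, 100)),
                        experiment_id=exp_id,
                    )
                )
        if len(sites):
            sites[f"covered_{exp_id}"] = covered_flags
        # decoy clusters placed away from every planted site
        by_tx = (
            {t: g[["start", "end"]].to_numpy() for t, g in sites.groupby("transcript_id")}
            if len(sites)
            else {}
        )
        for d in range(config.n_decoy_clusters):
            for _ in range(100):
                tx = transcripts[int(rng.integers(0, len(transcripts)))]
                length = int(rng.integers(20, 40))
                if tx_length[tx.transcript_id] <= length:
                    continue
                start = int(rng.integers(0, tx_length[tx.transcript_id] - length))
                end = start + length
                planted = by_tx.get(tx.transcript_id)
                if planted is not None and np.any(
                    (planted[:, 0] < end) & (start < planted[:, 1])
                ):
                    continue
                clusters.append(
                    ClipCluster(
                        interval=GenomicInterval(tx.transcript_id, start, end, "+"),
                        cluster_id=f"{exp_id}_d{d}",
                        read_count=int(rng.integers(1, 100)),
                        experiment_id=exp_id,
                    )
                )
                break
        experiments.append(
            ClipExperiment(
                experiment_id=exp_id,
                rbp_name="AGO2",
                cell_line="SYN",
                protocol="PAR-CLIP",
                clusters=clusters,
            )
        )
    if len(sites):
        sites["supporting_experiments"] = sites[
            [f"covered_{e}" for e in exp_ids]
        ].sum(axis=1)

    profiles = {
        gene: GeneFamilyProfile(
            gene_id=gene,
            biotype_class=classify_biotype(biotype_of[gene]),
            families=frozenset(assignment[gene]),
        )
        for gene in genes
    }
    truth = FixtureTruth(
        sites=sites,
        pairs=pd.DataFrame(
            [
                {"gene_a": p.gene_a, "gene_b": p.gene_b, "n_shared": p.n_shared}
                for p in config.planted_pairs
            ]
        ),
        profiles=profiles,
        sponges=pd.DataFrame(
            [
                {"family_id": s.family_id, "gene_id": s.gene_id, "n_sites": s.n_sites}
                for s in config.planted_sponges
            ]
        ),
    )
    bundle = FixtureBundle(
        config=config,
        mirnas=mirnas,
        families=families,
        transcripts=transcripts,
        experiments=experiments,
        truth=truth,
    )
    if out_dir is not None:
        bundle.paths = _write_bundle(bundle, Path(out_dir), biotype_of)
    return bundle


def _write_bundle(
    bundle: FixtureBundle, out_dir: Path, biotype_of: Mapping[str, str]
) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out_dir / "transcripts.fa"
    with fasta.open("w") as handle:
        for t in bundle.transcripts:
            handle.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.sequence), 80):
                handle.write(t.sequence[i : i + 80] + "\n")
    paths["transcripts_fasta"] = fasta

    table = out_dir / "transcripts.tsv"
    with table.open("w") as handle:
        handle.write("transcript_id\tgene_id\tgene_symbol\tgene_biotype\n")
        for t in bundle.transcripts:
            handle.write(
                f"{t.transcript_id}\t{t.gene_id}\t{t.gene_symbol}\t"
                f"{biotype_of[t.gene_id]}\n"
            )
    paths["transcript_table"] = table

    catalog = out_dir / "mirnas.tsv"
    with catalog.open("w") as handle:
        handle.write("mirna_id\tfamily_id\tmature_sequence\n")
        for m in bundle.mirnas:
            handle.write(f"{m.mirna_id}\t{m.family_id}\t{m.mature_sequence}\n")
    paths["mirna_catalog"] = catalog

    sidecar = out_dir / "experiments.tsv"
    with sidecar.open("w") as handle:
        handle.write("experiment_id\trbp_name\tcell_line\tprotocol\tbed_path\n")
        for exp in bundle.experiments:
            bed_name = f"{exp.experiment_id}.bed"
            with (out_dir / bed_name).open("w") as bed:
                write_bed(exp.clusters, bed)
            paths[f"bed_{exp.experiment_id}"] = out_dir / bed_name
            handle.write(
                f"{exp.experiment_id}\t{exp.rbp_name}\t{exp.cell_line}\t"
                f"{exp.protocol}\t{bed_name}\n"
            )
    paths["experiment_table"] = sidecar

    gmt = out_dir / "annotation.gmt"
    rng = _rng(bundle.config.rng_seed, "gmt")
    genes = sorted({t.gene_id for t in bundle.transcripts})
    with gmt.open("w") as handle:
        n_terms = 6
        size = min(25, max(2, len(genes) // 3))
        for i in range(n_terms):
            members = sorted(rng.choice(np.array(genes), size=size, replace=False))
            handle.write(
                f"TERM{i:02d}\tsynthetic term {i}\t" + "\t".join(members) + "\n"
            )
    paths["gmt"] = gmt

    truth_sites = out_dir / "truth_sites.tsv"
    bundle.truth.sites.to_csv(truth_sites, sep="\t", index=False)
    paths["truth_sites"] = truth_sites
    truth_pairs = out_dir / "truth_pairs.tsv"
    bundle.truth.pairs.to_csv(truth_pairs, sep="\t", index=False)
    paths["truth_pairs"] = truth_pairs
    return paths


def simulate_null_profiles(
    n_genes: int,
    n_families: int,
    families_per_gene: int,
    rng_seed: int = 0,
) -> dict[str, GeneFamilyProfile]:
    """Independent uniform k-subset profiles — the exact hypergeometric null.

    Each gene's family set is an independent uniform draw of
    ``families_per_gene`` families out of ``n_families``, so the shared
    count between any two genes follows hypergeometric(F, k, k) and the
    upper-tail test is exactly calibrated.
    """
    if families_per_gene < 1:
        raise ValueError("families_per_gene must be >= 1 (profiles are non-empty)")
    if families_per_gene > n_families:
        raise ValueError("families_per_gene cannot exceed n_families")
    rng = _rng(rng_seed, "null_profiles")
    fam_arr = np.array([f"FAM{i:03d}" for i in range(n_families)])
    return {
        f"N{i:04d}": GeneFamilyProfile(
            gene_id=f"N{i:04d}",
            biotype_class="protein_coding",
            families=frozenset(rng.choice(fam_arr, size=families_per_gene, replace=False)),
        )
        for i in range(n_genes)
    }
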