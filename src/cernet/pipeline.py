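"""End-to-end orchestration: scan -> support -> filter -> network -> reports.

The pipeline is deterministic: identical inputs and configuration produce
byte-identical output tables and an identical run manifest.  On a stage
failure, any partial outputs are moved to a ``quarantine/`` subdirectory
and a :class:`PipelineError` naming the stage is raised.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from cernet import __version__
from cernet.cerna_network import (
    build_cerna_network,
    build_family_profiles,
    find_cerna_partners,
    write_edges,
    write_profiles,
)
from cernet.enrichment import enrich, load_gmt, write_enrichment_report
from cernet.genomic_core import read_experiment_table
from cernet.sponge import count_family_sites, rank_sponges, write_sponge_report
from cernet.target_discovery import (
    DEFAULT_SITE_TYPES,
    annotate_interactions,
    collapse_families,
    filter_interactions,
    load_program_predictions,
    merge_evidence,
    read_mirna_catalog,
    read_transcripts,
    scan_seed_sites,
    write_interaction_table,
)

logger = logging.getLogger("cernet")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    transcripts_fasta: str
    transcript_table: str
    mirna_catalog: str
    experiment_table: str
    out_dir: str
    predictions: str | None = None
    gmt: str | None = None
    enrichment_universe: str | None = None
    min_experiments: int = 1
    min_programs: int = 1
    min_common: int = 3
    fdr_threshold: float = 0.05
    fdr_scope: str = "global"  # "global" or "per_query"
    query_gene: str | None = None
    sponge_min_sites: int = 5
    enabled_site_types: tuple[str, ...] = tuple(sorted(DEFAULT_SITE_TYPES))

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import tomllib

        with Path(path).open("rb") as handle:
            data = tomllib.load(handle)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunBundle:
    interactions: list
    profiles: dict
    edges: pd.DataFrame
    sponges: list
    enrichment: pd.DataFrame | None
    manifest: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_full_pipeline(config: PipelineConfig) -> RunBundle:
    """Execute every stage and write the output bundle to ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "catalog"
        logger.info("[%s] loading miRNA catalog", stage)
        mirnas = read_mirna_catalog(config.mirna_catalog)
        families = collapse_families(mirnas)

        stage = "transcripts"
        transcripts = read_transcripts(config.transcripts_fasta, config.transcript_table)
        biotype_of = {t.gene_id: t.biotype_class for t in transcripts}
        symbols = {t.gene_id: t.gene_symbol for t in transcripts}

        stage = "scan"
        enabled = frozenset(config.enabled_site_types)
        predicted = []
        for t in transcripts:
            for fam in families:
                predicted.extend(scan_seed_sites(t, fam, enabled))
        logger.info("[%s] %d scanner sites", stage, len(predicted))
        if config.predictions:
            with open(config.predictions) as handle:
                load = load_program_predictions(handle, families)
            predicted.extend(load.sites)
            logger.info(
                "[%s] %d external sites (%d dropped)",
                stage, len(load.sites), load.n_dropped,
            )

        stage = "merge"
        interactions = merge_evidence(predicted)

        stage = "support"
        experiments = read_experiment_table(config.experiment_table)
        interactions = annotate_interactions(interactions, experiments)

        stage = "filter"
        surviving = filter_interactions(
            interactions, config.min_experiments, config.min_programs
        )
        logger.info("[%s] %d of %d sites pass", stage, len(surviving), len(interactions))
        path = out_dir / "interactions.tsv"
        write_interaction_table(surviving, path)
        written.append(path)

        stage = "profiles"
        profiles = build_family_profiles(surviving, biotype_of)
        path = out_dir / "profiles.tsv"
        write_profiles(profiles, path)
        written.append(path)

        stage = "cerna"
        N = len(families)
        if config.fdr_scope == "per_query":
            if not config.query_gene:
                raise ValueError("fdr_scope 'per_query' requires query_gene")
            edges = find_cerna_partners(
                config.query_gene, profiles, N,
                config.min_common, config.fdr_threshold,
            )
        elif config.fdr_scope == "global":
            edges = (
                build_cerna_network(
                    profiles, N, config.min_common, config.fdr_threshold
                )
                if len(profiles) >= 2
                else pd.DataFrame()
            )
        else:
            raise ValueError(f"unknown fdr_scope {config.fdr_scope!r}")
        path = out_dir / "cerna_edges.tsv"
        write_edges(edges, path)
        written.append(path)

        stage = "sponge"
        sponges = rank_sponges(
            count_family_sites(surviving, symbols), config.sponge_min_sites
        )
        path = out_dir / "sponges.tsv"
        write_sponge_report(sponges, path)
        written.append(path)

        stage = "enrichment"
        enrichment_df = None
        if config.gmt:
            with open(config.gmt) as handle:
                category = load_gmt(handle, Path(config.gmt).stem)
            universe = None
            if config.enrichment_universe:
                universe = [
                    line.strip()
                    for line in Path(config.enrichment_universe).read_text().splitlines()
                    if line.strip()
                ]
            targeted = sorted({s.gene_id for s in surviving})
            if targeted:
                try:
                    enrichment_df = enrich(targeted, category, universe)
                except ValueError:
                    enrichment_df = None
            if enrichment_df is not None:
                path = out_dir / "enrichment.tsv"
                write_enrichment_report(enrichment_df, path)
                written.append(path)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config_hash": _config_hash(config),
            "config": asdict(config),
            "outputs": {p.name: _sha256(p) for p in sorted(written)},
            "inputs": {
                name: _sha256(Path(p))
                for name, p in {
                    "transcripts_fasta": config.transcripts_fasta,
                    "transcript_table": config.transcript_table,
                    "mirna_catalog": config.mirna_catalog,
                    "experiment_table": config.experiment_table,
                }.items()
            },
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(path)
    except Exception as exc:
        quarantine = out_dir / "quarantine"
        quarantine.mkdir(exist_ok=True)
        for p in written:
            if p.exists():
                p.rename(quarantine / p.name)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    return RunBundle(
        interactions=surviving,
        profiles=profiles,
        edges=edges,
        sponges=sponges,
        enrichment=enrichment_df,
        manifest=manifest,
        paths={p.name: p for p in written},
    )


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
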