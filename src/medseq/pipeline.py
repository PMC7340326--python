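"""End-to-end pipeline: simulate -> filter -> map -> count -> regions -> DMR -> cluster.

Stages are pure functions over files; every intermediate is written, and a
run-report JSON records per-stage counts, wall time, and a checksum for
every declared output so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import dmr as dmr_mod
from .reads import filter_reads, map_reads_exact, read_fastq, write_fastq
from .reference import MotifSpec, build_region_catalog, load_bed_intervals, load_gene_table, load_genome
from .regions import aggregate_regions
from .scoring import assign_site_counts, merge_profiles, write_bedgraph
from .simulate import (
    SimulationConfig,
    assign_methylation,
    exhaustion_demo_dmrs,
    generate_reference,
    simulate_sample_set,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for a full run."""

    output_dir: str = "medseq_run"
    genome_fasta: str | None = None
    gene_table: str | None = None
    islands_bed: str | None = None
    manifest: str | None = None  # sample_id, condition, fastq columns
    motif: str = "CCGG"
    anchor_offset: int = 1
    both_strands: bool = True
    min_offset: int = 13
    max_offset: int = 17
    multimap_policy: str = "fractional"
    group_pair: tuple[str, str] = ("single", "repeat")
    correction: str = "bonferroni"
    alpha: float = 0.05
    min_sites: int = 10
    min_span_bp: int = 100
    fold_threshold: float = 2.0
    seed: int = 0
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    replicates: dict = field(default_factory=lambda: {"single": 2, "repeat": 2})

    def motif_spec(self) -> MotifSpec:
        return MotifSpec(self.motif, self.anchor_offset, self.both_strands)

    def dmr_config(self) -> dmr_mod.DMRTestConfig:
        return dmr_mod.DMRTestConfig(
            correction=self.correction,
            alpha=self.alpha,
            min_sites=self.min_sites,
            min_span_bp=self.min_span_bp,
            fold_threshold=self.fold_threshold,
        )

    def validate(self) -> None:
        if not self.simulate:
            for label, path in (
                ("genome_fasta", self.genome_fasta),
                ("gene_table", self.gene_table),
                ("islands_bed", self.islands_bed),
                ("manifest", self.manifest),
            ):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{label}: missing input file {path!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "group_pair" in raw:
            raw["group_pair"] = tuple(raw["group_pair"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["group_pair"] = list(self.group_pair)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _checksum(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, returning (and writing) the run report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "outputs": {}, "seed": config.seed}
    motif = config.motif_spec()

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                report["stages"].setdefault(name, {})
                self.t0 = time.time()
                return self

            def __exit__(self, *exc):
                report["stages"][name]["seconds"] = round(time.time() - self.t0, 3)
                return False

        return _Timer()

    # --- reference / simulation ------------------------------------------
    with stage("reference"):
        if config.simulate:
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", config.seed)
            sim_kwargs["motif"] = motif
            sim_config = SimulationConfig(**sim_kwargs)
            genome, site_index, catalog = generate_reference(sim_config)
            truth = assign_methylation(
                site_index,
                catalog,
                planted=exhaustion_demo_dmrs(catalog, hyper_condition=config.group_pair[1]),
                conditions=tuple(config.replicates),
            )
            truth.to_json(out / "truth.json")
            manifest = simulate_sample_set(
                genome, site_index, truth, sim_config, config.replicates, out / "fastq"
            )
        else:
            genome = load_genome(config.genome_fasta)
            from .reference import build_site_index

            site_index = build_site_index(genome, motif)
            genes = load_gene_table(config.gene_table)
            islands = load_bed_intervals(config.islands_bed)
            catalog = build_region_catalog(genes, islands, genome.lengths)
            manifest = pd.read_csv(config.manifest, sep="\t")
        report["stages"]["reference"] = {
            "n_sites": site_index.n_sites,
            "n_genes": len(catalog.tss_windows),
            "n_islands": len(catalog.cpg_islands),
        }

    # --- filter / map / count --------------------------------------------
    profiles = []
    group_map = {}
    with stage("filter_map_count"):
        for row in manifest.itertuples():
            reads = list(read_fastq(row.fastq))
            kept, filter_report = filter_reads(
                reads, motif, config.min_offset, config.max_offset
            )
            (out / "filter").mkdir(exist_ok=True)
            (out / "filter" / f"{row.sample_id}.json").write_text(
                json.dumps(filter_report.as_dict(), indent=1)
            )
            write_fastq(kept, out / "filter" / f"{row.sample_id}.kept.fastq")
            placements, _map_report = map_reads_exact(kept, genome, config.multimap_policy)
            profile = assign_site_counts(
                placements, site_index, row.sample_id, config.min_offset, config.max_offset
            )
            (out / "counts").mkdir(exist_ok=True)
            write_bedgraph(profile, site_index, out / "counts" / f"{row.sample_id}.bedgraph")
            profiles.append(profile)
            group_map[row.sample_id] = row.condition
        report["stages"]["filter_map_count"].update(
            {
                "n_samples": len(profiles),
                "library_totals": {p.sample_id: p.library_total for p in profiles},
            }
        )

    grouped = merge_profiles(profiles, group_map)

    # --- regions -----------------------------------------------------------
    with stage("regions"):
        matrices = {}
        for kind in ("tss", "genebody", "cpg_island"):
            matrix = aggregate_regions(grouped, site_index, catalog, kind)
            matrix.to_tsv(out / f"regions_{kind}.tsv")
            matrices[kind] = matrix

    # --- DMR calling -------------------------------------------------------
    dmr_config = config.dmr_config()
    with stage("dmr"):
        all_records = []
        for kind, matrix in matrices.items():
            records = dmr_mod.call_region_dmrs(matrix, config.group_pair, dmr_config)
            dmr_mod.annotate_overlaps(records, catalog)
            frame = dmr_mod.dmrs_to_dataframe(records)
            frame.to_csv(out / f"dmr_{kind}.tsv", sep="\t", index=False)
            all_records.extend(r for r in records if r.significant)
        window_records = dmr_mod.sliding_window_dmrs(
            grouped, site_index, config.group_pair, dmr_config, catalog
        )
        dmr_mod.dmrs_to_dataframe(window_records).to_csv(
            out / "dmr_windows.tsv", sep="\t", index=False
        )
        dmr_mod.write_dmr_bed(window_records, out / "dmr_windows.bed")
        report["stages"]["dmr"] = {
            "significant_region_dmrs": len(all_records),
            "window_dmrs": len(window_records),
        }

    # --- clustering --------------------------------------------------------
    with stage("cluster"):
        significant_ids = [r.region_id for r in all_records]
        n_clustered = 0
        if significant_ids and len(profiles) >= 2:
            per_sample_tss = aggregate_regions(profiles, site_index, catalog, "tss")
            rows = [r for r in significant_ids if r in per_sample_tss.data.index]
            if rows:
                sub = per_sample_tss.data.loc[rows]
                z = cluster_mod.zscore_rows(sub)
                col_order = cluster_mod.hierarchical_cluster(z, axis="columns")
                cluster_mod.export_heatmap(z, out / "dmr_heatmap.png", col_order=col_order)
                n_clustered = len(rows)
        report["stages"]["cluster"] = {"n_dmrs_clustered": n_clustered}

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "run_report.json":
            report["outputs"][str(path.relative_to(out))] = _checksum(path)
    (out / "run_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
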