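"""Synthetic MeD-seq data with planted methylation differences.

The generator emulates the physical process the analysis assumes: a genome
carrying recognition-motif sites, per-site per-condition methylation
probabilities, and reads emitted only from methylated sites as short
fragments placed so the motif anchor sits 13-17 bp from one read end,
plus a configurable fraction of unanchored noise reads and per-base
substitution errors.

Planted differentially methylated regions (DMRs) give ground truth for
recovery tests.  The exhaustion-style demo plants a "Tcf7-like" promoter
that gains methylation (lowly methylated at baseline, as promoters of
expressed genes are) and a "Pdcd1-like" regulatory region that loses
methylation from a heavily methylated baseline — the directions reported
for repeat-stimulated cytotoxic T cells.

Two sampling routes share one statistical model: `simulate_reads` writes
FASTQ for end-to-end pipeline runs, while `simulate_site_counts` draws the
same multinomial site counts directly, for statistical experiments where
read-level fidelity (established separately) is not under test.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .reference import (
    GeneModel,
    MotifSpec,
    ReferenceGenome,
    Region,
    RegionCatalog,
    SiteIndex,
    build_region_catalog,
    build_site_index,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic MeD-seq experiment.

    ``site_density`` is approximate sites per kb; ``reads_per_site`` sets
    the expected number of site-derived reads per sample as
    ``reads_per_site * n_sites`` (``depth``, if given, overrides the total
    directly).  ``offset_weights`` is the distribution of the anchor
    distance over 13..17; ``noise_fraction`` is the proportion of reads
    drawn uniformly from the genome with no motif anchoring.
    """

    n_chroms: int = 2
    chrom_length: int = 100_000
    motif: MotifSpec = field(default_factory=lambda: MotifSpec("CCGG", 1, True))
    site_density: float = 8.0
    n_genes: int = 12
    n_islands: int = 6
    gene_length_range: tuple[int, int] = (2_000, 6_000)
    island_length: int = 4_000
    read_length: int = 50
    min_site_gap: int = 30  # > read_length - 2*min_offset + 1, so one read = one site
    min_offset: int = 13
    max_offset: int = 17
    offset_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    reads_per_site: float = 30.0
    depth: int | None = None
    noise_fraction: float = 0.05
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("n_chroms and chrom_length must be positive")
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must be in [0, 1)")
        if len(self.offset_weights) != self.max_offset - self.min_offset + 1:
            raise ValueError("offset_weights must cover [min_offset, max_offset]")
        if self.site_density <= 0 or self.reads_per_site <= 0:
            raise ValueError("site_density and reads_per_site must be positive")

    def total_depth(self, n_sites: int) -> int:
        if self.depth is not None:
            return int(self.depth)
        return int(round(self.reads_per_site * n_sites))


@dataclass(frozen=True)
class PlantedDMR:
    """A region whose methylation differs between two conditions.

    ``region`` is (kind, region_id) into the catalog, or
    ("interval", chrom, start, end) for an explicit interval.  ``fold`` is
    the target probability ratio in ``target_condition`` relative to the
    other conditions; ``direction`` "up" multiplies, "down" divides.
    ``baseline`` overrides the region's reference-condition probability
    (e.g. a heavily methylated regulatory region that will lose
    methylation).
    """

    region: tuple
    target_condition: str
    direction: str  # "up" | "down"
    fold: float
    baseline: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")


@dataclass
class SimulationTruth:
    """Per-site per-condition methylation probabilities plus planted DMRs."""

    conditions: list[str]
    methylation: dict[str, np.ndarray]  # condition -> probability per site
    planted: list[dict]  # resolved: label, chrom, start, end, direction, fold, n_sites

    def to_json(self, path: str | Path) -> None:
        payload = {
            "conditions": self.conditions,
            "planted": self.planted,
            "methylation": {c: np.asarray(p).tolist() for c, p in self.methylation.items()},
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# Genome generation


def _random_sequence(length: int, rng: np.random.Generator) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


def _patterns(motif: MotifSpec) -> list[re.Pattern]:
    pats = [motif.forward_pattern()]
    if motif.search_both_strands:
        rc = motif.reverse_pattern()
        if rc.pattern != pats[0].pattern:
            pats.append(rc)
    return pats


def _erase_motif(seq: bytearray, motif: MotifSpec, rng: np.random.Generator) -> None:
    """Mutate bases until the sequence contains no motif occurrence."""
    patterns = _patterns(motif)
    for _ in range(12):
        dirty = False
        text = seq.decode()
        for pattern in patterns:
            for match in pattern.finditer(text):
                dirty = True
                pos = match.start() + rng.integers(0, len(motif))
                current = chr(seq[pos])
                choices = [b for b in "ACGT" if b != current]
                seq[pos] = ord(choices[rng.integers(0, 3)])
        if not dirty:
            return
    raise RuntimeError("failed to erase motif occurrences from background sequence")


def _plant_sites(
    seq: bytearray,
    motif: MotifSpec,
    density_per_kb: float,
    rng: np.random.Generator,
    min_gap: int = 30,
) -> list[int]:
    """Write concrete motif instances at roughly regular, jittered spacing.

    ``density_per_kb`` counts indexed anchor sites; a palindromic motif
    scanned on both strands anchors two sites per instance, so the number
    of planted instances is scaled accordingly.  Instances are kept at
    least ``min_gap`` bp apart so that any one enzyme-cut fragment covers
    a single site (sites closer than read_length - 2*min_offset + 1 can
    legitimately qualify from both read ends; the scorer then splits the
    weight, which is correct but makes per-site truth non-unique).
    """
    length = len(seq)
    concrete = _concrete_motif(motif, rng)
    anchors_per_instance = max(len(motif.anchor_positions(concrete)), 1)
    n_target = int(round(density_per_kb * length / 1000.0 / anchors_per_instance))
    if n_target < 1:
        raise ValueError("site density unachievable at this chromosome length")
    spacing = length / n_target
    if spacing < max(len(motif) + 4, min_gap):
        raise ValueError("site density too high for motif length / minimum gap")
    margin = 60  # keep sites clear of chromosome ends so reads always fit
    positions: list[int] = []
    prev = -(10**9)
    for i in range(n_target):
        lo = max(int(i * spacing), margin, prev + min_gap)
        hi = min(int((i + 1) * spacing) - len(motif), length - margin - len(motif))
        if lo >= hi:
            continue
        start = int(rng.integers(lo, hi))
        seq[start : start + len(motif)] = concrete.encode()
        positions.append(start + motif.anchor_offset)
        prev = start
    return positions


def _concrete_motif(motif: MotifSpec, rng: np.random.Generator) -> str:
    from Bio.Data.IUPACData import ambiguous_dna_values

    out = []
    for base in motif.motif:
        expansion = ambiguous_dna_values[base]
        out.append(expansion[rng.integers(0, len(expansion))])
    return "".join(out)


def generate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceGenome, SiteIndex, RegionCatalog]:
    """Random genome with motif sites at the target density, plus annotation.

    Background sequence is scrubbed of accidental motif occurrences before
    concrete sites are planted, so the realised density tracks the target.
    Genes and CpG islands are placed non-overlappingly on a regular grid.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    for c in range(config.n_chroms):
        seq = _random_sequence(config.chrom_length, rng)
        _erase_motif(seq, config.motif, rng)
        planted = _plant_sites(
            seq, config.motif, config.site_density, rng, config.min_site_gap
        )
        if not planted:
            raise ValueError("no sites could be planted; increase chrom_length")
        sequences[f"chr{c + 1}"] = seq.decode()
    genome = ReferenceGenome(sequences)
    site_index = build_site_index(genome, config.motif)

    target = config.site_density * config.n_chroms * config.chrom_length / 1000.0
    if not 0.5 * target <= site_index.n_sites <= 1.5 * target:
        raise RuntimeError(
            f"realised site count {site_index.n_sites} far from target {target:.0f}"
        )

    genes, islands = _place_annotation(genome, config, rng)
    catalog = build_region_catalog(genes, islands, genome.lengths, flank=1000)
    return genome, site_index, catalog


def _place_annotation(
    genome: ReferenceGenome, config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[GeneModel], list[tuple[str, str, int, int]]]:
    chroms = genome.chroms
    n_slots = config.n_genes + config.n_islands
    genes: list[GeneModel] = []
    islands: list[tuple[str, str, int, int]] = []
    if n_slots == 0:
        return genes, islands
    # lay features out on a per-chromosome grid so nothing overlaps
    per_chrom = int(np.ceil(n_slots / len(chroms)))
    slot_len = config.chrom_length // max(per_chrom, 1)
    min_needed = max(config.gene_length_range[1] + 2000, config.island_length) + 200
    if slot_len < min_needed:
        raise ValueError(
            "chromosomes too short for the requested number of genes/islands"
        )
    slots = [
        (chrom, s * slot_len)
        for chrom in chroms
        for s in range(per_chrom)
    ][:n_slots]
    gene_slots = slots[: config.n_genes]
    island_slots = slots[config.n_genes :]
    for i, (chrom, base) in enumerate(gene_slots):
        length = int(rng.integers(*config.gene_length_range))
        start = base + 1100 + int(rng.integers(0, max(slot_len - length - 2400, 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss, tes = start, start + length
        else:
            tss, tes = start + length, start
        genes.append(GeneModel(f"g{i + 1:04d}", chrom, strand, tss, tes))
    for j, (chrom, base) in enumerate(island_slots):
        start = base + 200
        islands.append((f"cgi{j + 1:04d}", chrom, start, start + config.island_length))
    return genes, islands


# ---------------------------------------------------------------------------
# Methylation truth


def _resolve_region(region: tuple, catalog: RegionCatalog) -> Region:
    if region[0] == "interval":
        _, chrom, start, end = region
        return Region("interval", "interval", chrom, int(start), int(end))
    kind, region_id = region
    return catalog.lookup(kind, region_id)


def assign_methylation(
    site_index: SiteIndex,
    catalog: RegionCatalog,
    baseline_p: float = 0.2,
    planted: Sequence[PlantedDMR] = (),
    conditions: Sequence[str] = ("A", "B"),
    min_sites: int = 10,
    allow_subthreshold: bool = False,
) -> SimulationTruth:
    """Build per-site methylation probabilities for every condition.

    Background sites carry ``baseline_p`` in every condition.  Sites inside
    a planted region first take the planted baseline (if any) in all
    conditions, then the target condition's probability is multiplied
    (up) or divided (down) by ``fold``, clipped to [0, 1] with a warning.
    """
    if not 0 < baseline_p <= 1:
        raise ValueError("baseline_p must be in (0, 1]")
    probs = {c: np.full(site_index.n_sites, baseline_p, dtype=float) for c in conditions}
    resolved: list[dict] = []
    for spec in planted:
        region = _resolve_region(spec.region, catalog)
        lo, hi = site_index.interval_slice(region.chrom, region.start, region.end)
        n_sites = hi - lo
        if n_sites < min_sites and not allow_subthreshold:
            raise ValueError(
                f"planted DMR {spec.label or region.region_id} covers only "
                f"{n_sites} sites (< {min_sites}); increase site density or region size"
            )
        if spec.target_condition not in probs:
            raise ValueError(f"unknown condition {spec.target_condition!r}")
        ref_p = spec.baseline if spec.baseline is not None else baseline_p
        for cond in conditions:
            probs[cond][lo:hi] = ref_p
        if spec.direction == "up":
            new_p = ref_p * spec.fold
        else:
            new_p = ref_p / spec.fold
        if new_p > 1.0:
            logger.warning(
                "planted DMR %s: probability %.3f clipped to 1.0",
                spec.label or region.region_id,
                new_p,
            )
            new_p = 1.0
        probs[spec.target_condition][lo:hi] = new_p
        resolved.append(
            {
                "label": spec.label or region.region_id,
                "region_id": region.region_id,
                "kind": region.kind,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "target_condition": spec.target_condition,
                "direction": spec.direction,
                "fold": spec.fold,
                "n_sites": int(n_sites),
                "site_lo": int(lo),
                "site_hi": int(hi),
            }
        )
    return SimulationTruth(list(conditions), probs, resolved)


def exhaustion_demo_dmrs(
    catalog: RegionCatalog,
    hyper_condition: str = "repeat",
) -> list[PlantedDMR]:
    """The demo's planted truth: a promoter gaining and a regulatory region
    losing methylation in the chronically stimulated condition."""
    tcf7_like = catalog.tss_windows[0].region_id
    pdcd1_like = catalog.cpg_islands[0].region_id
    return [
        PlantedDMR(("tss", tcf7_like), hyper_condition, "up", 5.0, label="Tcf7_like_promoter"),
        PlantedDMR(
            ("cpg_island", pdcd1_like),
            hyper_condition,
            "down",
            3.0,
            baseline=0.9,
            label="Pdcd1_like_region",
        ),
    ]


# ---------------------------------------------------------------------------
# Read emission


@dataclass
class EmissionLog:
    """Per-read provenance: which site (or noise) each FASTQ record came from."""

    entries: list[tuple[str, str, int, str]] = field(default_factory=list)
    site_counts: np.ndarray | None = None
    n_site_reads: int = 0
    n_noise_reads: int = 0
    n_resampled: int = 0

    @property
    def n_records(self) -> int:
        return self.n_site_reads + self.n_noise_reads

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as handle:
            handle.write("read_id\tchrom\tpos\tsource\n")
            for read_id, chrom, pos, source in self.entries:
                handle.write(f"{read_id}\t{chrom}\t{pos}\t{source}\n")


def simulate_site_counts(
    truth: SimulationTruth,
    condition: str,
    n_reads: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial site-derived read counts: site choice ∝ methylation.

    This is the count-level marginal of `simulate_reads` with zero noise and
    error — the library is a fixed-size multinomial sample over sites with
    probabilities proportional to per-site methylation.
    """
    p = np.asarray(truth.methylation[condition], dtype=float)
    total = p.sum()
    if total <= 0:
        return np.zeros_like(p)
    return rng.multinomial(n_reads, p / total).astype(float)


def simulate_reads(
    genome: ReferenceGenome,
    site_index: SiteIndex,
    truth: SimulationTruth,
    condition: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    read_prefix: str = "r",
) -> tuple[list, EmissionLog]:
    """Emit one sample's reads for ``condition``.

    Site reads: a site is chosen proportionally to its methylation
    probability, an offset is drawn from the 13-17 distribution and a read
    end (5'/3') at random, and the read is the forward-strand genomic
    window of ``read_length`` placed so the motif anchor lies exactly that
    many bases from the chosen end.  ``noise_fraction`` of reads are
    uniform genomic windows.  Substitution errors are applied per base.
    Sites too close to a chromosome edge are resampled and counted.
    """
    from .reads import ReadRecord  # local import to avoid cycle

    if condition not in truth.methylation:
        raise ValueError(f"condition {condition!r} absent from truth")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_sites = site_index.n_sites
    total = config.total_depth(n_sites)
    n_noise = int(rng.binomial(total, config.noise_fraction)) if config.noise_fraction else 0
    n_site = total - n_noise

    p = np.asarray(truth.methylation[condition], dtype=float)
    log = EmissionLog(site_counts=np.zeros(n_sites))
    reads: list = []
    length = config.read_length
    offsets = np.arange(config.min_offset, config.max_offset + 1)
    offset_p = np.asarray(config.offset_weights, dtype=float)
    offset_p = offset_p / offset_p.sum()

    global_pos = np.concatenate(
        [site_index.positions[c] for c in site_index.chroms]
    ) if n_sites else np.empty(0, dtype=np.int64)
    chrom_idx = np.concatenate(
        [np.full(len(site_index.positions[c]), i) for i, c in enumerate(site_index.chroms)]
    ) if n_sites else np.empty(0, dtype=int)
    chrom_list = site_index.chroms

    if n_site > 0 and p.sum() > 0:
        site_draws = rng.choice(n_sites, size=n_site, p=p / p.sum())
        off_draws = rng.choice(offsets, size=n_site, p=offset_p)
        side_draws = rng.random(n_site) < 0.5
    else:
        site_draws = np.empty(0, dtype=int)
        off_draws = side_draws = np.empty(0, dtype=int)
        n_site = 0

    read_no = 0
    for global_idx, off, from_five in zip(site_draws, off_draws, side_draws):
        chrom = chrom_list[chrom_idx[global_idx]]
        anchor = int(global_pos[global_idx])
        chrom_seq = genome.sequences[chrom]
        off = int(off)
        placed = False
        for _attempt in range(10):
            if from_five:  # anchor measured from the 5' end
                start = anchor - (off - 1)
            else:  # from the 3' end
                start = anchor - length + off
            if 0 <= start and start + length <= len(chrom_seq):
                placed = True
                break
            log.n_resampled += 1
            off = int(rng.choice(offsets, p=offset_p))
            from_five = rng.random() < 0.5
        if not placed:
            continue
        seq = chrom_seq[start : start + length]
        seq = _apply_errors(seq, config.error_rate, rng)
        read_id = f"{read_prefix}{read_no:07d}"
        read_no += 1
        reads.append(ReadRecord(read_id, seq))
        log.entries.append((read_id, chrom, start, f"site:{int(global_idx)}"))
        log.site_counts[global_idx] += 1
        log.n_site_reads += 1

    chrom_names = genome.chroms
    lengths = np.array([len(genome.sequences[c]) for c in chrom_names], dtype=float)
    chrom_probs = lengths / lengths.sum()
    for _ in range(n_noise):
        ci = int(rng.choice(len(chrom_names), p=chrom_probs))
        chrom = chrom_names[ci]
        start = int(rng.integers(0, len(genome.sequences[chrom]) - length + 1))
        seq = _apply_errors(genome.sequences[chrom][start : start + length], config.error_rate, rng)
        read_id = f"{read_prefix}{read_no:07d}"
        read_no += 1
        reads.append(ReadRecord(read_id, seq))
        log.entries.append((read_id, chrom, start, "noise"))
        log.n_noise_reads += 1

    return reads, log


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = bytearray(seq.encode())
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        current = chr(arr[pos])
        choices = [b for b in "ACGT" if b != current]
        arr[pos] = ord(choices[rng.integers(0, len(choices))])
    return arr.decode()


# ---------------------------------------------------------------------------
# Sample sets


def simulate_sample_set(
    genome: ReferenceGenome,
    site_index: SiteIndex,
    truth: SimulationTruth,
    config: SimulationConfig,
    replicates: dict[str, int],
    out_dir: str | Path,
) -> "pd.DataFrame":
    """Write one FASTQ + emission log per sample and a manifest TSV.

    ``replicates`` maps condition -> number of samples.  Per-sample seeds
    are drawn from one generator seeded by ``config.seed`` so the whole set
    is reproducible.
    """
    import pandas as pd

    from .reads import write_fastq

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    rows = []
    for condition, n_reps in replicates.items():
        for rep in range(1, n_reps + 1):
            sample_id = f"{condition}_{rep}"
            sample_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sample_seed)
            reads, log = simulate_reads(
                genome, site_index, truth, condition, config, rng, read_prefix=f"{sample_id}:"
            )
            fastq = out_dir / f"{sample_id}.fastq"
            write_fastq(reads, fastq)
            log.write_tsv(out_dir / f"{sample_id}.emission.tsv")
            rows.append(
                {
                    "sample_id": sample_id,
                    "condition": condition,
                    "fastq": str(fastq),
                    "seed": sample_seed,
                    "n_reads": log.n_records,
                }
            )
            logger.info("sample %s: %d reads (seed %d)", sample_id, log.n_records, sample_seed)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
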