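"""Read filtering by recognition-site offset and genomic placement.

MeD-seq libraries are built from ~32 bp fragments cut around methylated
recognition sites, sequenced as 50 bp single-end reads.  A genuine
site-derived read therefore carries the recognition motif with its anchor
base a characteristic 13-17 bp from one read end; reads failing that rule
are discarded before mapping.

Placements come either from a SAM/BAM produced by a real aligner or from a
built-in exact matcher sufficient for synthetic genomes.  Multimapped reads
are kept: under the default "fractional" policy each of a read's k hit
locations carries weight 1/k so one read contributes one count in total.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
from Bio.Seq import reverse_complement

from .reference import MotifSpec, ReferenceGenome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    quality: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Placement:
    """One genomic location of a read, with its multimapping weight."""

    read_id: str
    chrom: str
    start: int  # 0-based leftmost
    length: int  # span on the reference
    n_hits: int = 1
    weight: float = 1.0
    strand: str = "+"


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    n_discarded: int = 0
    n_too_short: int = 0
    offset_histogram: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_discarded": self.n_discarded,
            "n_too_short": self.n_too_short,
            "retention": self.n_kept / self.n_input if self.n_input else 0.0,
            "offset_histogram": {str(k): v for k, v in sorted(self.offset_histogram.items())},
        }


def read_end_offsets(
    sequence: str, motif: MotifSpec, min_off: int = 13, max_off: int = 17
) -> list[int]:
    """1-based distances of in-range motif anchors from the nearer read end.

    The motif is searched on both orientations of the read when it is
    configured to scan both strands.  An anchor at 0-based read index i lies at distance
    i + 1 from the 5' end and L - i from the 3' end (the terminal base
    counts as 1); every distance falling in [min_off, max_off] is returned.
    """
    length = len(sequence)
    offsets = []
    for index, _strand in motif.anchor_positions(sequence):
        d5 = index + 1
        d3 = length - index
        if min_off <= d5 <= max_off:
            offsets.append(d5)
        if min_off <= d3 <= max_off:
            offsets.append(d3)
    return offsets


def filter_reads(
    reads: Iterable[ReadRecord],
    motif: MotifSpec,
    min_off: int = 13,
    max_off: int = 17,
) -> tuple[list[ReadRecord], FilterReport]:
    """Keep reads whose motif anchor lies 13-17 bp from either read end.

    Reads shorter than ``max_off + len(motif)`` cannot be judged reliably
    and are discarded, counted separately in the report.  The report's
    offset histogram records the smallest qualifying offset per kept read.
    """
    if min_off > max_off:
        raise ValueError("min_off must be <= max_off")
    kept: list[ReadRecord] = []
    report = FilterReport()
    min_len = max_off + len(motif)
    for read in reads:
        report.n_input += 1
        if len(read) < min_len:
            report.n_too_short += 1
            report.n_discarded += 1
            continue
        offsets = read_end_offsets(read.sequence, motif, min_off, max_off)
        if offsets:
            kept.append(read)
            report.n_kept += 1
            report.offset_histogram[min(offsets)] += 1
        else:
            report.n_discarded += 1
    return kept, report


# ---------------------------------------------------------------------------
# FASTQ I/O


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    with pysam.FastxFile(str(path)) as handle:
        for entry in handle:
            yield ReadRecord(entry.name, entry.sequence.upper(), entry.quality)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt") as handle:
        for read in reads:
            qual = read.quality or "I" * len(read)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Exact mapper


@dataclass
class MappingReport:
    n_reads: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_multimapped: int = 0


def _scan_chromosome(
    seq: str, prefix_map: dict[str, list[tuple[str, bool]]], k: int
) -> Iterator[tuple[int, str, bool]]:
    """Yield (position, read_seq, is_rc) for every exact full-length match."""
    n = len(seq)
    for i in range(n - k + 1):
        candidates = prefix_map.get(seq[i : i + k])
        if not candidates:
            continue
        for read_seq, is_rc in candidates:
            if seq.startswith(read_seq, i) and i + len(read_seq) <= n:
                yield i, read_seq, is_rc


def map_reads_exact(
    reads: Sequence[ReadRecord],
    genome: ReferenceGenome,
    multimap_policy: str = "fractional",
) -> tuple[list[Placement], MappingReport]:
    """Exact full-length placement of reads on both genome strands.

    Every exact occurrence of the read (or its reverse complement) on the
    forward genome sequence is reported; reads with zero hits are dropped
    and counted.  Under the "fractional" policy each of k hits carries
    weight 1/k; under "count-all" each carries weight 1.
    """
    if multimap_policy not in ("fractional", "count-all"):
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    report = MappingReport(n_reads=len(reads))
    if not reads:
        return [], report

    k = min(20, min(len(r) for r in reads))
    prefix_map: dict[str, list[tuple[str, bool]]] = defaultdict(list)
    seq_to_reads: dict[str, list[str]] = defaultdict(list)
    for read in reads:
        seq_to_reads[read.sequence].append(read.read_id)
    for seq in seq_to_reads:
        prefix_map[seq[:k]].append((seq, False))
        rc = reverse_complement(seq)
        prefix_map[rc[:k]].append((rc, True))

    # keyed by (chrom, pos) so a palindromic read is not double-counted
    hits: dict[str, dict[tuple[str, int], str]] = defaultdict(dict)
    for chrom, chrom_seq in genome.sequences.items():
        for pos, matched, is_rc in _scan_chromosome(chrom_seq, dict(prefix_map), k):
            original = reverse_complement(matched) if is_rc else matched
            hits[original].setdefault((chrom, pos), "-" if is_rc else "+")

    placements: list[Placement] = []
    for seq, read_ids in seq_to_reads.items():
        loc_map = hits.get(seq)
        if not loc_map:
            report.n_unmapped += len(read_ids)
            continue
        locs = sorted((chrom, pos, strand) for (chrom, pos), strand in loc_map.items())
        n_hits = len(locs)
        weight = 1.0 / n_hits if multimap_policy == "fractional" else 1.0
        report.n_mapped += len(read_ids)
        if n_hits > 1:
            report.n_multimapped += len(read_ids)
        for read_id in read_ids:
            for chrom, pos, strand in locs:
                placements.append(
                    Placement(read_id, chrom, pos, len(seq), n_hits, weight, strand)
                )
    return placements, report


# ---------------------------------------------------------------------------
# SAM ingestion


def ingest_sam(
    sam_path: str | Path, multimap_policy: str = "fractional"
) -> tuple[list[Placement], MappingReport]:
    """Convert SAM/BAM alignment records into placements.

    Unmapped and supplementary records are skipped; the number of hits per
    read is the number of (primary + secondary) alignment records sharing
    its name, and coordinates are pysam's 0-based.
    """
    if multimap_policy not in ("fractional", "count-all"):
        raise ValueError(f"unknown multimap policy {multimap_policy!r}")
    raw: list[tuple[str, str, int, int, str]] = []
    unmapped = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as handle:
        for record in handle:
            if record.is_unmapped:
                unmapped += 1
                continue
            if record.is_supplementary:
                continue
            length = record.reference_length or record.query_length or 0
            raw.append(
                (
                    record.query_name,
                    record.reference_name,
                    record.reference_start,
                    length,
                    "-" if record.is_reverse else "+",
                )
            )
    per_read = Counter(name for name, *_ in raw)
    report = MappingReport(
        n_reads=len(per_read) + unmapped,
        n_mapped=len(per_read),
        n_unmapped=unmapped,
        n_multimapped=sum(1 for v in per_read.values() if v > 1),
    )
    if not raw and unmapped:
        logger.warning("all %d records in %s unmapped", unmapped, sam_path)
    placements = []
    for name, chrom, start, length, strand in raw:
        n_hits = per_read[name]
        weight = 1.0 / n_hits if multimap_policy == "fractional" else 1.0
        placements.append(Placement(name, chrom, start, length, n_hits, weight, strand))
    return placements, report
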