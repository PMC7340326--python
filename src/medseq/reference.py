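"""Reference ingestion and recognition-site indexing.

Methylation-dependent restriction-enzyme sequencing (MeD-seq) assigns read
counts to individual genomic occurrences of the enzyme's recognition motif
(for LpnPI, CCDG with the methylated cytosine at the second position).  This
module loads reference sequences, gene models and CpG-island intervals and
builds the genome-wide site index that every downstream stage shares.

All coordinates are 0-based, half-open.  BED input is taken as-is; GTF input
(1-based, closed) is converted on ingest.
"""

from __future__ import annotations

import difflib
import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Genome


@dataclass
class ReferenceGenome:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def load_genome(fasta_path: str | Path) -> ReferenceGenome:
    """Load a (possibly gzipped, multi-record) FASTA into memory.

    Sequences are uppercased; the alphabet is restricted to A, C, G, T, N.
    Raises ``ValueError`` naming the offending record on empty input,
    duplicate record names, or non-nucleotide characters.
    """
    sequences: dict[str, str] = {}
    with _open_text(fasta_path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate FASTA record name: {record.id!r}")
            seq = str(record.seq).upper()
            bad = re.search(r"[^ACGTN]", seq)
            if bad:
                raise ValueError(
                    f"non-nucleotide character {bad.group()!r} in record "
                    f"{record.id!r} at position {bad.start() + 1}"
                )
            sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return ReferenceGenome(sequences)


# ---------------------------------------------------------------------------
# Motif


def _iupac_regex(motif: str) -> re.Pattern:
    parts = []
    for base in motif:
        expansion = ambiguous_dna_values[base]
        parts.append(base if len(expansion) == 1 else f"[{expansion}]")
    # lookahead so overlapping occurrences are all found
    return re.compile("(?=" + "".join(parts) + ")")


@dataclass(frozen=True)
class MotifSpec:
    """Recognition motif of a methylation-dependent restriction enzyme.

    ``anchor_offset`` is the 0-based index, within the motif, of the base
    whose genomic coordinate identifies the site (for LpnPI the methylated
    cytosine of the CpG).  Read-end distances are measured to this base.
    """

    motif: str
    anchor_offset: int = 1
    search_both_strands: bool = True
    validate_cpg: bool = False

    def __post_init__(self) -> None:
        motif = self.motif.upper()
        object.__setattr__(self, "motif", motif)
        if len(motif) < 2:
            raise ValueError("motif length must be >= 2")
        if not (0 <= self.anchor_offset < len(motif)):
            raise ValueError("anchor_offset must fall inside the motif")
        for base in motif:
            if base not in ambiguous_dna_values:
                raise ValueError(f"invalid IUPAC base {base!r} in motif")
        if self.validate_cpg and not self._can_contain_cpg():
            raise ValueError(f"motif {motif!r} cannot contain a CpG dinucleotide")

    def _can_contain_cpg(self) -> bool:
        for i in range(len(self.motif) - 1):
            if "C" in ambiguous_dna_values[self.motif[i]] and "G" in ambiguous_dna_values[
                self.motif[i + 1]
            ]:
                return True
        return False

    def __len__(self) -> int:
        return len(self.motif)

    def forward_pattern(self) -> re.Pattern:
        return _iupac_regex(self.motif)

    def reverse_pattern(self) -> re.Pattern:
        return _iupac_regex(reverse_complement(self.motif))

    def anchor_positions(self, sequence: str) -> list[tuple[int, str]]:
        """All (anchor position, strand) occurrences of the motif in ``sequence``.

        Minus-strand occurrences are occurrences of the reverse complement on
        the given (forward) sequence; their anchor is the forward-strand
        coordinate of the anchored base.  A window matching on both strands
        (a palindromic occurrence) is one physical double-stranded
        recognition site and is reported once, strand '.', at the
        forward-strand anchor.
        """
        m = len(self.motif)
        fwd_starts = {match.start() for match in self.forward_pattern().finditer(sequence)}
        if not self.search_both_strands:
            return [(start + self.anchor_offset, "+") for start in sorted(fwd_starts)]
        rc_starts = {match.start() for match in self.reverse_pattern().finditer(sequence)}
        rc_anchor = m - 1 - self.anchor_offset
        hits = []
        for start in sorted(fwd_starts | rc_starts):
            if start in fwd_starts and start in rc_starts:
                hits.append((start + self.anchor_offset, "."))
            elif start in fwd_starts:
                hits.append((start + self.anchor_offset, "+"))
            else:
                hits.append((start + rc_anchor, "-"))
        return hits


#: LpnPI recognition site (vendor documentation); methylated C at offset 1.
DEFAULT_MOTIF = MotifSpec("CCDG", anchor_offset=1, search_both_strands=True)


# ---------------------------------------------------------------------------
# Site index


@dataclass
class SiteIndex:
    """Ordered genome-wide catalog of recognition-site anchor positions.

    Per-chromosome position arrays are strictly ascending; a position hit on
    both strands is stored once with strand '.'.  Global site order is
    chromosome order then position, so a single flat counts array can be
    aligned to the index.
    """

    chroms: list[str]
    positions: dict[str, np.ndarray]
    strands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        offset = 0
        self._offsets: dict[str, int] = {}
        for chrom in self.chroms:
            self._offsets[chrom] = offset
            offset += len(self.positions[chrom])
        self._n_sites = offset

    @property
    def n_sites(self) -> int:
        return self._n_sites

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Global [start, end) index range of a chromosome's sites."""
        start = self._offsets[chrom]
        return start, start + len(self.positions[chrom])

    def sites(self) -> Iterator[tuple[str, int, str]]:
        for chrom in self.chroms:
            for pos, strand in zip(self.positions[chrom], self.strands[chrom]):
                yield chrom, int(pos), str(strand)

    def to_dataframe(self) -> pd.DataFrame:
        rows = list(self.sites())
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])

    def interval_slice(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global index range of sites with position in [start, end)."""
        base = self._offsets[chrom]
        pos = self.positions[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        return base + lo, base + hi


def build_site_index(genome: ReferenceGenome, motif: MotifSpec) -> SiteIndex:
    """Index every occurrence of the motif's anchor base in the genome.

    Overlapping occurrences are each recorded; scanning is deterministic, so
    the index is a pure function of (genome, motif).
    """
    positions: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for chrom, seq in genome.sequences.items():
        hits = motif.anchor_positions(seq)
        merged: dict[int, str] = {}
        for pos, strand in hits:
            prev = merged.get(pos)
            if prev is None:
                merged[pos] = strand
            elif prev != strand:
                merged[pos] = "."
        order = sorted(merged)
        positions[chrom] = np.asarray(order, dtype=np.int64)
        strands[chrom] = np.asarray([merged[p] for p in order], dtype="U1")
    return SiteIndex(genome.chroms, positions, strands)


# ---------------------------------------------------------------------------
# Gene models and regions


@dataclass(frozen=True)
class GeneModel:
    """One gene with strand-resolved transcription start/end coordinates.

    ``tss``/``tes`` are genomic (0-based) coordinates after strand
    resolution: for '+' genes tss <= tes, for '-' genes tes <= tss.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss <= tes")
        if self.strand == "-" and self.tes > self.tss:
            raise ValueError(f"gene {self.gene_id}: - strand requires tes <= tss")


@dataclass(frozen=True)
class Region:
    region_id: str
    kind: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.region_id}: empty interval")


REGION_KINDS = ("tss", "genebody", "cpg_island", "tss2kb")


@dataclass
class RegionCatalog:
    """TSS windows, gene bodies and CpG islands as half-open intervals.

    ``tss2kb`` is an alias kind for the TSS windows (the 2 kb window
    surrounding the TSS used for per-gene read-count summaries).
    """

    tss_windows: list[Region] = field(default_factory=list)
    gene_bodies: list[Region] = field(default_factory=list)
    cpg_islands: list[Region] = field(default_factory=list)

    def regions(self, kind: str) -> list[Region]:
        if kind in ("tss", "tss2kb"):
            return self.tss_windows
        if kind == "genebody":
            return self.gene_bodies
        if kind == "cpg_island":
            return self.cpg_islands
        raise ValueError(f"unknown region kind {kind!r}; expected one of {REGION_KINDS}")

    def lookup(self, kind: str, region_id: str) -> Region:
        for region in self.regions(kind):
            if region.region_id == region_id:
                return region
        near = difflib.get_close_matches(
            region_id, [r.region_id for r in self.regions(kind)], n=3
        )
        raise KeyError(f"no {kind} region {region_id!r}; close matches: {near}")


def build_region_catalog(
    genes: Iterable[GeneModel],
    islands: Iterable[tuple[str, str, int, int]],
    chrom_lengths: dict[str, int],
    flank: int = 1000,
) -> RegionCatalog:
    """Construct TSS windows, gene bodies and CpG-island regions.

    The TSS window is [tss - flank, tss + flank) in genomic coordinates
    regardless of strand (strand only determines which gene end is the TSS).
    The gene body runs from ``flank`` bp downstream of the TSS to the TES,
    strand-aware; genes shorter than ``flank`` yield no body and are logged.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    catalog = RegionCatalog()
    for gene in genes:
        if gene.chrom not in chrom_lengths:
            raise ValueError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom}")
        chrom_len = chrom_lengths[gene.chrom]
        if not (0 <= gene.tss < chrom_len):
            raise ValueError(
                f"gene {gene.gene_id}: TSS {gene.tss} outside chromosome "
                f"{gene.chrom} (length {chrom_len})"
            )
        win_start = max(0, gene.tss - flank)
        win_end = min(chrom_len, gene.tss + flank)
        catalog.tss_windows.append(
            Region(gene.gene_id, "tss", gene.chrom, win_start, win_end)
        )
        if gene.strand == "+":
            body_start, body_end = gene.tss + flank, gene.tes
        else:
            body_start, body_end = gene.tes, gene.tss - flank
        body_start = max(0, body_start)
        body_end = min(chrom_len, body_end)
        if body_start < body_end:
            catalog.gene_bodies.append(
                Region(gene.gene_id, "genebody", gene.chrom, body_start, body_end)
            )
        else:
            logger.warning(
                "gene %s shorter than %d bp downstream of TSS; no gene-body region",
                gene.gene_id,
                flank,
            )
    for island_id, chrom, start, end in islands:
        if chrom not in chrom_lengths:
            raise ValueError(f"island {island_id}: unknown chromosome {chrom}")
        start = max(0, int(start))
        end = min(chrom_lengths[chrom], int(end))
        if start < end:
            catalog.cpg_islands.append(Region(island_id, "cpg_island", chrom, start, end))
    return catalog


# ---------------------------------------------------------------------------
# Annotation readers


def _dedupe_gene_ids(genes: list[GeneModel]) -> list[GeneModel]:
    seen: dict[str, int] = {}
    out = []
    for gene in genes:
        if gene.gene_id in seen:
            seen[gene.gene_id] += 1
            new_id = f"{gene.gene_id}.{seen[gene.gene_id]}"
            logger.warning("duplicate gene id %s renamed to %s", gene.gene_id, new_id)
            gene = GeneModel(new_id, gene.chrom, gene.strand, gene.tss, gene.tes)
        else:
            seen[gene.gene_id] = 0
        out.append(gene)
    return out


def load_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a 5-column TSV gene table: gene_id, chrom, strand, tss, tes.

    Comment lines (#) are skipped; a header row naming the columns is
    accepted.  Coordinates are 0-based.
    """
    genes: list[GeneModel] = []
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":
                continue
            if len(fields) < 5:
                raise ValueError(f"{path}:{line_no}: expected 5 columns, got {len(fields)}")
            gene_id, chrom, strand, tss, tes = fields[:5]
            genes.append(GeneModel(gene_id, chrom, strand, int(tss), int(tes)))
    return _dedupe_gene_ids(genes)


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')


def load_gtf_genes(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Extract one GeneModel per ``feature`` row of a GTF file.

    GTF coordinates (1-based, closed) are converted to the internal 0-based
    convention; the strand-appropriate ends become TSS/TES.
    """
    genes: list[GeneModel] = []
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{line_no}: malformed GTF row")
            if fields[2] != feature:
                continue
            chrom, start, end, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            match = _GTF_GENE_ID.search(fields[8])
            if not match:
                raise ValueError(f"{path}:{line_no}: missing gene_id attribute")
            if strand == "+":
                tss, tes = start - 1, end
            else:
                tss, tes = end - 1, start - 1
            genes.append(GeneModel(match.group(1), chrom, strand, tss, tes))
    return _dedupe_gene_ids(genes)


def load_bed_intervals(path: str | Path, id_prefix: str = "cgi") -> list[tuple[str, str, int, int]]:
    """Read BED3+ intervals (0-based half-open) as (id, chrom, start, end)."""
    intervals: list[tuple[str, str, int, int]] = []
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{id_prefix}{line_no:05d}"
            intervals.append((name, chrom, start, end))
    return intervals
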