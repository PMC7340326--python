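import numpy as np
import pytest

from medseq.reference import MotifSpec, ReferenceGenome, build_site_index
from medseq.simulate import (
    SimulationConfig,
    assign_methylation,
    exhaustion_demo_dmrs,
    generate_reference,
)

CCGG = MotifSpec("CCGG", anchor_offset=1, search_both_strands=True)


@pytest.fixture
def ccgg() -> MotifSpec:
    return CCGG


@pytest.fixture(scope="session")
def small_reference():
    """2 x 100 kb synthetic reference shared by read-level tests."""
    config = SimulationConfig(
        n_chroms=2,
        chrom_length=100_000,
        reads_per_site=10,
        noise_fraction=0.0,
        error_rate=0.0,
        seed=7,
    )
    genome, site_index, catalog = generate_reference(config)
    return config, genome, site_index, catalog


@pytest.fixture(scope="session")
def demo_truth(small_reference):
    config, genome, site_index, catalog = small_reference
    truth = assign_methylation(
        site_index,
        catalog,
        planted=exhaustion_demo_dmrs(catalog, hyper_condition="repeat"),
        conditions=("single", "repeat"),
    )
    return truth


def random_genome(length: int, rng: np.random.Generator, chrom: str = "chr1") -> ReferenceGenome:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
    return ReferenceGenome({chrom: seq})


def naive_anchor_scan(sequence: str, motif: MotifSpec) -> list[tuple[int, str]]:
    """Independent brute-force motif scan: check every window position
    against the IUPAC expansion of the motif on each strand."""
    from Bio.Data.IUPACData import ambiguous_dna_values
    from Bio.Seq import reverse_complement

    def matches(window: str, pattern: str) -> bool:
        return len(window) == len(pattern) and all(
            base in ambiguous_dna_values[p] for base, p in zip(window, pattern)
        )

    m = len(motif.motif)
    rc = reverse_complement(motif.motif)
    hits = []
    for i in range(len(sequence) - m + 1):
        window = sequence[i : i + m]
        fwd = matches(window, motif.motif)
        rev = motif.search_both_strands and matches(window, rc)
        if fwd and rev:
            hits.append((i + motif.anchor_offset, "."))
        elif fwd:
            hits.append((i + motif.anchor_offset, "+"))
        elif rev:
            hits.append((i + m - 1 - motif.anchor_offset, "-"))
    return hits
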