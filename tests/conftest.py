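import numpy as np
import pytest

from haplokit import synthetic
from haplokit.io_core import GenomicSequence

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture
def random_sequence(rng):
    return GenomicSequence("rand", random_dna(rng, 10_000))


def scrub_site(s: str, site: str = "TCGA") -> str:
    """Remove every occurrence of a restriction site by point changes."""
    while site in s:
        s = s.replace(site, site[:-1] + ("G" if site[-1] != "G" else "C"))
    return s


def probe_ladder_contig(rng, sizes):
    """A contig whose digest yields one probe-positive fragment per size.

    Returns (contig, probe). Bodies are scrubbed of the TaqI site as whole
    strings so no site can span chunk junctions.
    """
    probe = scrub_site(random_dna(rng, 300))
    parts = []
    for size in sizes:
        body = scrub_site(
            random_dna(rng, 100) + probe + random_dna(rng, size - 300 - 100)
        )
        parts.append(body + "TCGA")
    contig = GenomicSequence(
        "c", "".join(parts) + scrub_site(random_dna(rng, 800))
    )
    return contig, probe


@pytest.fixture(scope="session")
def small_haplotype():
    """One 120 kb contig with genes, repeats and a 30 kb direct+inverted block."""
    cfg = synthetic.HaplotypeConfig(
        n_contigs=2,
        contig_length_bp=[120_000, 80_000],
        family_mix={"MHCY_classI": 8, "YLEC": 6},
        repeat_fraction=0.40,
        block_specs=[
            synthetic.BlockSpec(
                length_bp=30_000,
                n_copies=2,
                orientations=["direct", "inverted"],
                completeness=[1.0, 1.0],
            )
        ],
        divergence=0.0,
        seed=7,
    )
    return synthetic.generate_haplotype(cfg)
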