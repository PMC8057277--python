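import numpy as np
import pytest

from tsmpanel.metrics import default_catalog
from tsmpanel.reference import (
    MutationContext,
    SomaticSNV,
    TranscriptModel,
    map_to_cds,
    reverse_complement,
)

# Toy single-exon transcript: CDS ATG CCT TCA TGA at chr1:101-112, plus strand.
TOY_CDS = "ATGCCTTCATGA"
TOY_GENOME_LEN = 300


def _toy_genome() -> dict[str, str]:
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, 100))
    right = "".join(rng.choice(bases, TOY_GENOME_LEN - 100 - len(TOY_CDS)))
    return {"chr1": left + TOY_CDS + right}


@pytest.fixture(scope="session")
def toy_genome():
    return _toy_genome()


@pytest.fixture(scope="session")
def toy_transcript():
    return TranscriptModel("T1", "G1", "chr1", "+", ((101, 112),), TOY_CDS)


@pytest.fixture(scope="session")
def toy_minus_transcript(toy_genome):
    # CDS spelled on the minus strand over chr1:131-142.
    seq = reverse_complement(toy_genome["chr1"][130:142])
    return TranscriptModel("T2", "G2", "chr1", "-", ((131, 142),), seq)


def make_context(
    flank: str = "NNNCNNN",
    coding_ref: str = "C",
    coding_alt: str = "T",
    codon_position: int = 1,
    synonymous: bool = False,
    ref_codon: str = "CAA",
    alt_codon: str = "TAA",
    cds_position: int | None = None,
) -> MutationContext:
    """Hand-assembled context for metric-engine tests."""
    if cds_position is None:
        cds_position = codon_position
    snv = SomaticSNV("P1", "chr1", 100 + cds_position, coding_ref, coding_alt)
    return MutationContext(
        snv=snv,
        transcript_id="T1",
        coding_ref=coding_ref,
        coding_alt=coding_alt,
        cds_position=cds_position,
        codon_index=(cds_position - 1) // 3 + 1,
        codon_position=(cds_position - 1) % 3 + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        synonymous=synonymous,
        flank=flank,
    )


def contexts_from_cds(cds: str, mutations: list[tuple[int, str]]) -> list[MutationContext]:
    """Map (cds_position, alt) mutations through the real mapping code.

    Builds a plus-strand transcript holding ``cds`` at 101.. and routes each
    mutation through map_to_cds, so contexts carry genuine flanks/codons.
    """
    tx = TranscriptModel("TX", "GX", "chrX", "+", ((101, 100 + len(cds)),), cds)
    out = []
    for cds_pos, alt in mutations:
        ref = cds[cds_pos - 1]
        snv = SomaticSNV("P1", "chrX", 100 + cds_pos, ref, alt)
        ctx = map_to_cds(snv, [tx])
        assert ctx is not None
        out.append(ctx)
    return out


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()
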