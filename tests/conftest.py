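import logging

import pytest

from selectigene.cub_engine import CodonWeightTable
from selectigene.codons import AA_TO_CODONS, SENSE_CODONS
from selectigene.sequence_model import GeneRecord, HostGenome, Microbiome
from selectigene.synthetic_fixtures import FixtureSpec, make_goi, make_microbiome

logging.disable(logging.WARNING)


def uniform_weights(host_id: str = "h", scheme: str = "CAI") -> CodonWeightTable:
    return CodonWeightTable(scheme=scheme, host_id=host_id,
                            w={c: 1.0 for c in SENSE_CODONS})


def family_weight_table(host_id: str, fam_weights: dict[str, dict[str, float]],
                        default: float = 1.0) -> CodonWeightTable:
    """Weight table with explicit per-family weights, 1.0 elsewhere."""
    w = {c: default for c in SENSE_CODONS}
    for aa, table in fam_weights.items():
        for codon, val in table.items():
            assert codon in AA_TO_CODONS[aa]
            w[codon] = val
    return CodonWeightTable(scheme="CAI", host_id=host_id, w=w)


def bare_host(host_id: str, role: str, enzymes=()) -> HostGenome:
    return HostGenome(host_id=host_id, role=role, enzymes=list(enzymes))


@pytest.fixture(scope="session")
def small_microbiome() -> Microbiome:
    """2+2 hosts with strong, mirrored codon bias."""
    spec = FixtureSpec(seed=101, n_wanted=2, n_unwanted=2, genes_per_host=30,
                       gene_length_codons=120, bias_strength=0.9)
    return make_microbiome(spec)


@pytest.fixture(scope="session")
def small_goi() -> GeneRecord:
    return make_goi(80, seed=102)
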