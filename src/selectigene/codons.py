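"""Genetic-code tables and small sequence utilities shared across the package.

All coding-sequence logic uses the bacterial/archaeal genetic code
(NCBI translation table 11). Only the 61 sense codons carry codon-usage
weights; stop codons are never scored because they are not decoded by
elongating ribosomes.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

TABLE_ID = 11
_TABLE = CodonTable.unambiguous_dna_by_id[TABLE_ID]

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: codon -> one-letter amino acid
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: one-letter amino acid -> tuple of synonymous codons (lexicographic)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_c,)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# IUPAC ambiguity codes -> the set of concrete bases they admit
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def reverse_complement(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are mapped to their complements."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS (table 11) without the terminal stop symbol."""
    prot = str(Seq(cds).translate(table=TABLE_ID))
    return prot[:-1] if prot.endswith("*") else prot


def split_codons(cds: str, drop_stop: bool = True) -> list[str]:
    """Split an in-frame CDS into codons, optionally dropping a terminal stop."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    if drop_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def has_internal_stop(cds: str) -> bool:
    codons = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
    return any(c in STOP_CODONS for c in codons)


def iupac_matches(pattern: str, window: str) -> bool:
    """True if *window* (concrete A/C/G/T) matches the IUPAC *pattern*."""
    if len(pattern) != len(window):
        return False
    return all(w in IUPAC_SETS[p] for p, w in zip(pattern, window))


def is_iupac(site: str) -> bool:
    return len(site) > 0 and all(ch in IUPAC_SETS for ch in site)
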