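"""Standard genetic code helpers shared across the package.

Codon/amino-acid bookkeeping is derived once from Biopython's standard
(NCBI table 1) codon table, so every module agrees on the 61 sense codons,
the synonymous families and the stop set.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, DNA alphabet, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: stop codons (DNA alphabet)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> sorted tuple of synonymous codons
SYNONYMS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMS.setdefault(_aa, ())
SYNONYMS = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in sorted({*CODON_TO_AA.values()})
}

#: the 20 proteinogenic amino acids, one-letter, sorted
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(SYNONYMS))

#: amino acids with a single codon (excluded from CAI geometric means)
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, codons in SYNONYMS.items() if len(codons) == 1
)


def codons_of(seq: str) -> list[str]:
    """Split an in-frame nucleotide string into codons."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate(seq: str) -> str:
    """Translate an in-frame DNA string; stop codons become '*'."""
    return "".join(CODON_TO_AA.get(c, "*") for c in codons_of(seq))


def has_internal_stop(seq: str) -> bool:
    """True if any codon other than the final one is a stop codon."""
    cods = codons_of(seq)
    return any(c in STOP_CODONS for c in cods[:-1])
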