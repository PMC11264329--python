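"""Codon tables for mutagenesis library design.

Substitutions in cassette libraries use exactly one codon per amino acid so
that the pool contains no synonymous duplicates and no unintended stop
codons.  The default table ranks synonymous codons by *E. coli* K-12 usage;
`preferred` returns the top-ranked codon, and the ranked alternatives are
used when a codon must be rewritten synonymously (e.g. to destroy a Type IIS
recognition site that a mutation would otherwise create).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

STOP = "*"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = frozenset("ACGT")

# Synonymous codons ranked by E. coli K-12 usage frequency (most used first).
_ECOLI_RANKED: dict[str, tuple[str, ...]] = {
    "A": ("GCG", "GCC", "GCA", "GCT"),
    "C": ("TGC", "TGT"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGC", "GGT", "GGG", "GGA"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("CTG", "TTA", "TTG", "CTT", "CTC", "CTA"),
    "M": ("ATG",),
    "N": ("AAC", "AAT"),
    "P": ("CCG", "CCA", "CCT", "CCC"),
    "Q": ("CAG", "CAA"),
    "R": ("CGT", "CGC", "CGG", "CGA", "AGA", "AGG"),
    "S": ("AGC", "TCT", "TCC", "TCG", "AGT", "TCA"),
    "T": ("ACC", "ACG", "ACT", "ACA"),
    "V": ("GTG", "GTT", "GTC", "GTA"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
    STOP: ("TAA", "TGA", "TAG"),
}


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def validate_dna(seq: str, *, context: str = "sequence") -> str:
    """Reject anything outside strict uppercase ACGT (no ambiguity codes)."""
    if not seq or set(seq) <= DNA_ALPHABET:
        return seq
    bad = sorted(set(seq) - DNA_ALPHABET)
    raise ValueError(f"{context} contains non-ACGT characters: {bad}")


@dataclass(frozen=True)
class CodonTable:
    """Ranked synonymous codons per amino acid (plus stop).

    ``ranked[aa][0]`` is the preferred codon used for designed substitutions;
    the remainder are fall-backs for synonymous recoding, tried in order.
    """

    ranked: Mapping[str, tuple[str, ...]]
    _by_codon: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_codon: dict[str, str] = {}
        for aa, codons in self.ranked.items():
            if not codons:
                raise ValueError(f"amino acid {aa!r} has no codons")
            for codon in codons:
                if len(codon) != 3 or set(codon) - DNA_ALPHABET:
                    raise ValueError(f"invalid codon {codon!r} for {aa!r}")
                if codon in by_codon:
                    raise ValueError(f"codon {codon!r} assigned twice")
                by_codon[codon] = aa
        missing = set(AMINO_ACIDS + STOP) - set(self.ranked)
        if missing:
            raise ValueError(f"table lacks codons for {sorted(missing)}")
        object.__setattr__(self, "_by_codon", by_codon)

    def preferred(self, aa: str) -> str:
        try:
            return self.ranked[aa][0]
        except KeyError:
            raise KeyError(f"unknown amino acid {aa!r}") from None

    def synonyms(self, aa: str) -> tuple[str, ...]:
        return tuple(self.ranked[aa])

    def amino_acid(self, codon: str) -> str:
        """Translate one codon; raises for codons absent from the table."""
        try:
            return self._by_codon[codon]
        except KeyError:
            raise KeyError(f"unknown codon {codon!r}") from None

    def translate(self, dna: str) -> str:
        if len(dna) % 3:
            raise ValueError("length not divisible by 3")
        return "".join(self.amino_acid(dna[i : i + 3]) for i in range(0, len(dna), 3))


ECOLI_TABLE = CodonTable(_ECOLI_RANKED)
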