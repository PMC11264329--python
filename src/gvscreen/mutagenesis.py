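"""Parent coding sequences, mutation specs, and mutant library generators.

The two library chemistries implemented here mirror the rounds of a directed
evolution campaign on a gas-vesicle structural protein:

* *scanning site saturation* — every codon of the CDS is substituted with the
  19 non-parent amino acids plus a stop codon, one member per substitution,
  so a 70-codon gene yields exactly 1400 members and an 87-codon gene 1740;
* *paired recombination* — beneficial single mutations found in round 1 are
  combined two at a time, one member per unordered pair of mutations at
  distinct positions.

Members are concrete DNA sequences (one fixed codon per substitution, chosen
from a usage-ranked codon table) so the designed pools contain no synonymous
duplicates and no accidental premature stops.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .codons import AMINO_ACIDS, ECOLI_TABLE, STOP, CodonTable, validate_dna

_MUTATION_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


class MutationParseError(ValueError):
    """A mutation name could not be parsed."""


class MutationValidationError(ValueError):
    """A parsed mutation is inconsistent with the parent protein."""


@dataclass(frozen=True)
class ParentCDS:
    """A validated parent coding sequence (no terminal stop codon).

    Starts with ATG, length divisible by 3, no internal stop codon, strict
    uppercase ACGT alphabet.
    """

    id: str
    sequence: str
    _protein: str = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seq = self.sequence
        validate_dna(seq, context=f"CDS {self.id!r}")
        if len(seq) % 3:
            raise ValueError(f"CDS {self.id!r} length {len(seq)} not divisible by 3")
        if not seq.startswith("ATG"):
            raise ValueError(f"CDS {self.id!r} does not start with ATG")
        protein = ECOLI_TABLE.translate(seq)
        if STOP in protein:
            raise ValueError(f"CDS {self.id!r} contains an internal stop codon")
        object.__setattr__(self, "_protein", protein)

    @property
    def protein(self) -> str:
        return self._protein

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codon(self, position: int) -> str:
        """Codon at 1-based amino-acid position."""
        if not 1 <= position <= self.n_codons:
            raise IndexError(f"position {position} outside 1..{self.n_codons}")
        return self.sequence[3 * (position - 1) : 3 * position]


@dataclass(frozen=True, order=True)
class MutationSpec:
    """One amino-acid substitution, 1-based (initiator Met = residue 1)."""

    position: int
    parent_aa: str
    mutant_aa: str

    def __post_init__(self) -> None:
        ok = set(AMINO_ACIDS + STOP)
        if self.parent_aa not in ok or self.mutant_aa not in ok:
            raise MutationParseError(
                f"invalid amino-acid code in {self.parent_aa}{self.position}{self.mutant_aa}"
            )
        if self.parent_aa == self.mutant_aa:
            raise MutationValidationError(
                f"identity substitution {self.parent_aa}{self.position}{self.mutant_aa}"
            )
        if self.position < 1:
            raise MutationValidationError(f"position {self.position} is not 1-based")

    def validate_against(self, parent: ParentCDS) -> None:
        if self.position > parent.n_codons:
            raise MutationValidationError(
                f"position {self.position} beyond protein length {parent.n_codons}"
            )
        actual = parent.protein[self.position - 1]
        if actual != self.parent_aa:
            raise MutationValidationError(
                f"parent residue at position {self.position} is {actual}, "
                f"not {self.parent_aa}"
            )

    @property
    def name(self) -> str:
        return f"{self.parent_aa}{self.position}{self.mutant_aa}"


def parse_mutation_string(text: str, parent: ParentCDS) -> list[MutationSpec]:
    """Parse a mutant name like ``"T6A"`` or ``"S9G-R31L-R85L"``.

    Each dash-separated token is ``<parent aa><1-based position><mutant aa>``;
    every token is validated against the parent protein.  Order is preserved.
    """
    tokens = text.strip().split("-")
    specs: list[MutationSpec] = []
    for token in tokens:
        m = _MUTATION_RE.match(token)
        if m is None:
            raise MutationParseError(f"malformed mutation token {token!r}")
        spec = MutationSpec(int(m.group(2)), m.group(1), m.group(3))
        spec.validate_against(parent)
        specs.append(spec)
    return specs


def format_mutation_string(mutations: Sequence[MutationSpec]) -> str:
    """Inverse of :func:`parse_mutation_string` on valid specs."""
    if not mutations:
        return ""
    return "-".join(m.name for m in mutations)


@dataclass(frozen=True)
class LibraryMember:
    """One designed mutant: its mutations and full mutant CDS."""

    member_id: str
    mutations: tuple[MutationSpec, ...]
    cds: str
    designed_mutation_count: int

    def __post_init__(self) -> None:
        if len(self.mutations) != self.designed_mutation_count:
            raise ValueError(
                f"{self.member_id}: {len(self.mutations)} mutations but "
                f"designed_mutation_count={self.designed_mutation_count}"
            )


def apply_mutations(
    parent: ParentCDS,
    mutations: Sequence[MutationSpec],
    table: CodonTable = ECOLI_TABLE,
) -> str:
    """Mutant CDS: parent with each mutated codon set to the table's
    preferred codon for the new amino acid."""
    codons = [parent.sequence[i : i + 3] for i in range(0, len(parent.sequence), 3)]
    seen: set[int] = set()
    for spec in mutations:
        spec.validate_against(parent)
        if spec.position in seen:
            raise MutationValidationError(
                f"multiple mutations at position {spec.position}"
            )
        seen.add(spec.position)
        codons[spec.position - 1] = table.preferred(spec.mutant_aa)
    return "".join(codons)


def make_member(
    parent: ParentCDS,
    mutations: Sequence[MutationSpec],
    table: CodonTable = ECOLI_TABLE,
    member_id: str | None = None,
) -> LibraryMember:
    muts = tuple(mutations)
    return LibraryMember(
        member_id=member_id or (format_mutation_string(muts) or f"{parent.id}-WT"),
        mutations=muts,
        cds=apply_mutations(parent, muts, table),
        designed_mutation_count=len(muts),
    )


def member_from_cds(
    parent: ParentCDS, cds: str, member_id: str
) -> LibraryMember:
    """Reconstruct a member from an observed CDS by amino-acid comparison.

    Used to parse sequenced pools back into members for QC.  The observed
    CDS must align codon-for-codon with the parent (no indels).
    """
    validate_dna(cds, context=f"member {member_id!r}")
    if len(cds) != len(parent.sequence):
        raise ValueError(
            f"member {member_id!r} length {len(cds)} != parent {len(parent.sequence)}"
        )
    protein = ECOLI_TABLE.translate(cds)
    muts = tuple(
        MutationSpec(i + 1, p, q)
        for i, (p, q) in enumerate(zip(parent.protein, protein))
        if p != q
    )
    return LibraryMember(member_id, muts, cds, len(muts))


def design_site_saturation(
    parent: ParentCDS,
    table: CodonTable = ECOLI_TABLE,
    codon_range: tuple[int, int] | None = None,
) -> list[LibraryMember]:
    """Scanning site-saturation library over ``codon_range`` (1-based,
    inclusive; default the full CDS).

    Each codon in range yields 20 members: the 19 non-parent amino acids plus
    a stop codon, each encoded by the table's preferred codon, each member
    differing from the parent at exactly that one codon.
    """
    lo, hi = codon_range if codon_range is not None else (1, parent.n_codons)
    if not (1 <= lo <= hi <= parent.n_codons):
        raise ValueError(
            f"codon range {lo}-{hi} outside CDS (1-{parent.n_codons})"
        )
    members: list[LibraryMember] = []
    for pos in range(lo, hi + 1):
        parent_aa = parent.protein[pos - 1]
        for aa in AMINO_ACIDS + STOP:
            if aa == parent_aa:
                continue
            spec = MutationSpec(pos, parent_aa, aa)
            members.append(make_member(parent, [spec], table))
    return members


@dataclass(frozen=True)
class RecombinationLibrary(Sequence):
    """Paired-recombination members plus the report of skipped pairs
    (pairs whose mutations share a position cannot coexist in one CDS)."""

    members: tuple[LibraryMember, ...]
    skipped_pairs: tuple[tuple[MutationSpec, MutationSpec], ...]

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, i):
        return self.members[i]


def design_paired_recombination(
    parent: ParentCDS,
    mutations: Sequence[MutationSpec],
    table: CodonTable = ECOLI_TABLE,
) -> RecombinationLibrary:
    """One member per unordered pair of mutations at distinct positions."""
    if len(mutations) < 2:
        raise ValueError("paired recombination needs at least 2 mutations")
    for spec in mutations:
        spec.validate_against(parent)
    members: list[LibraryMember] = []
    skipped: list[tuple[MutationSpec, MutationSpec]] = []
    for a, b in combinations(mutations, 2):
        if a.position == b.position:
            skipped.append((a, b))
            continue
        pair = tuple(sorted((a, b)))
        members.append(make_member(parent, pair, table))
    return RecombinationLibrary(tuple(members), tuple(skipped))


@dataclass(frozen=True)
class MutationCountQC:
    """Partition of an observed pool by mutation count vs. the design.

    PCR amplification of near-identical oligo pools swaps mutations between
    members (template swapping), so a pool designed at two mutations per
    member acquires a tail of zero- and three-mutation sequences.  Members
    off the designed count are the candidate artifacts.
    """

    designed_count: int
    counts: dict[str, int]
    matching: tuple[str, ...]
    fewer: tuple[str, ...]
    more: tuple[str, ...]

    @property
    def flagged(self) -> tuple[str, ...]:
        return self.fewer + self.more


def qc_mutation_count(
    observed: Iterable[LibraryMember],
    designed_count: int,
    parent: ParentCDS | None = None,
) -> MutationCountQC:
    """Partition observed members into {matching, fewer, more} by their
    amino-acid mutation count.  When ``parent`` is given, counts are
    recomputed from each member's CDS rather than trusted from metadata."""
    counts: dict[str, int] = {}
    matching: list[str] = []
    fewer: list[str] = []
    more: list[str] = []
    for member in observed:
        if parent is not None:
            n = sum(
                p != q
                for p, q in zip(parent.protein, ECOLI_TABLE.translate(member.cds))
            )
        else:
            n = len(member.mutations)
        counts[member.member_id] = n
        if n == designed_count:
            matching.append(member.member_id)
        elif n < designed_count:
            fewer.append(member.member_id)
        else:
            more.append(member.member_id)
    return MutationCountQC(
        designed_count, counts, tuple(matching), tuple(fewer), tuple(more)
    )


@dataclass(frozen=True)
class CoverageCheck:
    fold: float
    threshold: float
    passed: bool


def check_library_coverage(
    n_transformants: int, n_unique_designed: int, threshold: float = 100.0
) -> CoverageCheck:
    """Transformant fold-coverage of the designed diversity.

    Libraries are transformed until the colony count is at least
    ``threshold`` times the number of unique designed sequences (default
    100×) so that every member is sampled.
    """
    if n_transformants < 0 or n_unique_designed < 0:
        raise ValueError("counts must be non-negative")
    if n_unique_designed == 0:
        raise ValueError("n_unique_designed must be positive")
    fold = n_transformants / n_unique_designed
    return CoverageCheck(fold=fold, threshold=threshold, passed=fold >= threshold)


def random_parent_cds(
    n_codons: int, seed: int, id: str = "synthetic-parent"
) -> ParentCDS:
    """A synthetic parent CDS: ATG followed by ``n_codons - 1`` random
    non-stop, non-Met codons drawn from the ranked codon table.

    Stands in for real gas-vesicle structural-protein genes in tests and
    simulations; only the codon count matters for library cardinality.
    Sequences are domesticated for cassette cloning (no BsaI recognition
    site on either strand), as Golden Gate parts must be.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    choices = [
        codon
        for aa in AMINO_ACIDS
        if aa != "M"
        for codon in ECOLI_TABLE.synonyms(aa)
    ]
    for _ in range(1000):
        body = [choices[i] for i in rng.integers(0, len(choices), size=n_codons - 1)]
        seq = "ATG" + "".join(body)
        if "GGTCTC" not in seq and "GAGACC" not in seq:
            return ParentCDS(id=id, sequence=seq)
    raise RuntimeError("could not draw a domesticated sequence")  # pragma: no cover


def expected_saturation_size(n_codons: int) -> int:
    """Closed-form library size: 20 substitutions (19 aa + stop) per codon."""
    return 20 * n_codons


def expected_recombination_size(n_mutations: int) -> int:
    return math.comb(n_mutations, 2)
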