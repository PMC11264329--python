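"""Cassette oligo design and in-silico Golden Gate assembly.

Mutant libraries are synthesized as oligo pools: each oligo carries a
*variable region* (one window of the CDS, with the member's mutations) framed
by constant primer-binding flanks and inward-facing Type IIS recognition
sites.  Digestion releases the variable region with 4-nt single-stranded
overhangs; ligation into a window-specific acceptor vector (which carries the
rest of the gene constant, plus a chromoprotein dropout between matching
Type IIS sites) reconstitutes the full-length mutant CDS.

The junction overhangs are taken from the parent sequence itself (last 4 nt
of the constant region upstream of a window, first 4 nt downstream), so a
correct assembly is an exact sequence round trip.  All overhangs in a design
must be mutually distinct and non-palindromic or ligation would scramble.

The digestion/ligation engine below works on plain sequences: it locates
recognition sites on both strands, cuts with the enzyme's spacer/overhang
geometry, and enumerates every circular ligation product, so wrong or
scrambled overhangs surface as assembly failures rather than silent errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .codons import ECOLI_TABLE, CodonTable, reverse_complement, validate_dna
from .mutagenesis import LibraryMember, ParentCDS


class TilingError(ValueError):
    """No valid window tiling (e.g. unavoidable overhang collision)."""


class OligoDesignError(ValueError):
    """A member cannot be encoded as a single cassette oligo."""


class AssemblyError(ValueError):
    """Golden Gate assembly failed (no product, or ambiguous products)."""


@dataclass(frozen=True)
class TypeIIS:
    """A Type IIS restriction enzyme cutting outside its recognition site."""

    name: str = "BsaI"
    recognition: str = "GGTCTC"
    spacer: int = 1
    overhang_len: int = 4

    @property
    def recognition_rc(self) -> str:
        return reverse_complement(self.recognition)


BSAI = TypeIIS()

# Constant vector arms shared by all acceptor vectors.  The last/first 4 nt
# serve as the terminal assembly overhangs (AATG ahead of the start codon,
# GCTT after the CDS); both are non-palindromic and free of BsaI sites.
DEFAULT_UP_ARM = "CGTGAGGTGAATCCGTAATG"
DEFAULT_DOWN_ARM = "GCTTCGAGTGCCATCACGTC"
DEFAULT_DROPOUT = "ATGGCAAGCTGTGATCCTCGGCACCACGTTAAGCCACGGATC"  # chromoprotein stub

# Constant primer-binding flanks, one pair per window index (cycled if a
# design has more windows).  Arbitrary fixed sequences chosen free of BsaI
# sites on either strand.
_WINDOW_FLANKS: tuple[tuple[str, str], ...] = (
    ("CACCTATCCAGGTGAACTCT", "TGGATCAACCTGCCATCAGT"),
    ("GATTACGCCAAGCTTGCATG", "CATGGTCATAGCTGTTTCCT"),
    ("TCCCAGTCACGACGTTGTAA", "GCGGATAACAATTTCACACA"),
    ("ACGACGGCCAGTGAATTGTA", "TCACACAGGAAACAGCTATG"),
    ("GTTGTAAAACGACGGCCAGT", "CAGGAAACAGCTATGACCAT"),
    ("TTGTGAGCGGATAACAATTT", "ACTGGCCGTCGTTTTACAAC"),
)


def is_palindromic(seq: str) -> bool:
    return seq == reverse_complement(seq)


def _has_site(seq: str, enzyme: TypeIIS = BSAI) -> bool:
    return enzyme.recognition in seq or enzyme.recognition_rc in seq


@dataclass(frozen=True)
class CassetteWindow:
    """One tiling window of the CDS (1-based inclusive codon interval)."""

    start: int
    end: int
    upstream_flank: str
    downstream_flank: str
    overhang_5: str
    overhang_3: str
    index: int = 0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid window {self.start}-{self.end}")
        for oh in (self.overhang_5, self.overhang_3):
            if len(oh) != 4:
                raise ValueError(f"overhang {oh!r} is not 4 nt")

    @property
    def n_codons(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def variable_slice(self) -> slice:
        return slice(3 * (self.start - 1), 3 * self.end)


def _window_overhang_pairs(
    parent: ParentCDS,
    boundaries: Sequence[int],
    up_arm: str,
    down_arm: str,
) -> list[tuple[str, str]]:
    """(overhang_5, overhang_3) for each window of a tiling.

    ``boundaries`` are 1-based codon indices where a new window starts.
    A window's 5' overhang is the last 4 nt of its upstream constant region
    (vector arm + parent prefix) and its 3' overhang the first 4 nt of the
    downstream constant region (parent suffix + vector arm), so assembly
    reconstitutes the parent sequence exactly.
    """
    seq = parent.sequence
    starts = [1, *boundaries]
    ends = [*(b - 1 for b in boundaries), parent.n_codons]
    pairs = []
    for s, e in zip(starts, ends):
        oh5 = (up_arm + seq[: 3 * (s - 1)])[-4:]
        oh3 = (seq[3 * e :] + down_arm)[:4]
        pairs.append((oh5, oh3))
    return pairs


def _overhang_collisions(overhangs: Sequence[str]) -> list[int]:
    """Indices of junction overhangs that collide (duplicate, palindromic,
    or equal to another's reverse complement)."""
    bad: set[int] = set()
    for i, oh in enumerate(overhangs):
        if is_palindromic(oh):
            bad.add(i)
        for j in range(i + 1, len(overhangs)):
            other = overhangs[j]
            if oh == other or oh == reverse_complement(other):
                bad.add(i)
                bad.add(j)
    return sorted(bad)


def tile_cds(
    parent: ParentCDS,
    max_variable_len: int = 90,
    boundaries: Sequence[int] | None = None,
    up_arm: str = DEFAULT_UP_ARM,
    down_arm: str = DEFAULT_DOWN_ARM,
    max_shift: int = 3,
) -> list[CassetteWindow]:
    """Tile the CDS into cassette windows of near-equal size.

    Windows cover every codon exactly once with variable regions at most
    ``max_variable_len`` nt.  Junction overhangs are read off the parent
    sequence; when the even split collides (duplicate / palindromic / reverse
    complement overhangs) junctions are shifted by up to ``max_shift`` codons
    to find a clean set, and a :class:`TilingError` lists the colliding
    junctions if none exists.

    ``boundaries`` (1-based codon indices starting each window after the
    first) overrides the automatic split; explicit boundaries are used as-is
    and only validated.
    """
    if max_variable_len < 3:
        raise ValueError("max_variable_len must be >= 3 nt (one codon)")
    n = parent.n_codons
    max_codons = max_variable_len // 3

    if boundaries is not None:
        bounds = list(boundaries)
        for b in bounds:
            if not float(b).is_integer() or not 2 <= b <= n:
                raise TilingError(f"boundary {b} is not a codon start within the CDS")
        if sorted(set(bounds)) != bounds:
            raise TilingError("boundaries must be strictly increasing and unique")
        candidates = [bounds]
    else:
        n_windows = -(-n // max_codons)  # ceil
        base, rem = divmod(n, n_windows)
        # near-equal windows; the remainder codons go to the trailing windows
        widths = [base] * (n_windows - rem) + [base + 1] * rem
        bounds = []
        pos = 1
        for w in widths[:-1]:
            pos += w
            bounds.append(pos)
        candidates = _boundary_variants(bounds, n, max_codons, max_shift)

    last_collisions: list[int] = []
    for bounds in candidates:
        if any(not 2 <= b <= n for b in bounds):
            continue
        widths = _window_widths(bounds, n)
        if any(w < 1 or w > max_codons for w in widths):
            continue
        pairs = _window_overhang_pairs(parent, bounds, up_arm, down_arm)
        flat = [oh for pair in pairs for oh in pair]
        collisions = _overhang_collisions(flat)
        if not collisions:
            return _build_windows(parent, bounds, pairs)
        last_collisions = collisions
    raise TilingError(
        f"no overhang-compatible tiling of {parent.id!r}: colliding junctions "
        f"{last_collisions}"
    )


def _window_widths(bounds: Sequence[int], n: int) -> list[int]:
    starts = [1, *bounds]
    ends = [*(b - 1 for b in bounds), n]
    return [e - s + 1 for s, e in zip(starts, ends)]


def _boundary_variants(
    bounds: list[int], n: int, max_codons: int, max_shift: int
) -> Iterable[list[int]]:
    """Even split first, then boundary shifts in increasing total distance."""
    if not bounds:
        yield []
        return
    from itertools import product

    shifts = sorted(range(-max_shift, max_shift + 1), key=abs)
    combos = sorted(
        product(shifts, repeat=len(bounds)), key=lambda c: sum(abs(x) for x in c)
    )
    for combo in combos:
        cand = [b + s for b, s in zip(bounds, combo)]
        if all(x < y for x, y in zip(cand, cand[1:])):
            yield cand


def _build_windows(
    parent: ParentCDS,
    bounds: Sequence[int],
    overhang_pairs: Sequence[tuple[str, str]],
) -> list[CassetteWindow]:
    starts = [1, *bounds]
    ends = [*(b - 1 for b in bounds), parent.n_codons]
    windows = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        flank5, flank3 = _WINDOW_FLANKS[i % len(_WINDOW_FLANKS)]
        windows.append(
            CassetteWindow(
                start=s,
                end=e,
                upstream_flank=flank5,
                downstream_flank=flank3,
                overhang_5=overhang_pairs[i][0],
                overhang_3=overhang_pairs[i][1],
                index=i,
            )
        )
    return windows


@dataclass(frozen=True)
class Recoding:
    """A synonymous codon rewrite that removed a Type IIS site."""

    member_id: str
    position: int
    old_codon: str
    new_codon: str


@dataclass(frozen=True)
class OligoDesign:
    member_id: str
    variable_region: str
    full_oligo: str
    window: CassetteWindow
    recodings: tuple[Recoding, ...] = ()


def _count_sites(seq: str, enzyme: TypeIIS) -> int:
    count = 0
    for site in (enzyme.recognition, enzyme.recognition_rc):
        start = 0
        while (i := seq.find(site, start)) != -1:
            count += 1
            start = i + 1
    return count


def _rescue_forbidden_sites(
    member: LibraryMember,
    variable: str,
    window: CassetteWindow,
    table: CodonTable,
    enzyme: TypeIIS,
) -> tuple[str, list[Recoding]]:
    """Remove enzyme recognition sites from a variable region by synonymous
    recoding of a codon overlapping the site.

    Deterministic: codons overlapping the site are tried left to right, and
    for each, synonymous codons in table rank order; the first rewrite that
    leaves the region free of sites on both strands wins.
    """
    mutated = {m.position for m in member.mutations}
    recodings: list[Recoding] = []
    for _ in range(10):  # a rewrite could in principle expose another site
        hit = _first_site(variable, enzyme)
        if hit is None:
            return variable, recodings
        site_start, site_len = hit
        first_codon = site_start // 3
        last_codon = (site_start + site_len - 1) // 3
        fixed = None
        for ci in range(first_codon, last_codon + 1):
            pos = window.start + ci  # 1-based protein position of codon ci
            old = variable[3 * ci : 3 * ci + 3]
            aa = table.amino_acid(old)
            for alt in table.synonyms(aa):
                if alt == old:
                    continue
                cand = variable[: 3 * ci] + alt + variable[3 * ci + 3 :]
                if _first_site(cand, enzyme) is not None:
                    continue
                fixed = (cand, Recoding(member.member_id, pos, old, alt))
                break
            if fixed:
                break
        if fixed is None:
            raise OligoDesignError(
                f"{member.member_id}: cannot remove {enzyme.name} site from "
                "variable region by synonymous recoding"
            )
        variable, rec = fixed
        recodings.append(rec)
    raise OligoDesignError(
        f"{member.member_id}: recoding loop did not converge"
    )


def _first_site(seq: str, enzyme: TypeIIS) -> tuple[int, int] | None:
    hits = []
    for site in (enzyme.recognition, enzyme.recognition_rc):
        i = seq.find(site)
        if i != -1:
            hits.append((i, len(site)))
    return min(hits) if hits else None


def emit_oligos(
    members: Iterable[LibraryMember],
    windows: Sequence[CassetteWindow],
    parent: ParentCDS,
    adapters: tuple[str, str] = ("", ""),
    table: CodonTable = ECOLI_TABLE,
    enzyme: TypeIIS = BSAI,
) -> list[OligoDesign]:
    """One cassette oligo per member.

    Layout: ``adapter5 + flank5 + REC + spacer + overhang_5 + variable +
    overhang_3 + spacer + rc(REC) + flank3 + adapter3`` — two inward-facing
    recognition sites whose digestion releases the variable region carrying
    the window's overhangs.  Members whose mutations (or whose window
    sequence) contain a recognition site are recoded synonymously and the
    rewrite reported on the oligo.
    """
    for ad in adapters:
        validate_dna(ad, context="adapter")
        if _has_site(ad, enzyme):
            raise OligoDesignError(f"adapter contains a {enzyme.name} site")
    spacer = "A" * enzyme.spacer
    oligos: list[OligoDesign] = []
    for member in members:
        window = _window_for(member, windows)
        variable = member.cds[window.variable_slice()]
        variable, recodings = _rescue_forbidden_sites(
            member, variable, window, table, enzyme
        )
        full = (
            adapters[0]
            + window.upstream_flank
            + enzyme.recognition
            + spacer
            + window.overhang_5
            + variable
            + window.overhang_3
            + spacer
            + enzyme.recognition_rc
            + window.downstream_flank
            + adapters[1]
        )
        if _count_sites(full, enzyme) != 2:
            raise OligoDesignError(
                f"{member.member_id}: oligo does not contain exactly two "
                f"{enzyme.name} sites"
            )
        oligos.append(
            OligoDesign(
                member_id=member.member_id,
                variable_region=variable,
                full_oligo=full,
                window=window,
                recodings=tuple(recodings),
            )
        )
    return oligos


def _window_for(
    member: LibraryMember, windows: Sequence[CassetteWindow]
) -> CassetteWindow:
    if not member.mutations:
        return windows[0]
    positions = [m.position for m in member.mutations]
    for window in windows:
        if all(window.contains(p) for p in positions):
            return window
    raise OligoDesignError(
        f"{member.member_id}: mutations at {positions} do not fall inside a "
        "single cassette window"
    )


@dataclass(frozen=True)
class AcceptorVector:
    """Circular acceptor plasmid for one cassette window.

    Carries the constant remainder of the CDS with a dropout stub between
    inward-facing Type IIS sites; digestion excises the dropout and exposes
    the window's two overhangs on the backbone.
    """

    id: str
    sequence: str  # linearized representation of the circular plasmid
    up_arm: str
    down_arm: str
    window: CassetteWindow


def build_acceptor(
    parent: ParentCDS,
    window: CassetteWindow,
    up_arm: str = DEFAULT_UP_ARM,
    down_arm: str = DEFAULT_DOWN_ARM,
    dropout: str = DEFAULT_DROPOUT,
    enzyme: TypeIIS = BSAI,
) -> AcceptorVector:
    if window.overhang_5 != (up_arm + parent.sequence[: 3 * (window.start - 1)])[-4:]:
        raise ValueError("window overhang_5 inconsistent with parent/arm")
    if window.overhang_3 != (parent.sequence[3 * window.end :] + down_arm)[:4]:
        raise ValueError("window overhang_3 inconsistent with parent/arm")
    for name, seq in (("up_arm", up_arm), ("down_arm", down_arm), ("dropout", dropout)):
        if _has_site(seq, enzyme):
            raise ValueError(f"{name} contains a {enzyme.name} site")
    spacer = "A" * enzyme.spacer
    prefix = parent.sequence[: 3 * (window.start - 1)]
    suffix = parent.sequence[3 * window.end :]
    for region, name in ((prefix, "upstream"), (suffix, "downstream")):
        if _has_site(region, enzyme):
            raise ValueError(
                f"{parent.id!r}: {name} constant region contains a "
                f"{enzyme.name} site — the parent must be domesticated before "
                "cassette cloning"
            )
    seq = (
        up_arm
        + prefix
        + spacer
        + enzyme.recognition_rc
        + dropout
        + enzyme.recognition
        + spacer
        + suffix
        + down_arm
    )
    if len(_cut_positions(seq, enzyme, circular=True)) != 2:
        raise ValueError(
            f"{parent.id!r}: acceptor for window {window.index} does not digest "
            "at exactly two sites"
        )
    return AcceptorVector(
        id=f"{parent.id}-acceptor-w{window.index}",
        sequence=seq,
        up_arm=up_arm,
        down_arm=down_arm,
        window=window,
    )


# ---------------------------------------------------------------------------
# digestion / ligation engine


@dataclass(frozen=True)
class Fragment:
    """A double-stranded fragment in the shared-overhang representation.

    ``seq`` is the top strand *including* both 4-nt overhangs; ``left`` /
    ``right`` are those terminal 4-mers (None for a blunt/uncut end, which
    cannot ligate here).
    """

    seq: str
    left: str | None
    right: str | None

    def reverse_complement(self) -> "Fragment":
        return Fragment(
            reverse_complement(self.seq),
            None if self.right is None else reverse_complement(self.right),
            None if self.left is None else reverse_complement(self.left),
        )


def _cut_positions(seq: str, enzyme: TypeIIS, circular: bool) -> list[int]:
    """0-based positions c of each cut's shared overhang window [c, c+4)."""
    n = len(seq)
    search = seq + seq[: len(enzyme.recognition) + enzyme.spacer + enzyme.overhang_len] if circular else seq
    cuts: set[int] = set()
    start = 0
    while (i := search.find(enzyme.recognition, start)) != -1:
        if i < n:
            c = i + len(enzyme.recognition) + enzyme.spacer
            cuts.add(c % n if circular else c)
        start = i + 1
    start = 0
    while (i := search.find(enzyme.recognition_rc, start)) != -1:
        if i < n:
            c = i - enzyme.spacer - enzyme.overhang_len
            cuts.add(c % n if circular else c)
        start = i + 1
    if not circular:
        cuts = {c for c in cuts if 0 <= c and c + enzyme.overhang_len <= n}
    return sorted(cuts)


def digest(seq: str, enzyme: TypeIIS = BSAI, circular: bool = False) -> list[Fragment]:
    """Cut a sequence at every Type IIS site (both strands)."""
    k = enzyme.overhang_len
    cuts = _cut_positions(seq, enzyme, circular)
    n = len(seq)
    if not cuts:
        return [Fragment(seq, None, None)]
    frags: list[Fragment] = []
    if circular:
        for a, b in zip(cuts, cuts[1:] + [cuts[0] + n]):
            piece = (seq + seq)[a : b + k]
            frags.append(Fragment(piece, piece[:k], piece[-k:]))
    else:
        prev = 0
        prev_oh: str | None = None
        for c in cuts:
            piece = seq[prev : c + k]
            frags.append(Fragment(piece, prev_oh, seq[c : c + k]))
            prev, prev_oh = c, seq[c : c + k]
        piece = seq[prev:]
        frags.append(Fragment(piece, prev_oh, None))
    return frags


def _canonical_circular(seq: str) -> str:
    """Rotation- and strand-invariant canonical form of a circular sequence."""
    best = None
    for s in (seq, reverse_complement(seq)):
        doubled = s + s
        for i in range(len(s)):
            rot = doubled[i : i + len(s)]
            if best is None or rot < best:
                best = rot
    return best or seq


def ligate_circular(fragments: Sequence[Fragment]) -> list[str]:
    """Enumerate all distinct circular ligation products.

    Fragments may be used in either orientation, each at most once per
    product.  Overhangs join by exact 4-mer identity in the shared-overhang
    representation (Watson–Crick complementarity is implicit).  Returns
    canonicalized circular sequences.
    """
    oriented: list[list[Fragment]] = [
        [f, f.reverse_complement()] for f in fragments if f.left and f.right
    ]
    products: dict[str, str] = {}

    def extend(chain: list[Fragment], used: set[int]) -> None:
        tail = chain[-1]
        if tail.right == chain[0].left:
            # circle closes; dropping each fragment's right-hand 4-mer leaves
            # every junction overhang represented exactly once
            circ = "".join(f.seq[:-4] for f in chain)
            products.setdefault(_canonical_circular(circ), circ)
        for idx, orients in enumerate(oriented):
            if idx in used:
                continue
            for frag in orients:
                if frag.left == tail.right:
                    extend(chain + [frag], used | {idx})

    for idx, orients in enumerate(oriented):
        for frag in orients:
            extend([frag], {idx})
    return list(products.values())


def simulate_assembly(
    oligo: OligoDesign,
    acceptor: AcceptorVector,
    enzyme: TypeIIS = BSAI,
) -> str:
    """Golden Gate assembly of one cassette oligo into its acceptor vector.

    Digests both molecules, ligates, and requires exactly one circular
    product that contains the vector backbone; returns the CDS extracted
    from between the vector arms.  Raises :class:`AssemblyError` on overhang
    mismatch (no product) or ambiguity (>1 distinct product).
    """
    oligo_frags = digest(oligo.full_oligo, enzyme, circular=False)
    inserts = [f for f in oligo_frags if f.left and f.right]
    if len(inserts) != 1:
        raise AssemblyError(
            f"{oligo.member_id}: oligo digestion yielded {len(inserts)} "
            "double-sticky fragments (expected 1)"
        )
    acceptor_frags = digest(acceptor.sequence, enzyme, circular=True)
    backbones = [
        f for f in acceptor_frags if acceptor.down_arm in f.seq and f.left and f.right
    ]
    if len(backbones) != 1:
        raise AssemblyError(
            f"{acceptor.id}: digestion did not yield a unique backbone fragment"
        )
    products = ligate_circular([inserts[0], backbones[0]])
    with_backbone = [p for p in products if acceptor.down_arm in p + p]
    if not with_backbone:
        raise AssemblyError(
            f"{oligo.member_id} + {acceptor.id}: no circular product "
            "(overhang mismatch)"
        )
    # deduplicate backbone-only self-circles vs full assemblies
    full = [p for p in with_backbone if len(p) > len(backbones[0].seq)]
    if len(full) > 1:
        raise AssemblyError(
            f"{oligo.member_id} + {acceptor.id}: ambiguous assembly "
            f"({len(full)} distinct products)"
        )
    if not full:
        raise AssemblyError(
            f"{oligo.member_id} + {acceptor.id}: no full-length product "
            "(overhang mismatch)"
        )
    return _extract_cds(full[0], acceptor)


def _extract_cds(circular_product: str, acceptor: AcceptorVector) -> str:
    doubled = circular_product + circular_product
    rc = reverse_complement(circular_product)
    for candidate in (doubled, rc + rc):
        i = candidate.find(acceptor.up_arm)
        if i == -1:
            continue
        start = i + len(acceptor.up_arm)
        j = candidate.find(acceptor.down_arm, start)
        if j == -1:
            continue
        return candidate[start:j]
    raise AssemblyError("vector arms not found in assembly product")
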