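"""Break-construct data model and junction decomposition.

A double-strand break is described by the two broken arms, each written
5'->3' on the top strand: ``left_arm`` ends at the break, ``right_arm``
begins at it.  For a P-element excision gap each arm carries genomic
flank, the 8-bp target-site duplication created on insertion, and a
17-nt 3' single-stranded tail; the two tails are mutual reverse
complements.  Case in the arm strings is a display annotation only
(uppercase overhang, lowercase flank/TSD) and is ignored for matching.

A repair-product junction read spanning the break is decomposed by the
maximal-retention convention: the longest read prefix matching the left
arm (``p``) and the longest read suffix matching the right arm (``s``)
are each independently maximal.  If ``p + s`` exceeds the read length
the overlap is microhomology -- sequence attributable to either side of
the break; if it falls short, the middle segment is an insertion,
sequence present at neither end of the original break.  Deletion
extents on each side are reported as ``[min, max]`` ranges because the
microhomology can be assigned to either arm.

Microhomology calls can be refined mismatch-tolerantly.  By default
only calls of >= 6 nt with <= 1 internal mismatch (never at a terminal
position) upgrade the exact call: an imperfect call must be strictly
longer than any perfect microhomology the construct offers, otherwise
spurious 5-nt one-mismatch overlaps would reclassify junctions whose
annealing is fully explained by a short perfect microhomology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AltEJError",
    "UnanchoredReadError",
    "DegenerateReadError",
    "BreakConstruct",
    "JunctionRead",
    "Decomposition",
    "MicrohomologyCall",
    "reverse_complement",
    "longest_common_prefix",
    "longest_common_suffix",
    "decompose",
    "refine_microhomology",
    "deletion_flags",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")
_VALID = frozenset("ACGTacgt")


class AltEJError(ValueError):
    """Base class for junction-analysis errors."""


class UnanchoredReadError(AltEJError):
    """The read does not begin in the left arm or end in the right arm."""


class DegenerateReadError(AltEJError):
    """The read lies wholly within a single arm and spans no junction."""


def _check_alphabet(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - _VALID
    if bad:
        raise AltEJError(
            f"{what} contains non-ACGT character(s): {sorted(bad)!r}"
        )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, uppercased.

    Raises :class:`AltEJError` on non-ACGT input.
    """
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1].upper()


def longest_common_prefix(a: str, b: str) -> int:
    """Length of the longest shared prefix of *a* and *b*, case-insensitive."""
    a = a.upper()
    b = b.upper()
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def longest_common_suffix(a: str, b: str) -> int:
    """Length of the longest shared suffix of *a* and *b*, case-insensitive."""
    a = a.upper()
    b = b.upper()
    n = min(len(a), len(b))
    i = 0
    while i < n and a[len(a) - 1 - i] == b[len(b) - 1 - i]:
        i += 1
    return i


@dataclass(frozen=True)
class BreakConstruct:
    """The two broken arms and their annotated spans.

    ``left_arm`` is written 5'->3' on the top strand and ends at the
    break; ``right_arm`` begins at it.  ``*_overhang_len`` give the
    single-stranded tail lengths at the break-proximal ends and
    ``tsd_len`` the target-site duplication adjacent to each tail.
    """

    left_arm: str
    right_arm: str
    left_overhang_len: int = 0
    right_overhang_len: int = 0
    tsd_len: int = 0
    name: str = "construct"

    def __post_init__(self) -> None:
        if not self.left_arm or not self.right_arm:
            raise AltEJError("construct arms must be non-empty")
        _check_alphabet(self.left_arm, "left_arm")
        _check_alphabet(self.right_arm, "right_arm")
        if self.left_overhang_len + self.tsd_len > len(self.left_arm):
            raise AltEJError("left overhang + TSD exceed left arm length")
        if self.right_overhang_len + self.tsd_len > len(self.right_arm):
            raise AltEJError("right overhang + TSD exceed right arm length")

    def swapped(self) -> "BreakConstruct":
        """The same break viewed from the bottom strand.

        Arms swap and reverse-complement; a read decomposed against the
        swapped construct must be reverse-complemented too.
        """
        return BreakConstruct(
            left_arm=reverse_complement(self.right_arm),
            right_arm=reverse_complement(self.left_arm),
            left_overhang_len=self.right_overhang_len,
            right_overhang_len=self.left_overhang_len,
            tsd_len=self.tsd_len,
            name=self.name + "_revcomp",
        )


@dataclass(frozen=True)
class JunctionRead:
    """One repair-product top-strand sequence with its isolate count."""

    read_id: str
    sequence: str
    genotype: str = ""
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AltEJError(f"read {self.read_id}: empty sequence")
        _check_alphabet(self.sequence, f"read {self.read_id}")
        if self.multiplicity < 1:
            raise AltEJError(f"read {self.read_id}: multiplicity must be >= 1")


@dataclass(frozen=True)
class Decomposition:
    """Maximal-retention decomposition of one junction read.

    ``p``/``s`` are the maximal left/right retentions; ``mh_len`` /
    ``mh_seq`` the microhomology overlap (empty if none); ``insertion``
    the read segment attributable to neither arm.  Deletion extents are
    ``[min, max]`` with range width ``mh_len``.
    """

    p: int
    s: int
    mh_len: int
    mh_seq: str
    insertion: str
    del_left_min: int
    del_left_max: int
    del_right_min: int
    del_right_max: int
    past_tsd_left: bool = False
    past_tsd_right: bool = False
    flank_exhausted: bool = False


@dataclass(frozen=True)
class MicrohomologyCall:
    """A (possibly imperfect) microhomology spanning the junction.

    ``exact_side`` names the arm the read matches exactly over the call
    span; ``both`` means a perfect microhomology.  ``span`` is 0-based
    half-open on the read.
    """

    length: int
    mismatch_count: int
    mismatch_offsets: tuple[int, ...]
    exact_side: str  # "left" | "right" | "both"
    span: tuple[int, int]


def decompose(construct: BreakConstruct, read: JunctionRead) -> Decomposition:
    """Decompose *read* against *construct* by maximal retention.

    Raises :class:`UnanchoredReadError` if the read shares no sequence
    with an arm terminus, and :class:`DegenerateReadError` if it lies
    wholly within one arm.
    """
    seq = read.sequence
    n = len(seq)
    p = longest_common_prefix(seq, construct.left_arm)
    s = longest_common_suffix(seq, construct.right_arm)
    if p == n or s == n:
        raise DegenerateReadError(
            f"read {read.read_id} lies wholly within one arm (p={p}, s={s})"
        )
    if p == 0 or s == 0:
        raise UnanchoredReadError(
            f"read {read.read_id} does not join both arms (p={p}, s={s})"
        )
    mh_len = max(0, p + s - n)
    mh_seq = seq[n - s : p] if mh_len else ""
    insertion = seq[p : n - s] if p + s < n else ""
    del_left_min = len(construct.left_arm) - p
    del_right_min = len(construct.right_arm) - s
    d = Decomposition(
        p=p,
        s=s,
        mh_len=mh_len,
        mh_seq=mh_seq,
        insertion=insertion,
        del_left_min=del_left_min,
        del_left_max=del_left_min + mh_len,
        del_right_min=del_right_min,
        del_right_max=del_right_min + mh_len,
    )
    ptl, ptr, fex = deletion_flags(construct, d)
    return Decomposition(
        **{
            **d.__dict__,
            "past_tsd_left": ptl,
            "past_tsd_right": ptr,
            "flank_exhausted": fex,
        }
    )


def deletion_flags(
    construct: BreakConstruct, d: Decomposition
) -> tuple[bool, bool, bool]:
    """(past_tsd_left, past_tsd_right, flank_exhausted) for a decomposition.

    A deletion is "past the target" when its minimal extent exceeds the
    overhang plus the target-site duplication on that side.  The flank
    is exhausted when the maximal deletion range reaches the outer end
    of a supplied arm, in which case the true deletion may exceed what
    the supplied sequence can represent.
    """
    ptl = d.del_left_min > construct.left_overhang_len + construct.tsd_len
    ptr = d.del_right_min > construct.right_overhang_len + construct.tsd_len
    fex = d.del_left_max >= len(construct.left_arm) or d.del_right_max >= len(
        construct.right_arm
    )
    return ptl, ptr, fex


def _mismatches(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def refine_microhomology(
    construct: BreakConstruct,
    read: JunctionRead,
    max_mismatch: int = 1,
    min_len: int = 6,
    allow_insertions: bool = False,
) -> MicrohomologyCall:
    """Longest junction-spanning microhomology allowing internal mismatches.

    Scans every read span that (a) is reachable with the flanks outside
    it matching the arms exactly, (b) matches one arm's continuation
    exactly over the span, and (c) matches the other arm's corresponding
    positions with at most *max_mismatch* substitutions, none at a
    terminal position.  Only calls of at least ``max(min_len, exact+1)``
    upgrade the exact decomposition's microhomology; otherwise the exact
    call (all positions matching both arms) is returned.

    Insertion-bearing junctions are not scanned unless
    *allow_insertions* is set; their microhomology is 0 by definition.
    """
    d = decompose(construct, read)
    seq = read.sequence.upper()
    n = len(seq)
    la = construct.left_arm.upper()
    ra = construct.right_arm.upper()
    exact = MicrohomologyCall(
        length=d.mh_len,
        mismatch_count=0,
        mismatch_offsets=(),
        exact_side="both",
        span=(n - d.s, d.p) if d.mh_len else (d.p, d.p),
    )
    if d.insertion and not allow_insertions:
        return MicrohomologyCall(0, 0, (), "both", (d.p, d.p))

    best: MicrohomologyCall | None = None
    floor = max(min_len, d.mh_len + 1)
    # i: span start, j: span end on the read.
    for i in range(0, d.p + 1):
        right_len = n - i  # read[i:] aligned to a right-arm suffix
        if right_len > len(ra):
            continue
        for j in range(i + floor, n + 1):
            if j > len(la):
                break
            if n - j > d.s:
                continue
            length = j - i
            mh_read = seq[i:j]
            left_ref = la[i:j]
            right_ref = ra[len(ra) - right_len : len(ra) - right_len + length]
            ml = _mismatches(mh_read, left_ref)
            mr = _mismatches(mh_read, right_ref)
            for side, mism in (("left", mr), ("right", ml)):
                other = ml if side == "left" else mr
                if other:  # the named side must match exactly
                    continue
                if len(mism) > max_mismatch:
                    continue
                if mism and (mism[0] == 0 or mism[-1] == length - 1):
                    continue
                cand = MicrohomologyCall(
                    length=length,
                    mismatch_count=len(mism),
                    mismatch_offsets=tuple(mism),
                    exact_side="both" if not mism else side,
                    span=(i, j),
                )
                if best is None or _better(cand, best):
                    best = cand
    return best if best is not None else exact


_SIDE_ORDER = {"both": 0, "left": 1, "right": 2}


def _better(a: MicrohomologyCall, b: MicrohomologyCall) -> bool:
    """Tie-break: longer, then fewer mismatches, then left before right."""
    ka = (-a.length, a.mismatch_count, _SIDE_ORDER[a.exact_side], a.span)
    kb = (-b.length, b.mismatch_count, _SIDE_ORDER[b.exact_side], b.span)
    return ka < kb
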