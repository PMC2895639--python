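"""Template search for junction insertions.

Insertions at alt-EJ repair junctions are frequently copied -- possibly
imperfectly, in either orientation -- from DNA flanking the break
(templated or "T" nucleotides).  This module performs an exhaustive
ungapped scan of an insertion against the construct arms and greedily
segments complex insertions into imperfect-repeat runs, modelling
iterative rounds of synthesis.

A :class:`TemplateHit` is *maximal*: it cannot be extended in either
direction while keeping at most ``max_mismatch`` substitutions, and its
terminal positions always match (a mismatched terminal adds no
template evidence).
"""

from __future__ import annotations

from dataclasses import dataclass

from .break_model import AltEJError, BreakConstruct, reverse_complement

__all__ = [
    "TemplateHit",
    "SegmentDecomposition",
    "find_templates",
    "segment_insertion",
    "templated_fraction",
]

#: extra template source label used for snap-back (insertion-as-template) hits
SNAPBACK_SOURCE = "insertion"

_ARM_ORDER = {"left": 0, "right": 1, SNAPBACK_SOURCE: 2}
_ORI_ORDER = {"direct": 0, "reverse_complement": 1}


@dataclass(frozen=True)
class TemplateHit:
    """Ungapped alignment of part of an insertion to a template source."""

    insertion_span: tuple[int, int]
    source_arm: str  # "left" | "right" | "insertion" (snap-back)
    source_span: tuple[int, int]
    orientation: str  # "direct" | "reverse_complement"
    mismatch_count: int
    length: int


@dataclass(frozen=True)
class UntemplatedRun:
    """A stretch of an insertion with no identified template."""

    insertion_span: tuple[int, int]
    sequence: str


@dataclass(frozen=True)
class SegmentDecomposition:
    """Tiling of an insertion into template hits and untemplated runs."""

    segments: tuple[object, ...]
    templated_fraction: float


def _sort_key(h: TemplateHit):
    return (
        -h.length,
        h.mismatch_count,
        h.insertion_span,
        h.source_span,
        _ARM_ORDER[h.source_arm],
        _ORI_ORDER[h.orientation],
    )


def _window(arm: str, side: str, cap: int) -> tuple[str, int]:
    """Break-proximal search window of an arm; returns (seq, arm offset)."""
    if len(arm) <= cap:
        return arm, 0
    if side == "left":  # break-proximal end of the left arm is its suffix
        return arm[-cap:], len(arm) - cap
    return arm[:cap], 0


def _scan_source(
    insertion: str,
    source: str,
    min_len: int,
    max_mismatch: int,
    rc: bool,
) -> list[tuple[int, int, int, int, int]]:
    """Maximal ungapped diagonal matches of *insertion* against *source*.

    Returns tuples ``(ins_start, ins_end, tgt_start, tgt_end, mismatches)``
    in coordinates of *source* as given (reverse-complemented upstream if
    *rc*).
    """
    target = reverse_complement(source) if rc else source.upper()
    ins = insertion.upper()
    li, lt = len(ins), len(target)
    out = []
    # diagonal d: ins position i aligns to target position i + d
    for d in range(-(li - 1), lt):
        lo = max(0, -d)
        hi = min(li, lt - d)
        if hi - lo < min_len:
            continue
        match = [ins[i] == target[i + d] for i in range(lo, hi)]
        m = len(match)
        # all windows with terminal matches and <= max_mismatch mismatches,
        # keeping only those not contained in a longer qualifying window
        spans = []
        for a in range(m):
            if not match[a]:
                continue
            mism = 0
            b_best = -1
            for b in range(a, m):
                if not match[b]:
                    mism += 1
                    continue
                if mism <= max_mismatch:
                    b_best = b
                else:
                    break
            if b_best - a + 1 >= min_len:
                spans.append((a, b_best))
        for a, b in spans:
            if any(x <= a and b <= y and (x, y) != (a, b) for x, y in spans):
                continue  # contained in a longer window on this diagonal
            i0, i1 = lo + a, lo + b + 1
            mm = sum(1 for i in range(i0, i1) if ins[i] != target[i + d])
            out.append((i0, i1, i0 + d, i1 + d, mm))
    return out


def find_templates(
    insertion: str,
    construct: BreakConstruct,
    min_len: int = 4,
    max_mismatch: int = 1,
    orientations: frozenset[str] = frozenset(
        {"direct", "reverse_complement"}
    ),
    window: int = 100,
    extra_sources: dict[str, str] | None = None,
) -> list[TemplateHit]:
    """All maximal ungapped templates for *insertion* in the flanking arms.

    Arms longer than *window* are clipped to the break-proximal
    *window* nucleotides.  *extra_sources* maps additional source
    labels (e.g. the nascent insertion itself for snap-back search) to
    sequences.  Hits are sorted by length (desc), mismatches (asc),
    then leftmost spans, left arm before right, direct before
    reverse-complement.
    """
    if min_len < 1:
        raise AltEJError("min_len must be >= 1")
    if not insertion:
        return []
    sources: list[tuple[str, str, int]] = []
    for side, arm in (("left", construct.left_arm), ("right", construct.right_arm)):
        seq, off = _window(arm, side, window)
        sources.append((side, seq, off))
    for label, seq in (extra_sources or {}).items():
        if seq:
            sources.append((label, seq, 0))

    hits: list[TemplateHit] = []
    for label, seq, off in sources:
        for ori in ("direct", "reverse_complement"):
            if ori not in orientations:
                continue
            rc = ori == "reverse_complement"
            for i0, i1, t0, t1, mm in _scan_source(
                insertion, seq, min_len, max_mismatch, rc
            ):
                if rc:
                    # map back from revcomp coordinates to the source itself
                    s0, s1 = len(seq) - t1, len(seq) - t0
                else:
                    s0, s1 = t0, t1
                hits.append(
                    TemplateHit(
                        insertion_span=(i0, i1),
                        source_arm=label,
                        source_span=(s0 + off, s1 + off),
                        orientation=ori,
                        mismatch_count=mm,
                        length=i1 - i0,
                    )
                )
    hits.sort(key=_sort_key)
    return hits


def segment_insertion(
    insertion: str,
    construct: BreakConstruct,
    min_len: int = 4,
    max_mismatch: int = 1,
    orientations: frozenset[str] = frozenset(
        {"direct", "reverse_complement"}
    ),
    window: int = 100,
    snapback: bool = True,
) -> SegmentDecomposition:
    """Greedy tiling of an insertion by iterative template hits.

    Repeatedly takes the best remaining hit (by :func:`find_templates`
    ordering) that fits entirely within still-uncovered insertion
    positions; with *snapback* the already-placed insertion prefix is
    also offered as a template source, modelling a synthesis round that
    copies from the nascent strand.  Leftover positions become
    :class:`UntemplatedRun` segments.
    """
    n = len(insertion)
    if n == 0:
        return SegmentDecomposition(segments=(), templated_fraction=0.0)
    covered = [False] * n
    placed: list[TemplateHit] = []
    while True:
        gaps = _uncovered_intervals(covered)
        best: TemplateHit | None = None
        for g0, g1 in gaps:
            if g1 - g0 < min_len:
                continue
            extra = None
            if snapback and g0 > 0:
                extra = {SNAPBACK_SOURCE: insertion[:g0]}
            for h in find_templates(
                insertion[g0:g1],
                construct,
                min_len=min_len,
                max_mismatch=max_mismatch,
                orientations=orientations,
                window=window,
                extra_sources=extra,
            ):
                shifted = TemplateHit(
                    insertion_span=(
                        h.insertion_span[0] + g0,
                        h.insertion_span[1] + g0,
                    ),
                    source_arm=h.source_arm,
                    source_span=h.source_span,
                    orientation=h.orientation,
                    mismatch_count=h.mismatch_count,
                    length=h.length,
                )
                if best is None or _sort_key(shifted) < _sort_key(best):
                    best = shifted
                break  # hits are sorted; only the top hit per gap matters
        if best is None:
            break
        placed.append(best)
        for i in range(*best.insertion_span):
            covered[i] = True

    segments: list[object] = list(placed)
    for g0, g1 in _uncovered_intervals(covered):
        segments.append(
            UntemplatedRun(insertion_span=(g0, g1), sequence=insertion[g0:g1])
        )
    segments.sort(key=lambda s: s.insertion_span)
    frac = sum(h.length for h in placed) / n
    return SegmentDecomposition(
        segments=tuple(segments), templated_fraction=frac
    )


def templated_fraction(seg: SegmentDecomposition) -> float:
    """Templated nucleotides / total nucleotides (0 for an empty insertion)."""
    return seg.templated_fraction


def _uncovered_intervals(covered: list[bool]) -> list[tuple[int, int]]:
    out = []
    i = 0
    n = len(covered)
    while i < n:
        if covered[i]:
            i += 1
            continue
        j = i
        while j < n and not covered[j]:
            j += 1
        out.append((i, j))
        i = j
    return out
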