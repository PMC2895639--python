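"""Unit and property tests for insertion template search and segmentation."""

import random

import pytest

from altej import (
    AltEJError,
    BreakConstruct,
    find_templates,
    reverse_complement,
    segment_insertion,
    templated_fraction,
)
from altej.template_search import SegmentDecomposition, TemplateHit, UntemplatedRun


def brute_force_templates(insertion, construct, min_len, max_mismatch, window=100):
    """Independent exhaustive-scan oracle over all substring pairs."""
    ins = insertion.upper()
    sources = []
    la, ra = construct.left_arm, construct.right_arm
    sources.append(("left", la[-window:] if len(la) > window else la,
                    max(0, len(la) - window)))
    sources.append(("right", ra[:window], 0))
    hits = []
    for arm, seq, off in sources:
        for ori in ("direct", "reverse_complement"):
            target = reverse_complement(seq) if ori == "reverse_complement" else seq.upper()
            # every same-diagonal window with terminal matches and small
            # mismatch count; keep only windows not strictly contained in
            # another qualifying window on the same diagonal
            windows = {}
            for i0 in range(len(ins)):
                for t0 in range(len(target)):
                    d = t0 - i0
                    for length in range(1, min(len(ins) - i0, len(target) - t0) + 1):
                        a, b = ins[i0 : i0 + length], target[t0 : t0 + length]
                        mism = sum(1 for x, y in zip(a, b) if x != y)
                        if mism > max_mismatch:
                            continue
                        if a[0] != b[0] or a[-1] != b[-1]:
                            continue
                        windows.setdefault(d, []).append((i0, i0 + length, mism))
            for d, wins in windows.items():
                for i0, i1, mism in wins:
                    if any(
                        x0 <= i0 and i1 <= x1 and (x0, x1) != (i0, i1)
                        for x0, x1, _ in wins
                    ):
                        continue
                    if i1 - i0 < min_len:
                        continue
                    t0, t1 = i0 + d, i1 + d
                    if ori == "reverse_complement":
                        s0, s1 = len(seq) - t1, len(seq) - t0
                    else:
                        s0, s1 = t0, t1
                    hits.append(
                        TemplateHit(
                            insertion_span=(i0, i1),
                            source_arm=arm,
                            source_span=(s0 + off, s1 + off),
                            orientation=ori,
                            mismatch_count=mism,
                            length=i1 - i0,
                        )
                    )
    return set(hits)


class TestFindTemplates:
    def test_right_arm_direct_hit(self, construct):
        hits = find_templates(
            "GTTA", construct, min_len=4, max_mismatch=0,
            orientations=frozenset({"direct"}),
        )
        assert (
            TemplateHit(
                insertion_span=(0, 4),
                source_arm="right",
                source_span=(3, 7),
                orientation="direct",
                mismatch_count=0,
                length=4,
            )
            in hits
        )

    def test_planted_exact_template(self, construct):
        ins = construct.left_arm[2:8]  # flank substring without a revcomp twin
        top = find_templates(ins, construct, min_len=4, max_mismatch=0)[0]
        assert top.insertion_span == (0, len(ins))
        assert top.mismatch_count == 0
        assert top.orientation == "direct"
        assert (top.source_arm, top.source_span) == ("left", (2, 8))

    def test_no_possible_match(self):
        construct = BreakConstruct(left_arm="AAAATTTT", right_arm="TTTTAAAA")
        assert find_templates("GGGGGG", construct, min_len=4, max_mismatch=1) == []

    def test_min_len_validated(self, construct):
        with pytest.raises(AltEJError):
            find_templates("ACGT", construct, min_len=0)

    def test_matches_exhaustive_oracle_on_random_arms(self):
        rng = random.Random(777)
        for _ in range(150):
            la = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 30)))
            ra = "".join(rng.choice("ACGT") for _ in range(rng.randint(6, 30)))
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            construct = BreakConstruct(left_arm=la, right_arm=ra)
            min_len = rng.choice([3, 4])
            mm = rng.choice([0, 1])
            got = set(find_templates(ins, construct, min_len=min_len, max_mismatch=mm))
            assert got == brute_force_templates(ins, construct, min_len, mm)

    def test_revcomp_hits_verify_literally(self, construct):
        rng = random.Random(123)
        for _ in range(50):
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 12)))
            for h in find_templates(ins, construct, min_len=4, max_mismatch=1):
                arm = construct.left_arm if h.source_arm == "left" else construct.right_arm
                tpl = arm[slice(*h.source_span)]
                if h.orientation == "reverse_complement":
                    tpl = reverse_complement(tpl)
                piece = ins[slice(*h.insertion_span)]
                mism = sum(1 for x, y in zip(piece, tpl.upper()) if x != y)
                assert mism == h.mismatch_count

    def test_coverage_monotone_in_parameters(self, construct):
        """More mismatch budget or a lower length floor never uncovers
        a previously templated position."""
        rng = random.Random(99)
        for _ in range(40):
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 14)))

            def covered(min_len, mm):
                pos = set()
                for h in find_templates(ins, construct, min_len=min_len, max_mismatch=mm):
                    pos.update(range(*h.insertion_span))
                return pos

            assert covered(4, 0) <= covered(4, 1)
            assert covered(4, 1) <= covered(3, 1)


class TestSegmentInsertion:
    def test_empty_insertion(self, construct):
        seg = segment_insertion("", construct)
        assert seg.segments == ()
        assert templated_fraction(seg) == 0.0

    def test_two_planted_arm_substrings(self, construct):
        ins = construct.left_arm[9:15] + construct.right_arm[2:8]
        seg = segment_insertion(ins.upper(), construct, min_len=4, max_mismatch=0,
                                snapback=False)
        assert templated_fraction(seg) == 1.0
        assert len(seg.segments) == 2
        assert all(isinstance(s, TemplateHit) for s in seg.segments)

    def test_complex_insertion_matches_oracle_tiling(self, construct):
        """The 15-nt complex insertion from the published junction tables:
        a single 13-nt one-mismatch reverse-complement template covers all
        but the first two nucleotides."""
        seg = segment_insertion("TCATGAAATATCATA", construct, min_len=4, max_mismatch=1)
        assert seg.templated_fraction == pytest.approx(13 / 15)
        hit = [s for s in seg.segments if isinstance(s, TemplateHit)]
        assert len(hit) == 1
        assert hit[0].insertion_span == (2, 15)
        assert hit[0].orientation == "reverse_complement"
        assert hit[0].source_arm == "right"
        # oracle cross-check: greedy over the brute-force hit enumeration
        assert seg.templated_fraction == pytest.approx(
            greedy_oracle_fraction("TCATGAAATATCATA", construct, 4, 1)
        )

    def test_segments_tile_without_overlap(self, construct):
        rng = random.Random(5)
        for _ in range(50):
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 20)))
            seg = segment_insertion(ins, construct, min_len=3, max_mismatch=1)
            spans = sorted(s.insertion_span for s in seg.segments)
            assert spans[0][0] == 0 and spans[-1][1] == len(ins)
            assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))
            tpl = sum(
                s.length for s in seg.segments if isinstance(s, TemplateHit)
            )
            assert seg.templated_fraction == pytest.approx(tpl / len(ins))

    def test_fraction_monotone_in_min_len(self, construct):
        rng = random.Random(6)
        for _ in range(40):
            ins = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 16)))
            f4 = segment_insertion(ins, construct, min_len=4).templated_fraction
            f3 = segment_insertion(ins, construct, min_len=3).templated_fraction
            assert f3 >= f4


def greedy_oracle_fraction(ins, construct, min_len, max_mismatch):
    """Greedy longest-first tiling driven by the brute-force hit oracle."""
    covered = [False] * len(ins)
    total = 0
    while True:
        best = None
        gaps = []
        i = 0
        while i < len(ins):
            if covered[i]:
                i += 1
                continue
            j = i
            while j < len(ins) and not covered[j]:
                j += 1
            gaps.append((i, j))
            i = j
        for g0, g1 in gaps:
            hits = brute_force_templates(
                ins[g0:g1], construct, min_len, max_mismatch
            )
            # snap-back source: the insertion prefix before the gap
            if g0 > 0:
                prefix = BreakConstruct(left_arm=ins[:g0], right_arm="A")
                for h in brute_force_templates(
                    ins[g0:g1], prefix, min_len, max_mismatch
                ):
                    if h.source_arm == "left":
                        hits.add(h)
            for h in hits:
                if best is None or (-h.length, h.mismatch_count) < (
                    -best.length,
                    best.mismatch_count,
                ):
                    best = TemplateHit(
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
        if best is None:
            return total / len(ins)
        total += best.length
        for i in range(*best.insertion_span):
            covered[i] = True


def test_templated_fraction_arithmetic():
    seg = SegmentDecomposition(
        segments=(
            TemplateHit((0, 6), "left", (0, 6), "direct", 0, 6),
            UntemplatedRun((6, 10), "ACGT"),
        ),
        templated_fraction=0.6,
    )
    assert templated_fraction(seg) == 0.6
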