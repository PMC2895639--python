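"""Junction classification, cohort summaries, and exact contingency tests.

Repair junctions fall into five mutually exclusive classes.  Junctions
with an insertion are split at 3 bp (1-3 bp insertions are typical of
classical NHEJ; >= 4 bp insertions of alt-EJ).  Junctions without an
insertion are classed by their (mismatch-refined) microhomology length:
long microhomologies (>= 5 nt) mark alt-EJ annealing, 1-4 nt
microhomologies and blunt joins mark NHEJ-like outcomes.

Cohort comparisons use the two-sided Fisher's exact test computed by
the point-probability rule: the p-value sums the hypergeometric
probabilities of every same-margin table whose point probability does
not exceed the observed one (within relative tolerance 1 + 1e-7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .break_model import AltEJError, Decomposition, JunctionRead, MicrohomologyCall

__all__ = [
    "CLASS_LABELS",
    "Thresholds",
    "CohortSummary",
    "ContingencyTable",
    "classify",
    "summarize",
    "fisher_exact_two_sided",
    "compare_class",
    "round_half_away",
]

CLASS_LABELS = (
    "long_mh",
    "short_mh",
    "blunt",
    "small_insertion",
    "large_insertion",
)

INSERTION_CLASSES = ("small_insertion", "large_insertion")
MH_CLASSES = ("long_mh", "short_mh")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round *x* to *ndigits* decimals, halves away from zero."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Thresholds:
    """Class boundaries: long MH >= long_mh_min, short MH <= short_mh_max,
    small insertion <= small_ins_max nucleotides."""

    long_mh_min: int = 5
    short_mh_max: int = 4
    small_ins_max: int = 3

    def __post_init__(self) -> None:
        if not (1 <= self.short_mh_max < self.long_mh_min):
            raise AltEJError("require 1 <= short_mh_max < long_mh_min")
        if self.small_ins_max < 1:
            raise AltEJError("small_ins_max must be >= 1")


def classify(
    d: Decomposition,
    mh: MicrohomologyCall | None = None,
    t: Thresholds = Thresholds(),
) -> str:
    """Assign one of the five junction classes.

    A non-empty insertion takes precedence; otherwise the refined
    microhomology length (falling back to the exact one) decides.
    """
    if d.insertion:
        return (
            "small_insertion"
            if len(d.insertion) <= t.small_ins_max
            else "large_insertion"
        )
    mh_len = mh.length if mh is not None else d.mh_len
    if mh_len >= t.long_mh_min:
        return "long_mh"
    if mh_len >= 1:
        return "short_mh"
    return "blunt"


@dataclass(frozen=True)
class CohortSummary:
    """Multiplicity-weighted per-genotype class counts and statistics.

    ``mean_insertion_len`` / ``mean_mh_len`` are reported to one
    decimal (half away from zero) over insertion-class / MH-class
    isolates and are ``None`` when the relevant classes are empty.
    ``frac_ins_gt3`` is the fraction of *all* isolates whose insertion
    exceeds three nucleotides.
    """

    genotype: str
    n: int
    class_counts: dict[str, int] = field(default_factory=dict)
    class_fractions: dict[str, float] = field(default_factory=dict)
    mean_insertion_len: float | None = None
    mean_mh_len: float | None = None
    frac_ins_gt3: float = 0.0


def summarize(
    cohort: list[tuple[JunctionRead, Decomposition, MicrohomologyCall | None]],
    t: Thresholds = Thresholds(),
    extra_classes: list[tuple[str, int]] | None = None,
) -> CohortSummary:
    """Aggregate a classified cohort into a :class:`CohortSummary`.

    *extra_classes* adds (class_label, multiplicity) pairs for isolates
    whose class is known by annotation but whose sequence cannot be
    decomposed (e.g. junctions whose deletion runs past the supplied
    flank); these contribute to counts and fractions only.
    """
    genotypes = {r.genotype for r, _, _ in cohort}
    if len(genotypes) > 1:
        raise AltEJError(f"cohort mixes genotypes: {sorted(genotypes)}")
    genotype = genotypes.pop() if genotypes else ""

    counts = {c: 0 for c in CLASS_LABELS}
    ins_sum = ins_n = mh_sum = mh_n = gt3 = 0
    for read, d, mh in cohort:
        cls = classify(d, mh, t)
        w = read.multiplicity
        counts[cls] += w
        if cls in INSERTION_CLASSES:
            ins_sum += len(d.insertion) * w
            ins_n += w
            if len(d.insertion) > 3:
                gt3 += w
        elif cls in MH_CLASSES:
            mh_len = mh.length if mh is not None else d.mh_len
            mh_sum += mh_len * w
            mh_n += w
    for cls, w in extra_classes or []:
        if cls not in counts:
            raise AltEJError(f"unknown class label {cls!r}")
        counts[cls] += w
    n = sum(counts.values())
    return CohortSummary(
        genotype=genotype,
        n=n,
        class_counts=counts,
        class_fractions={c: (counts[c] / n if n else 0.0) for c in counts},
        mean_insertion_len=(
            round_half_away(ins_sum / ins_n, 1) if ins_n else None
        ),
        mean_mh_len=round_half_away(mh_sum / mh_n, 1) if mh_n else None,
        frac_ins_gt3=gt3 / n if n else 0.0,
    )


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table of non-negative counts (rows: cohorts; cols: class)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise AltEJError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise AltEJError("contingency table is all zero")


def fisher_exact_two_sided(tbl: ContingencyTable) -> float:
    """Two-sided Fisher's exact p-value by the point-probability rule.

    Exact integer arithmetic over the hypergeometric support; a table
    contributes when its point probability is at most the observed
    one times (1 + 1e-7).
    """
    a, b, c, d = tbl.a, tbl.b, tbl.c, tbl.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    # point probability of table with first cell k, common denominator C(n, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    obs = weights[a - lo]
    denom = sum(weights)
    # w <= obs * (1 + 1e-7), in exact integer form: w * 10**7 <= obs * (10**7 + 1)
    num = sum(w for w in weights if w * 10**7 <= obs * (10**7 + 1))
    return num / denom


def compare_class(
    a: CohortSummary, b: CohortSummary, cls: str
) -> tuple[ContingencyTable, float]:
    """2x2 (cohort x in-class/out-of-class) table and its two-sided p."""
    if a.n == 0 or b.n == 0:
        raise AltEJError("cannot compare an empty cohort")
    if cls not in CLASS_LABELS:
        raise AltEJError(f"unknown class label {cls!r}")
    ka = a.class_counts.get(cls, 0)
    kb = b.class_counts.get(cls, 0)
    tbl = ContingencyTable(ka, a.n - ka, kb, b.n - kb)
    return tbl, fisher_exact_two_sided(tbl)
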