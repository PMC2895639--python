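"""Mechanistic alt-EJ junction simulator.

Generates synthetic repair-product reads for a break construct under a
simple generative model of alternative end joining: each broken end is
resected by a geometric number of nucleotides; the ends then either
anneal at a pre-existing microhomology exposed by unwinding (long,
>= 5 nt, or short, 1-4 nt), join bluntly, or acquire an insertion
synthesised in iterative rounds of 3-8 nt template copying (direct or
reverse-complement, from either arm's break-proximal window or from the
nascent insertion itself -- snap-back) before joining.  Every junction
carries a ground-truth class label and a trace whose replay
reconstructs the read byte-identically, so the decomposition and
classification stages can be validated end to end without any external
data.

Annealing and blunt outcomes are sampled from a precomputed catalog of
all left-prefix/right-suffix joins of the construct, bucketed by their
decomposed-and-refined class and weighted by the geometric resection
probabilities: the generative label and the classifier label then agree
by construction.  Insertion boundary bases are resampled to differ from
the arm continuations, because a boundary base equal to the arm
continuation is, by definition, retained flank rather than insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .break_model import (
    AltEJError,
    BreakConstruct,
    JunctionRead,
    decompose,
    refine_microhomology,
    reverse_complement,
)
from .classify_stats import Thresholds, classify

__all__ = [
    "PATHWAYS",
    "SimParams",
    "SimulatedJunction",
    "GenotypePreset",
    "preset",
    "PRESET_NAMES",
    "sample_resection",
    "synthesize_insertion",
    "simulate_junction",
    "simulate_cohort",
    "replay_trace",
    "estimate_pathway_weights",
]

PATHWAYS = (
    "long_mh_anneal",
    "short_mh_anneal",
    "blunt",
    "templated_insertion",
    "untemplated_insertion",
)

_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Generative-model parameters.

    ``pathway_weights`` need not be normalised.  ``resection_geom_p``
    is the per-end geometric parameter for extra nucleotides lost
    (support 0, 1, 2, ...); ``rounds_geom_p`` likewise for synthesis
    rounds beyond the first.  ``run_len_min/max`` bound the
    nucleotides copied per synthesis round; ``unwind_window`` is the
    break-proximal flank (nt) exposed for microhomology search and
    template choice.
    """

    pathway_weights: dict[str, float] = field(
        default_factory=lambda: {
            "long_mh_anneal": 0.30,
            "short_mh_anneal": 0.40,
            "blunt": 0.02,
            "templated_insertion": 0.14,
            "untemplated_insertion": 0.14,
        }
    )
    resection_geom_p: float = 0.25
    unwind_window: int = 25
    run_len_min: int = 3
    run_len_max: int = 8
    rounds_geom_p: float = 0.7
    error_rate: float = 0.02
    revcomp_prob: float = 0.5
    snapback_prob: float = 0.15
    label: str = "sim"

    def __post_init__(self) -> None:
        unknown = set(self.pathway_weights) - set(PATHWAYS)
        if unknown:
            raise AltEJError(f"unknown pathway(s): {sorted(unknown)}")
        if not any(w > 0 for w in self.pathway_weights.values()):
            raise AltEJError("pathway weights must not all be zero")
        if any(w < 0 for w in self.pathway_weights.values()):
            raise AltEJError("pathway weights must be non-negative")
        if not (1 <= self.run_len_min <= self.run_len_max):
            raise AltEJError("require 1 <= run_len_min <= run_len_max")
        for name in ("resection_geom_p", "rounds_geom_p"):
            if not (0 < getattr(self, name) <= 1):
                raise AltEJError(f"{name} must be in (0, 1]")
        for name in ("error_rate", "revcomp_prob", "snapback_prob"):
            if not (0 <= getattr(self, name) <= 1):
                raise AltEJError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedJunction:
    """A simulated read with its generative class label and trace."""

    read: JunctionRead
    true_class: str
    trace: dict


@dataclass(frozen=True)
class GenotypePreset:
    name: str
    params: SimParams


def _presets() -> dict[str, SimParams]:
    # Pathway weights follow the published cohort spectra: the baseline
    # alt-EJ spectrum for wildtype/spnA, loss of long-MH annealing for the
    # D5 separation-of-function combination (complex insertions retained,
    # with more synthesis rounds), and loss of both alt-EJ functions for D2.
    wt = SimParams(label="wildtype")
    return {
        "wildtype": wt,
        "spnA": replace(wt, label="spnA"),
        "mus308_D5": SimParams(
            pathway_weights={
                "long_mh_anneal": 0.0,
                "short_mh_anneal": 0.43,
                "blunt": 0.04,
                "templated_insertion": 0.44,
                "untemplated_insertion": 0.09,
            },
            rounds_geom_p=0.35,
            label="mus308_D5",
        ),
        "mus308_D2": SimParams(
            pathway_weights={
                "long_mh_anneal": 0.0,
                "short_mh_anneal": 0.50,
                "blunt": 0.08,
                "templated_insertion": 0.005,
                "untemplated_insertion": 0.415,
            },
            label="mus308_D2",
        ),
    }


PRESET_NAMES = tuple(_presets())


def preset(name: str) -> SimParams:
    """Genotype preset parameters (wildtype, spnA, mus308_D5, mus308_D2)."""
    try:
        return _presets()[name]
    except KeyError:
        raise AltEJError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}"
        ) from None


def sample_resection(rng: np.random.Generator, p: float) -> int:
    """Geometric draw of extra nucleotides resected (support 0, 1, 2, ...)."""
    if not (0 < p <= 1):
        raise AltEJError("resection parameter must be in (0, 1]")
    return int(rng.geometric(p)) - 1


@lru_cache(maxsize=8)
def _junction_catalog(
    construct: BreakConstruct, unwind_window: int, thresholds: Thresholds
) -> dict[str, list[tuple[int, int, str]]]:
    """All (left prefix end p, right suffix start q) joins, bucketed by the
    class their decomposition-plus-refinement receives."""
    la, ra = construct.left_arm, construct.right_arm
    buckets: dict[str, list[tuple[int, int, str]]] = {
        "long_mh": [],
        "short_mh": [],
        "blunt": [],
    }
    for p in range(max(1, len(la) - unwind_window), len(la) + 1):
        for q in range(0, min(unwind_window, len(ra) - 1) + 1):
            seq = la[:p] + ra[q:]
            read = JunctionRead(read_id="cand", sequence=seq)
            try:
                d = decompose(construct, read)
            except AltEJError:
                continue
            if d.insertion:
                continue
            mh = refine_microhomology(construct, read)
            buckets[classify(d, mh, thresholds)].append((p, q, seq))
    return buckets


_CLASS_FOR_PATHWAY = {
    "long_mh_anneal": "long_mh",
    "short_mh_anneal": "short_mh",
    "blunt": "blunt",
}
_FALLBACK = {"long_mh": "short_mh", "short_mh": "blunt"}


def _sample_join(
    rng: np.random.Generator,
    construct: BreakConstruct,
    params: SimParams,
    cls: str,
) -> tuple[str, tuple[int, int, str]]:
    buckets = _junction_catalog(construct, params.unwind_window, Thresholds())
    while cls not in buckets or not buckets[cls]:
        if cls not in _FALLBACK:
            raise AltEJError("no blunt join candidate exists")  # unreachable
        cls = _FALLBACK[cls]
    cands = buckets[cls]
    g = params.resection_geom_p
    la_len = len(construct.left_arm)
    w = np.array(
        [(1 - g) ** (la_len - p) * (1 - g) ** q for p, q, _ in cands], dtype=float
    )
    if w.sum() == 0:  # g == 1 with only resected candidates
        w = np.ones(len(cands))
    idx = int(rng.choice(len(cands), p=w / w.sum()))
    return cls, cands[idx]


def synthesize_insertion(
    rng: np.random.Generator, construct: BreakConstruct, params: SimParams
) -> tuple[str, list[dict]]:
    """Iterative templated synthesis of an insertion.

    Each round copies ``run_len`` nucleotides from a uniform position
    in the break-proximal window of either arm (or from the nascent
    insertion, with probability ``snapback_prob``), in direct or
    reverse-complement orientation, misincorporating each base with
    probability ``error_rate``.  Returns the insertion and the
    per-round trace.
    """
    rounds = int(rng.geometric(params.rounds_geom_p))  # >= 1
    la, ra = construct.left_arm, construct.right_arm
    win = params.unwind_window
    nascent = ""
    trace: list[dict] = []
    for _ in range(rounds):
        if nascent and rng.random() < params.snapback_prob:
            source_name, source, off = "snapback", nascent, 0
        elif rng.random() < 0.5:
            w = min(win, len(la))
            source_name, source, off = "left", la[-w:], len(la) - w
        else:
            w = min(win, len(ra))
            source_name, source, off = "right", ra[:w], 0
        run_len = int(rng.integers(params.run_len_min, params.run_len_max + 1))
        run_len = min(run_len, len(source))
        start = int(rng.integers(0, len(source) - run_len + 1))
        segment = source[start : start + run_len].upper()
        rc = bool(rng.random() < params.revcomp_prob)
        if rc:
            segment = reverse_complement(segment)
        errors: list[list] = []
        out = list(segment)
        for i in range(len(out)):
            if rng.random() < params.error_rate:
                base = _BASES[int(rng.integers(0, 3))]
                if base == out[i]:  # pick among the three other bases
                    base = _BASES[3]
                out[i] = base
                errors.append([i, base])
        trace.append(
            {
                "source": source_name,
                "start": off + start,
                "end": off + start + run_len,
                "orientation": "reverse_complement" if rc else "direct",
                "errors": errors,
            }
        )
        nascent += "".join(out)
    return nascent, trace


def _untemplated(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[int(i)] for i in rng.integers(0, 4, size=length))


def _boundary_ok(
    construct: BreakConstruct, p0: int, q0: int, ins: str
) -> bool:
    """True when the insertion's boundary bases cannot be absorbed into
    the retained arms by maximal-retention decomposition."""
    la, ra = construct.left_arm.upper(), construct.right_arm.upper()
    if p0 < len(la) and ins[0].upper() == la[p0]:
        return False
    if q0 > 0 and ins[-1].upper() == ra[q0 - 1]:
        return False
    return True


def simulate_junction(
    rng: np.random.Generator,
    construct: BreakConstruct,
    params: SimParams,
    read_id: str = "sim",
    thresholds: Thresholds = Thresholds(),
) -> SimulatedJunction:
    """Draw one junction: pathway, resection, annealing or synthesis."""
    names = [pw for pw in PATHWAYS if params.pathway_weights.get(pw, 0) > 0]
    w = np.array([params.pathway_weights[pw] for pw in names], dtype=float)
    pathway = names[int(rng.choice(len(names), p=w / w.sum()))]

    if pathway in _CLASS_FOR_PATHWAY:
        want = _CLASS_FOR_PATHWAY[pathway]
        got, (p, q, seq) = _sample_join(rng, construct, params, want)
        trace = {
            "pathway": pathway,
            "p": p,
            "q": q,
            "fallback": got != want,
        }
        true_class = got
    else:
        la_len = len(construct.left_arm)
        ra_len = len(construct.right_arm)
        rl = min(sample_resection(rng, params.resection_geom_p), la_len - 1)
        rr = min(sample_resection(rng, params.resection_geom_p), ra_len - 1)
        p0, q0 = la_len - rl, rr
        for attempt in range(100):
            if pathway == "templated_insertion":
                ins, rounds = synthesize_insertion(rng, construct, params)
            else:
                ins, rounds = _untemplated(rng, int(rng.integers(1, 4))), []
            if _boundary_ok(construct, p0, q0, ins):
                break
        else:
            raise AltEJError("could not draw an unambiguous insertion boundary")
        seq = construct.left_arm[:p0] + ins + construct.right_arm[q0:]
        trace = {
            "pathway": pathway,
            "p": p0,
            "q": q0,
            "insertion": ins,
            "rounds": rounds,
            "resamples": attempt,
        }
        true_class = (
            "small_insertion"
            if len(ins) <= thresholds.small_ins_max
            else "large_insertion"
        )
    read = JunctionRead(
        read_id=read_id, sequence=seq, genotype=params.label, multiplicity=1
    )
    return SimulatedJunction(read=read, true_class=true_class, trace=trace)


def simulate_cohort(
    construct: BreakConstruct,
    params: SimParams,
    n: int,
    seed: int,
) -> list[SimulatedJunction]:
    """*n* independent junctions; deterministic for a fixed seed."""
    if n < 0:
        raise AltEJError("n must be >= 0")
    rng = np.random.default_rng(seed)
    return [
        simulate_junction(rng, construct, params, read_id=f"sim_{i + 1:05d}")
        for i in range(n)
    ]


def replay_trace(construct: BreakConstruct, trace: dict) -> str:
    """Reconstruct a simulated read from its trace."""
    la, ra = construct.left_arm, construct.right_arm
    p, q = trace["p"], trace["q"]
    if trace["pathway"] in _CLASS_FOR_PATHWAY:
        return la[:p] + ra[q:]
    if trace["rounds"]:
        nascent = ""
        for rnd in trace["rounds"]:
            source = {"left": la, "right": ra, "snapback": nascent}[rnd["source"]]
            segment = source[rnd["start"] : rnd["end"]].upper()
            if rnd["orientation"] == "reverse_complement":
                segment = reverse_complement(segment)
            out = list(segment)
            for i, base in rnd["errors"]:
                out[i] = base
            nascent += "".join(out)
        ins = nascent
    else:
        ins = trace["insertion"]
    return la[:p] + ins + ra[q:]


def estimate_pathway_weights(labels: list[str]) -> dict[str, float]:
    """Estimate pathway weights from classified junction labels.

    The two insertion pathways are not identifiable from class labels
    alone, so their pooled weight is reported under ``insertion``.
    """
    n = len(labels)
    if n == 0:
        return {}
    freq = {cls: labels.count(cls) / n for cls in set(labels)}
    return {
        "long_mh_anneal": freq.get("long_mh", 0.0),
        "short_mh_anneal": freq.get("short_mh", 0.0),
        "blunt": freq.get("blunt", 0.0),
        "insertion": freq.get("small_insertion", 0.0)
        + freq.get("large_insertion", 0.0),
    }
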