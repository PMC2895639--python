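"""Readers, writers, and packaged junction-table fixtures.

The package ships the three published junction tables (one per
genotype cohort) as plain TSV fixtures, plus the break-construct
definition, so the whole analysis is reproducible offline.  Reads can
also be supplied as FASTA (multiplicity via a ``mult=N`` header tag)
or as a junction TSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .break_model import (
    AltEJError,
    BreakConstruct,
    Decomposition,
    JunctionRead,
    MicrohomologyCall,
    decompose,
    refine_microhomology,
)
from .classify_stats import CohortSummary, Thresholds, classify, summarize
from .template_search import segment_insertion

__all__ = [
    "FixtureRow",
    "load_fixture",
    "fixture_to_reads",
    "load_construct",
    "pwa_construct",
    "read_fasta",
    "write_fasta",
    "read_junction_tsv",
    "write_decomposition_table",
    "analyze_reads",
    "analyze_fixture_cohort",
]

logger = logging.getLogger("altej")

FIXTURE_IDS = ("table1", "table2", "table3")

DECOMPOSITION_COLUMNS = [
    "read_id",
    "genotype",
    "p",
    "s",
    "mh_len",
    "mh_seq",
    "mh_mismatches",
    "insertion",
    "ins_len",
    "del_left_min",
    "del_left_max",
    "del_right_min",
    "del_right_max",
    "past_tsd_left",
    "past_tsd_right",
    "class",
    "templated_fraction",
]


@dataclass(frozen=True)
class FixtureRow:
    """One verbatim row of a published junction table.

    ``field_mid`` keeps the original notation: parentheses mark a
    microhomology, a bare string an insertion, ``-`` a blunt join.
    Rows whose flank field reads ``none`` are not reconstructable (the
    deletion runs past the supplied sequence); their class is carried
    by annotation only.
    """

    table_id: str
    row_id: str
    genotype: str
    paper_class: str
    field_5prime: str
    field_mid: str
    field_3prime: str
    n_isolates: int
    footnote_flags: frozenset[str] = frozenset()

    @property
    def reconstructable(self) -> bool:
        return self.field_5prime not in ("none", "-") and self.field_3prime not in (
            "none",
            "-",
        )

    @property
    def is_mh(self) -> bool:
        return self.field_mid.startswith("(")

    @property
    def mid_sequence(self) -> str:
        """The middle field with notation stripped ('' for blunt)."""
        mid = self.field_mid.strip("()")
        return "" if mid == "-" else mid

    @property
    def sequence(self) -> str:
        if not self.reconstructable:
            raise AltEJError(f"{self.table_id}/{self.row_id} is not reconstructable")
        return self.field_5prime + self.mid_sequence + self.field_3prime


def _data_path(name: str):
    return resources.files("altej.data").joinpath(name)


def load_fixture(table_id: str) -> list[FixtureRow]:
    """Load one of the packaged junction tables (``table1``..``table3``)."""
    if table_id not in FIXTURE_IDS:
        raise AltEJError(f"unknown fixture table {table_id!r}")
    rows = []
    with _data_path(f"{table_id}.tsv").open() as fh:
        for rec in csv.DictReader(fh, delimiter="\t"):
            flags = rec["footnote_flags"]
            rows.append(
                FixtureRow(
                    table_id=rec["table_id"],
                    row_id=rec["row_id"],
                    genotype=rec["genotype"],
                    paper_class=rec["paper_class"],
                    field_5prime=rec["field_5prime"],
                    field_mid=rec["field_mid"],
                    field_3prime=rec["field_3prime"],
                    n_isolates=int(rec["n_isolates"]),
                    footnote_flags=frozenset(
                        [] if flags == "-" else flags.split(",")
                    ),
                )
            )
    return rows


def fixture_to_reads(
    rows: Iterable[FixtureRow], expand: bool = True
) -> list[JunctionRead]:
    """Reconstruct junction reads from fixture rows.

    Non-reconstructable rows are skipped with a logged warning.  With
    *expand* each isolate becomes its own read of multiplicity 1;
    otherwise one read per row carries the isolate count.
    """
    reads = []
    for row in rows:
        if not row.reconstructable:
            logger.warning(
                "skipping non-reconstructable row %s/%s (flank past supplied arm)",
                row.table_id,
                row.row_id,
            )
            continue
        base = f"{row.table_id}_{row.row_id}"
        if expand:
            reads.extend(
                JunctionRead(
                    read_id=f"{base}_{i + 1:02d}",
                    sequence=row.sequence,
                    genotype=row.genotype,
                    multiplicity=1,
                )
                for i in range(row.n_isolates)
            )
        else:
            reads.append(
                JunctionRead(
                    read_id=base,
                    sequence=row.sequence,
                    genotype=row.genotype,
                    multiplicity=row.n_isolates,
                )
            )
    return reads


def load_construct(path: str | Path | None = None) -> BreakConstruct:
    """Load a break construct from a flat ``key = value`` text file.

    With no *path*, returns the packaged P-element excision construct.
    """
    if path is None:
        fh = _data_path("pwa_construct.cfg").open()
    else:
        fh = open(path)
    fields: dict[str, str] = {}
    with fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise AltEJError(f"construct config line {lineno}: expected key = value")
            key, _, value = line.partition("=")
            fields[key.strip()] = value.strip()
    try:
        return BreakConstruct(
            name=fields.get("name", "construct"),
            left_arm=fields["left_arm"],
            right_arm=fields["right_arm"],
            left_overhang_len=int(fields.get("left_overhang_len", 0)),
            right_overhang_len=int(fields.get("right_overhang_len", 0)),
            tsd_len=int(fields.get("tsd_len", 0)),
        )
    except KeyError as exc:
        raise AltEJError(f"construct config missing field {exc}") from exc


def pwa_construct() -> BreakConstruct:
    """The packaged P-element excision construct."""
    return load_construct(None)


@dataclass(frozen=True)
class RunConfig:
    """A whole-run configuration: construct, thresholds, search and
    simulator parameters, output directory, and seed."""

    construct: BreakConstruct
    thresholds: Thresholds
    template_min_len: int
    template_max_mismatch: int
    sim_params: "object"
    out_dir: Path
    seed: int | None
    verbosity: str


def load_run_config(path: str | Path) -> RunConfig:
    """Load a structured (YAML) run configuration.

    Keys: ``construct`` (path to a flat construct config; omitted for
    the packaged one), ``thresholds`` (long_mh_min/short_mh_max/
    small_ins_max), ``template_search`` (min_len/max_mismatch),
    ``simulate`` (preset name or SimParams fields), ``out_dir``,
    ``seed``, ``verbosity``.  Referenced paths must exist.
    """
    from .simulate_junctions import SimParams, preset

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    construct_path = raw.get("construct")
    if construct_path is not None and not Path(construct_path).exists():
        raise AltEJError(f"construct path does not exist: {construct_path}")
    thr = raw.get("thresholds") or {}
    sim = raw.get("simulate") or {}
    if isinstance(sim, str):
        sim_params = preset(sim)
    else:
        sim_params = SimParams(**sim) if sim else SimParams()
    return RunConfig(
        construct=load_construct(construct_path),
        thresholds=Thresholds(**thr),
        template_min_len=int((raw.get("template_search") or {}).get("min_len", 4)),
        template_max_mismatch=int(
            (raw.get("template_search") or {}).get("max_mismatch", 1)
        ),
        sim_params=sim_params,
        out_dir=Path(raw.get("out_dir", ".")),
        seed=raw.get("seed"),
        verbosity=str(raw.get("verbosity", "warning")),
    )


def read_fasta(path: str | Path, genotype: str = "") -> list[JunctionRead]:
    """Read junction reads from FASTA; ``mult=N`` in the header sets the
    isolate multiplicity (default 1)."""
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        mult = 1
        for token in rec.description.split():
            if token.startswith("mult="):
                try:
                    mult = int(token[5:])
                except ValueError as exc:
                    raise AltEJError(
                        f"bad multiplicity tag {token!r} in record {rec.id}"
                    ) from exc
        reads.append(
            JunctionRead(
                read_id=rec.id,
                sequence=str(rec.seq),
                genotype=genotype,
                multiplicity=mult,
            )
        )
    return reads


def write_fasta(path: str | Path, reads: Iterable[JunctionRead]) -> None:
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.read_id,
            description=f"mult={r.multiplicity}",
        )
        for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def read_junction_tsv(path: str | Path) -> list[JunctionRead]:
    """Read a junction TSV: read_id, genotype, sequence, multiplicity."""
    reads = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, rec in enumerate(reader, 2):
            try:
                reads.append(
                    JunctionRead(
                        read_id=rec["read_id"],
                        genotype=rec.get("genotype") or "",
                        sequence=rec["sequence"],
                        multiplicity=int(rec.get("multiplicity") or 1),
                    )
                )
            except (KeyError, TypeError, ValueError, AltEJError) as exc:
                raise AltEJError(f"{path}: malformed record at line {lineno}: {exc}")
    return reads


@dataclass(frozen=True)
class AnalyzedRead:
    """A read with its decomposition, refined MH call, and class."""

    read: JunctionRead
    decomposition: Decomposition
    mh_call: MicrohomologyCall
    label: str
    templated_fraction: float | None = None


def analyze_reads(
    construct: BreakConstruct,
    reads: Iterable[JunctionRead],
    thresholds: Thresholds = Thresholds(),
    max_mismatch: int = 1,
    min_imperfect_len: int = 6,
    with_templates: bool = False,
) -> list[AnalyzedRead]:
    """Decompose, refine, and classify each read against *construct*."""
    out = []
    for read in reads:
        d = decompose(construct, read)
        mh = refine_microhomology(
            construct, read, max_mismatch=max_mismatch, min_len=min_imperfect_len
        )
        frac = None
        if with_templates and d.insertion:
            frac = segment_insertion(d.insertion, construct).templated_fraction
        out.append(
            AnalyzedRead(
                read=read,
                decomposition=d,
                mh_call=mh,
                label=classify(d, mh, thresholds),
                templated_fraction=frac,
            )
        )
    return out


def analyze_fixture_cohort(
    table_id: str,
    construct: BreakConstruct | None = None,
    thresholds: Thresholds = Thresholds(),
    classify_by: str = "pipeline",
) -> CohortSummary:
    """Decompose and summarize one packaged cohort.

    ``classify_by="pipeline"`` recomputes every reconstructable row's
    class from its sequence (non-reconstructable rows contribute their
    annotated class); ``"paper"`` counts all rows by the annotated
    class labels instead.
    """
    rows = load_fixture(table_id)
    if classify_by == "paper":
        genotype = rows[0].genotype if rows else ""
        counts = [(r.paper_class, r.n_isolates) for r in rows]
        return _with_genotype(
            summarize([], t=thresholds, extra_classes=counts), genotype
        )
    if classify_by != "pipeline":
        raise AltEJError("classify_by must be 'pipeline' or 'paper'")
    construct = construct or pwa_construct()
    reads = fixture_to_reads(rows, expand=False)
    analyzed = analyze_reads(construct, reads, thresholds=thresholds)
    extra = [
        (r.paper_class, r.n_isolates) for r in rows if not r.reconstructable
    ]
    cohort = [(a.read, a.decomposition, a.mh_call) for a in analyzed]
    return summarize(cohort, t=thresholds, extra_classes=extra)


def _with_genotype(summary: CohortSummary, genotype: str) -> CohortSummary:
    return CohortSummary(
        genotype=genotype,
        n=summary.n,
        class_counts=summary.class_counts,
        class_fractions=summary.class_fractions,
        mean_insertion_len=summary.mean_insertion_len,
        mean_mh_len=summary.mean_mh_len,
        frac_ins_gt3=summary.frac_ins_gt3,
    )


def decomposition_rows(
    analyzed: Iterable[AnalyzedRead],
) -> list[dict[str, object]]:
    """Flatten analyzed reads into decomposition-table records."""
    rows = []
    for a in analyzed:
        d = a.decomposition
        rows.append(
            {
                "read_id": a.read.read_id,
                "genotype": a.read.genotype,
                "p": d.p,
                "s": d.s,
                "mh_len": a.mh_call.length,
                "mh_seq": a.read.sequence[slice(*a.mh_call.span)].upper(),
                "mh_mismatches": a.mh_call.mismatch_count,
                "insertion": d.insertion.upper(),
                "ins_len": len(d.insertion),
                "del_left_min": d.del_left_min,
                "del_left_max": d.del_left_max,
                "del_right_min": d.del_right_min,
                "del_right_max": d.del_right_max,
                "past_tsd_left": str(d.past_tsd_left).lower(),
                "past_tsd_right": str(d.past_tsd_right).lower(),
                "class": a.label,
                "templated_fraction": (
                    "" if a.templated_fraction is None else f"{a.templated_fraction:.4f}"
                ),
            }
        )
    return rows


def write_decomposition_table(
    path: str | Path, analyzed: Iterable[AnalyzedRead]
) -> None:
    """Write the decomposition TSV (fixed column order, LF line endings)."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=DECOMPOSITION_COLUMNS, delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for rec in decomposition_rows(analyzed):
            writer.writerow(rec)
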