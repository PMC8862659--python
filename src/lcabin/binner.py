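"""Taxonomic and functional binning of tabular protein alignments.

Reads are assigned per classification from their retained alignments:

* **Taxonomy / GTDB** — the naive LCA of the subject taxa for short
  reads, or an interval-union LCA for long reads. The long-read variant
  scores each candidate taxon by the length of the union of the query
  intervals its alignments cover, keeps taxa within ``percent_to_cover``
  percent of the best-covered taxon, and places the read on their LCA,
  so a long read spanning several genes is not dragged to the root by a
  single short off-target alignment.
* **EC / EGGNOG / INTERPRO2GO / KEGG / SEED** — the class of the best
  *mapped* retained alignment (highest bit score; ties broken by the
  lexicographically smallest subject accession).

Retention filters mirror the usual meganization conventions: a minimum
bit score, a maximum e-value, and a top-percent band relative to the
read's best surviving bit score. An optional clade restriction keeps
only alignments whose subject maps inside given taxonomic clades
(e.g. bacteria and archaea).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

from .refdb import CLASSIFICATIONS, MD5_CLASSIFICATIONS, MappingDatabase
from .taxonomy import TaxonomyError, TaxonomyTree

__all__ = [
    "NO_HITS",
    "UNASSIGNED",
    "FUNCTIONAL_CLASSIFICATIONS",
    "AlignmentRecord",
    "ReadAlignments",
    "BinningParams",
    "ReadAssignment",
    "RunResult",
    "RunSummary",
    "BinnerError",
    "parse_alignments_tab",
    "filter_alignments",
    "restrict_to_clades",
    "assign_taxon_naive_lca",
    "assign_taxon_interval_union_lca",
    "taxon_interval_cover",
    "subtree_cover",
    "assign_function_best_hit",
    "bin_run",
    "summarize_run",
    "percent",
    "ratio",
    "write_assignments_tsv",
    "read_assignments_tsv",
]

#: Outcome sentinel: the read had no retained alignments at all.
NO_HITS = "NO_HITS"
#: Outcome sentinel: retained alignments exist but none maps to a class.
UNASSIGNED = "UNASSIGNED"

FUNCTIONAL_CLASSIFICATIONS = ("EC", "EGGNOG", "INTERPRO2GO", "KEGG", "SEED")


class BinnerError(ValueError):
    """Parse or usage error in alignment binning."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One protein alignment of a read (BLAST tabular conventions).

    Query coordinates are 1-based inclusive nucleotide positions on the
    read; ``query_start > query_end`` marks a reverse-frame alignment and
    is normalized for interval arithmetic via :attr:`interval`.
    """

    query_id: str
    subject_accession: str
    percent_identity: float
    align_length: int
    query_start: int
    query_end: int
    evalue: float
    bit_score: float

    @property
    def reverse_frame(self) -> bool:
        return self.query_start > self.query_end

    @property
    def interval(self) -> tuple[int, int]:
        """Query interval normalized so start <= end."""
        if self.reverse_frame:
            return (self.query_end, self.query_start)
        return (self.query_start, self.query_end)


@dataclass
class ReadAlignments:
    """All parsed alignments of one read, in input order."""

    query_id: str
    records: list[AlignmentRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for record in self.records:
            if record.query_id != self.query_id:
                raise BinnerError(
                    f"record query {record.query_id!r} != group {self.query_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class BinningParams:
    """Retention-filter and assignment parameters.

    ``min_bit_score``/``max_evalue`` drop weak alignments outright;
    ``top_percent`` keeps only alignments whose bit score is within that
    percentage of the read's best surviving score. ``percent_to_cover``
    applies in long-read mode only. ``min_support`` pushes taxa with
    fewer assigned reads than the threshold up to their parent at the
    profile level; the default of 1 disables it.
    """

    min_bit_score: float = 50.0
    max_evalue: float = 0.01
    top_percent: float = 10.0
    min_support: int = 1
    long_read_mode: bool = False
    percent_to_cover: float = 80.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.top_percent <= 100.0:
            raise BinnerError("top_percent must lie in [0, 100]")
        if not 0.0 < self.percent_to_cover <= 100.0:
            raise BinnerError("percent_to_cover must lie in (0, 100]")


@dataclass
class ReadAssignment:
    """Per-classification outcome for one read (class id or sentinel)."""

    query_id: str
    outcomes: dict[str, str] = field(default_factory=dict)

    def is_assigned(self, classification: str) -> bool:
        outcome = self.outcomes.get(classification, NO_HITS)
        return outcome not in (NO_HITS, UNASSIGNED)


@dataclass
class RunResult:
    """All per-read assignments of one binning run."""

    total_reads: int
    aligned_reads: int
    assignments: list[ReadAssignment] = field(default_factory=list)

    def assignment_map(self, classification: str) -> dict[str, str]:
        """``query_id -> outcome`` (including sentinels) for one classification."""
        return {
            a.query_id: a.outcomes.get(classification, NO_HITS)
            for a in self.assignments
        }

    def assigned_count(self, classification: str) -> int:
        return sum(a.is_assigned(classification) for a in self.assignments)


@dataclass
class RunSummary:
    """Per-classification assignment counts and rates for one run."""

    total_reads: int
    aligned_reads: int
    assigned: dict[str, int]
    percent_of_reads: dict[str, float]
    percent_of_aligned: dict[str, float]
    aligned_reads_zero: bool = False


# ---------------------------------------------------------------------------
# parsing


@dataclass
class ParsedRun:
    """Grouped alignments plus the run-level read counts."""

    reads: list[ReadAlignments]
    total_reads: int
    aligned_reads: int


def _lines(source: str | Path | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(source, Path):
        with open(source) as handle:
            yield from handle
    elif isinstance(source, str):
        yield from io.StringIO(source)
    else:
        yield from source


def parse_alignments_tab(
    source: str | Path | IO[str] | Iterable[str],
    declared_total_reads: Optional[int] = None,
) -> ParsedRun:
    """Parse 12-column BLAST tabular (outfmt 6) alignments, grouped by read.

    Column order is fixed: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore. Groups preserve first-seen
    read order; ``aligned_reads`` is the number of distinct reads. When
    ``declared_total_reads`` is given it supplies the run's read total
    (reads without any alignment never appear in the file).
    """
    groups: dict[str, ReadAlignments] = {}
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise BinnerError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            record = AlignmentRecord(
                query_id=fields[0],
                subject_accession=fields[1],
                percent_identity=float(fields[2]),
                align_length=int(fields[3]),
                query_start=int(fields[6]),
                query_end=int(fields[7]),
                evalue=float(fields[10]),
                bit_score=float(fields[11]),
            )
        except ValueError as exc:
            raise BinnerError(f"line {lineno}: bad numeric field ({exc})") from None
        groups.setdefault(
            record.query_id, ReadAlignments(record.query_id)
        ).records.append(record)
    aligned = len(groups)
    total = declared_total_reads if declared_total_reads is not None else aligned
    if total < aligned:
        raise BinnerError(
            f"declared_total_reads={total} < {aligned} distinct aligned reads"
        )
    return ParsedRun(reads=list(groups.values()), total_reads=total, aligned_reads=aligned)


# ---------------------------------------------------------------------------
# filters


def filter_alignments(ra: ReadAlignments, params: BinningParams) -> ReadAlignments:
    """Apply the min-score, max-evalue and top-percent retention filters.

    Survivors of the absolute cutoffs are kept when their bit score is at
    least ``(1 - top_percent/100)`` times the best surviving score.
    """
    survivors = [
        r
        for r in ra.records
        if r.bit_score >= params.min_bit_score and r.evalue <= params.max_evalue
    ]
    if not survivors:
        return ReadAlignments(ra.query_id, [])
    best = max(r.bit_score for r in survivors)
    threshold = (1.0 - params.top_percent / 100.0) * best
    kept = [r for r in survivors if r.bit_score >= threshold]
    return ReadAlignments(ra.query_id, kept)


def restrict_to_clades(
    ra: ReadAlignments,
    mapping: MappingDatabase,
    tree: TaxonomyTree,
    clade_roots: set[str],
) -> ReadAlignments:
    """Keep only alignments whose subject taxon falls inside a clade root.

    Subjects without a taxonomy mapping are dropped. Mirrors restricting
    an aligner to, e.g., bacteria (taxon 2) and archaea (taxon 2157).
    """
    for root in clade_roots:
        if root not in tree:
            raise TaxonomyError(f"unknown clade root {root!r}")
    kept = []
    for record in ra.records:
        taxon = mapping.get_class(record.subject_accession, "Taxonomy")
        if taxon is None or taxon not in tree:
            continue
        if any(tree.is_ancestor(root, taxon) for root in clade_roots):
            kept.append(record)
    return ReadAlignments(ra.query_id, kept)


# ---------------------------------------------------------------------------
# taxonomic assignment


def _mapped_taxa(
    ra: ReadAlignments,
    mapping: MappingDatabase,
    tree: TaxonomyTree,
    classification: str,
) -> list[tuple[AlignmentRecord, str]]:
    pairs = []
    for record in ra.records:
        taxon = mapping.get_class(record.subject_accession, classification)
        if taxon is not None and taxon in tree:
            pairs.append((record, taxon))
    return pairs


def assign_taxon_naive_lca(
    ra: ReadAlignments,
    mapping: MappingDatabase,
    tree: TaxonomyTree,
    params: BinningParams,
    classification: str = "Taxonomy",
) -> str:
    """Naive LCA placement: the LCA of all retained subjects' taxa.

    ``ra`` is expected to be filtered already. Returns the taxon id, or
    :data:`NO_HITS` for an empty alignment set, or :data:`UNASSIGNED`
    when no retained subject maps to a taxon.
    """
    if not ra.records:
        return NO_HITS
    taxa = {taxon for _, taxon in _mapped_taxa(ra, mapping, tree, classification)}
    if not taxa:
        return UNASSIGNED
    return tree.lca(taxa)


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals.

    Overlapping or adjacent intervals (gap 0) are merged.
    """
    ordered = sorted(intervals)
    total = 0
    current_start: Optional[int] = None
    current_end = 0
    for start, end in ordered:
        if current_start is None:
            current_start, current_end = start, end
        elif start <= current_end + 1:
            current_end = max(current_end, end)
        else:
            total += current_end - current_start + 1
            current_start, current_end = start, end
    if current_start is not None:
        total += current_end - current_start + 1
    return total


def taxon_interval_cover(
    ra: ReadAlignments,
    mapping: MappingDatabase,
    tree: TaxonomyTree,
    classification: str = "Taxonomy",
) -> dict[str, int]:
    """Per-taxon interval-union cover over the mapped subject taxa.

    For each taxon directly hit by a retained alignment, the cover is the
    length of the union of the query intervals of its alignments.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for record, taxon in _mapped_taxa(ra, mapping, tree, classification):
        intervals.setdefault(taxon, []).append(record.interval)
    return {taxon: _union_length(ivs) for taxon, ivs in intervals.items()}


def subtree_cover(
    ra: ReadAlignments,
    mapping: MappingDatabase,
    tree: TaxonomyTree,
    classification: str = "Taxonomy",
) -> dict[str, int]:
    """Per-node cover: union length of intervals hitting the node's subtree.

    Monotone up the tree — a parent's cover is at least each child's.
    Used for diagnostics and as an oracle surface; the assignment rule
    itself works on :func:`taxon_interval_cover`.
    """
    per_node: dict[str, list[tuple[int, int]]] = {}
    for record, taxon in _mapped_taxa(ra, mapping, tree, classification):
        for ancestor in tree.lineage(taxon):
            per_node.setdefault(ancestor, []).append(record.interval)
    return {node: _union_length(ivs) for node, ivs in per_node.items()}


def assign_taxon_interval_union_lca(
    ra: ReadAlignments,
    mapping: MappingDatabase,
    tree: TaxonomyTree,
    params: BinningParams,
    classification: str = "Taxonomy",
) -> str:
    """Interval-union LCA placement for long reads.

    Each mapped subject taxon is scored by the union length of its query
    intervals; taxa whose cover reaches ``percent_to_cover`` percent of
    the best-covered taxon are retained and the read is placed on their
    LCA. A taxon supported over most of the read therefore wins over one
    supported by a single short segment.
    """
    if not ra.records:
        return NO_HITS
    cover = taxon_interval_cover(ra, mapping, tree, classification)
    if not cover:
        return UNASSIGNED
    best = max(cover.values())
    threshold = (params.percent_to_cover / 100.0) * best
    candidates = {taxon for taxon, c in cover.items() if c >= threshold}
    return tree.lca(candidates)


# ---------------------------------------------------------------------------
# functional assignment


def assign_function_best_hit(
    ra: ReadAlignments,
    mapping: MappingDatabase,
    classification: str,
    params: BinningParams,
) -> str:
    """Best mapped hit: class of the highest-scoring retained alignment
    whose subject carries a class in the classification.

    Ties on bit score go to the lexicographically smallest subject
    accession. Unmapped-but-better hits do not block assignment.
    """
    if not ra.records:
        return NO_HITS
    best: Optional[tuple[float, str, str]] = None
    for record in ra.records:
        class_id = mapping.get_class(record.subject_accession, classification)
        if class_id is None:
            continue
        key = (-record.bit_score, record.subject_accession)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], class_id)
    if best is None:
        return UNASSIGNED
    return best[2]


# ---------------------------------------------------------------------------
# run-level driver


def bin_run(
    alignments: str | Path | IO[str] | Iterable[str] | ParsedRun,
    mapping: MappingDatabase,
    params: BinningParams = BinningParams(),
    ncbi_tree: Optional[TaxonomyTree] = None,
    gtdb_tree: Optional[TaxonomyTree] = None,
    clade_roots: Optional[set[str]] = None,
    declared_total_reads: Optional[int] = None,
) -> RunResult:
    """Bin every read of an alignment file, all classifications at once.

    Applies clade restriction (if requested) then the retention filters,
    then per-read taxon assignment (naive LCA, or interval-union LCA in
    long-read mode) against each supplied tree flavor and best-mapped-hit
    assignment for each functional classification.
    """
    if isinstance(alignments, ParsedRun):
        parsed = alignments
    else:
        parsed = parse_alignments_tab(alignments, declared_total_reads)
    if clade_roots and ncbi_tree is None:
        raise BinnerError("clade restriction requires the NCBI tree")

    assign_taxon = (
        assign_taxon_interval_union_lca
        if params.long_read_mode
        else assign_taxon_naive_lca
    )
    assignments = []
    for ra in parsed.reads:
        working = ra
        if clade_roots:
            working = restrict_to_clades(working, mapping, ncbi_tree, clade_roots)
        working = filter_alignments(working, params)
        outcomes: dict[str, str] = {}
        if ncbi_tree is not None:
            outcomes["Taxonomy"] = assign_taxon(
                working, mapping, ncbi_tree, params, "Taxonomy"
            )
        if gtdb_tree is not None:
            outcomes["GTDB"] = assign_taxon(
                working, mapping, gtdb_tree, params, "GTDB"
            )
        for classification in FUNCTIONAL_CLASSIFICATIONS:
            outcomes[classification] = assign_function_best_hit(
                working, mapping, classification, params
            )
        assignments.append(ReadAssignment(ra.query_id, outcomes))
    return RunResult(
        total_reads=parsed.total_reads,
        aligned_reads=parsed.aligned_reads,
        assignments=assignments,
    )


# ---------------------------------------------------------------------------
# summaries


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded to ``decimals`` places."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, decimals)


def ratio(a: float, b: float, decimals: int = 1) -> float:
    """``a / b`` rounded to ``decimals`` places."""
    if b == 0:
        raise BinnerError("ratio denominator is zero")
    return round(a / b, decimals)


def summarize_run(run: RunResult) -> RunSummary:
    """Per-classification assigned counts, % of all reads and % of aligned reads."""
    classifications = sorted(
        {c for a in run.assignments for c in a.outcomes},
        key=lambda c: CLASSIFICATIONS.index(c) if c in CLASSIFICATIONS else 99,
    )
    assigned = {c: run.assigned_count(c) for c in classifications}
    return RunSummary(
        total_reads=run.total_reads,
        aligned_reads=run.aligned_reads,
        assigned=assigned,
        percent_of_reads={c: percent(n, run.total_reads) for c, n in assigned.items()},
        percent_of_aligned={
            c: percent(n, run.aligned_reads) for c, n in assigned.items()
        },
        aligned_reads_zero=run.aligned_reads == 0,
    )


# ---------------------------------------------------------------------------
# per-read assignment export / import


def write_assignments_tsv(
    run: RunResult,
    sink: str | Path | IO[str],
    trees: Optional[dict[str, TaxonomyTree]] = None,
    paths: bool = False,
) -> None:
    """Write per-read assignments as ``read_id  classification  class_id``.

    With ``paths=True`` taxonomic class ids are written as root-to-node
    paths (taxon ids joined by ``;``) using the matching tree in
    ``trees`` (keyed by classification); other classes are unchanged.
    Sentinel outcomes are written verbatim so the file is self-contained.
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as handle:
            write_assignments_tsv(run, handle, trees, paths)
        return
    sink.write("# total_reads=%d\taligned_reads=%d\n" % (run.total_reads, run.aligned_reads))
    for assignment in run.assignments:
        for classification, outcome in assignment.outcomes.items():
            value = outcome
            if (
                paths
                and outcome not in (NO_HITS, UNASSIGNED)
                and trees is not None
                and classification in trees
            ):
                value = ";".join(trees[classification].lineage(outcome))
            sink.write(f"{assignment.query_id}\t{classification}\t{value}\n")


def read_assignments_tsv(source: str | Path | IO[str] | Iterable[str]) -> RunResult:
    """Read a per-read assignment TSV written by :func:`write_assignments_tsv`."""
    total_reads = aligned_reads = 0
    by_read: dict[str, ReadAssignment] = {}
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split("\t"):
                key, _, value = token.strip().partition("=")
                if key == "total_reads":
                    total_reads = int(value)
                elif key == "aligned_reads":
                    aligned_reads = int(value)
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise BinnerError(f"line {lineno}: expected 3 columns")
        read_id, classification, class_id = fields
        by_read.setdefault(read_id, ReadAssignment(read_id)).outcomes[
            classification
        ] = class_id
    assignments = list(by_read.values())
    if aligned_reads == 0:
        aligned_reads = len(assignments)
    if total_reads == 0:
        total_reads = aligned_reads
    return RunResult(total_reads, aligned_reads, assignments)
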