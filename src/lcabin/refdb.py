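"""Reference FASTA and accession→classification mapping database.

Alignment-based binning needs two artifacts derived from an annotated
genome collection:

1. a protein reference FASTA in which every record is identified by a
   *two-part accession* ``gene_id + "__" + genome_id``, so that the
   genome of origin (and hence its taxonomy) can be recovered from any
   alignment subject; and
2. a single-file mapping database from each accession to at most one
   class per classification (NCBI Taxonomy, GTDB, EC, EGGNOG,
   INTERPRO2GO, KEGG, SEED).

Taxonomic classes come from the genome's taxonomy, KEGG orthologs from
per-gene candidate lists (one chosen deterministically when several are
listed, because a reference sequence may carry at most one class per
classification), and the remaining functional classes are transferred
from an external catalog by joining on the MD5 hash of the protein
sequence — two entries with identical sequences share annotations.
"""

from __future__ import annotations

import hashlib
import logging
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .taxonomy import TaxonomyError, TaxonomyTree, gtdb_deepest_path

logger = logging.getLogger(__name__)

__all__ = [
    "CLASSIFICATIONS",
    "MD5_CLASSIFICATIONS",
    "ProteinRecord",
    "AnnotationTables",
    "CatalogRow",
    "CrossReferenceCatalog",
    "MappingDatabase",
    "RefDbError",
    "make_two_part_accession",
    "parse_two_part_accession",
    "normalize_kegg",
    "select_kegg_class",
    "sequence_md5",
    "transfer_annotations_by_md5",
    "build_mapping_database",
    "write_reference_fasta",
    "read_reference_fasta",
    "save_mapping_store",
    "load_mapping_store",
    "export_mapping_tsv",
    "read_protein_table",
    "read_genome_taxonomy",
    "read_kegg_candidates",
    "read_catalog",
]

#: Classification columns of the mapping database, in storage order.
CLASSIFICATIONS = ("Taxonomy", "GTDB", "EC", "EGGNOG", "INTERPRO2GO", "KEGG", "SEED")

#: Classifications filled by the MD5 hash join against the external catalog.
MD5_CLASSIFICATIONS = ("EC", "EGGNOG", "INTERPRO2GO", "SEED")

_SEPARATOR = "__"
_KEGG_RE = re.compile(r"^K(\d{1,5})$")
_MD5_RE = re.compile(r"^[0-9a-f]{32}$")


class RefDbError(ValueError):
    """Validation or build error in reference-database construction."""


@dataclass(frozen=True)
class ProteinRecord:
    """One reference protein with its genome of origin."""

    gene_id: str
    gtdb_genome_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id or not self.gtdb_genome_id:
            raise RefDbError("gene_id and gtdb_genome_id must be non-empty")
        if not self.sequence:
            raise RefDbError(f"empty sequence for gene {self.gene_id!r}")

    @property
    def accession(self) -> str:
        return make_two_part_accession(self.gene_id, self.gtdb_genome_id)


@dataclass
class AnnotationTables:
    """Per-genome taxonomy and per-gene KEGG candidate lists.

    ``genome_taxonomy`` maps a genome id to ``(ncbi_taxon_id,
    gtdb_rank_string)``; ``kegg_candidates`` maps a gene id to an ordered
    list of KEGG ortholog identifiers (possibly more than one).
    """

    genome_taxonomy: dict[str, tuple[str, str]]
    kegg_candidates: dict[str, list[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class CatalogRow:
    """One external cross-reference: accession, sequence MD5 and classes."""

    external_accession: str
    sequence_md5: str
    classes: Mapping[str, str]

    def __post_init__(self) -> None:
        if not _MD5_RE.match(self.sequence_md5):
            raise RefDbError(
                f"malformed md5 {self.sequence_md5!r} for {self.external_accession!r}"
            )
        bad = set(self.classes) - set(MD5_CLASSIFICATIONS)
        if bad:
            raise RefDbError(f"unsupported catalog classifications: {sorted(bad)}")


CrossReferenceCatalog = list[CatalogRow]


class MappingDatabase:
    """Accession-keyed table with one nullable class per classification.

    Enforces the one-class-per-classification rule: each accession carries
    at most one class id in each of :data:`CLASSIFICATIONS`.
    """

    def __init__(self) -> None:
        self._rows: dict[str, dict[str, str]] = {}

    def add_row(self, accession: str, classes: Mapping[str, Optional[str]]) -> None:
        if accession in self._rows:
            raise RefDbError(f"duplicate accession {accession!r}")
        bad = set(classes) - set(CLASSIFICATIONS)
        if bad:
            raise RefDbError(f"unknown classifications {sorted(bad)}")
        self._rows[accession] = {
            c: v for c, v in classes.items() if v is not None
        }

    def get_class(self, accession: str, classification: str) -> Optional[str]:
        if classification not in CLASSIFICATIONS:
            raise RefDbError(f"unknown classification {classification!r}")
        row = self._rows.get(accession)
        return None if row is None else row.get(classification)

    def __contains__(self, accession: str) -> bool:
        return accession in self._rows

    def __len__(self) -> int:
        return len(self._rows)

    def accessions(self) -> list[str]:
        return sorted(self._rows)

    def rows(self) -> dict[str, dict[str, str]]:
        return {a: dict(r) for a, r in self._rows.items()}

    def counts(self) -> dict[str, int]:
        """Number of accessions mapped in each classification."""
        out = {c: 0 for c in CLASSIFICATIONS}
        for row in self._rows.values():
            for classification in row:
                out[classification] += 1
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MappingDatabase):
            return NotImplemented
        return self._rows == other._rows


# ---------------------------------------------------------------------------
# two-part accessions


def make_two_part_accession(gene_id: str, gtdb_genome_id: str) -> str:
    """Join gene and genome ids with a double underscore.

    Either part containing ``__`` would make the accession ambiguous to
    parse and is rejected.
    """
    for label, part in (("gene_id", gene_id), ("gtdb_genome_id", gtdb_genome_id)):
        if not part:
            raise RefDbError(f"{label} must be non-empty")
        if _SEPARATOR in part:
            raise RefDbError(f"{label} {part!r} contains the separator '__'")
    return gene_id + _SEPARATOR + gtdb_genome_id


def parse_two_part_accession(value: str) -> tuple[str, str]:
    """Split a two-part accession at the first ``__`` occurrence."""
    index = value.find(_SEPARATOR)
    if index < 0:
        raise RefDbError(f"accession {value!r} lacks the '__' separator")
    gene_id, genome_id = value[:index], value[index + len(_SEPARATOR) :]
    if not gene_id or not genome_id:
        raise RefDbError(f"accession {value!r} has an empty part")
    return gene_id, genome_id


# ---------------------------------------------------------------------------
# KEGG selection


def normalize_kegg(identifier: str) -> str:
    """Canonicalize a KEGG ortholog id to ``K#####``.

    Strips an optional ``ko:`` prefix, uppercases, and zero-pads the
    numeric part to five digits.
    """
    value = identifier.strip()
    if value.lower().startswith("ko:"):
        value = value[3:]
    value = value.upper()
    match = _KEGG_RE.match(value)
    if not match:
        raise RefDbError(f"malformed KEGG identifier {identifier!r}")
    return f"K{int(match.group(1)):05d}"


def select_kegg_class(
    gene_id: str, candidates: Iterable[str], seed: int
) -> Optional[str]:
    """Pick at most one KEGG ortholog for a gene, deterministically.

    A reference sequence may carry at most one class per classification,
    so when several orthologs are listed one is chosen by a keyed hash of
    ``(seed, gene_id)``. The draw is counter-free: it depends only on the
    seed and the gene, so the selection is stable under reordering of the
    protein list across builds.
    """
    normalized = [normalize_kegg(c) for c in candidates]
    if not normalized:
        return None
    if len(normalized) == 1:
        return normalized[0]
    digest = hashlib.blake2b(
        f"{seed}:{gene_id}".encode("utf-8"), digest_size=8
    ).digest()
    index = int.from_bytes(digest, "big") % len(normalized)
    return normalized[index]


# ---------------------------------------------------------------------------
# MD5 hash join


def sequence_md5(sequence: str) -> str:
    """MD5 of the uppercase sequence with whitespace and ``*`` removed."""
    cleaned = "".join(sequence.split()).replace("*", "").upper()
    return hashlib.md5(cleaned.encode("ascii")).hexdigest()


def transfer_annotations_by_md5(
    proteins: Iterable[ProteinRecord], catalog: CrossReferenceCatalog
) -> dict[str, dict[str, str]]:
    """Copy catalog classes onto proteins that share a sequence MD5.

    Returns ``accession -> {classification: class_id}`` restricted to
    :data:`MD5_CLASSIFICATIONS`. When several catalog rows share an MD5 the
    earliest row wins per classification (conflicts are logged); a protein
    without any MD5 match receives no entries.
    """
    by_md5: dict[str, dict[str, str]] = {}
    for row in catalog:
        merged = by_md5.setdefault(row.sequence_md5, {})
        for classification, class_id in row.classes.items():
            if classification in merged:
                if merged[classification] != class_id:
                    logger.warning(
                        "md5 %s: conflicting %s classes (%r kept, %r from %s ignored)",
                        row.sequence_md5,
                        classification,
                        merged[classification],
                        class_id,
                        row.external_accession,
                    )
                continue
            merged[classification] = class_id
    out: dict[str, dict[str, str]] = {}
    for protein in proteins:
        classes = by_md5.get(sequence_md5(protein.sequence))
        if classes:
            out[protein.accession] = dict(classes)
    return out


# ---------------------------------------------------------------------------
# full build


def build_mapping_database(
    proteins: Iterable[ProteinRecord],
    tables: AnnotationTables,
    catalog: CrossReferenceCatalog,
    ncbi_tree: Optional[TaxonomyTree] = None,
    gtdb_tree: Optional[TaxonomyTree] = None,
    seed: int = 0,
) -> MappingDatabase:
    """Assemble the accession→classification mapping database.

    Taxonomy and GTDB are taken from the genome's taxonomy row (keyed by
    the genome part of the accession); KEGG via :func:`select_kegg_class`
    on the gene part; EC/EGGNOG/INTERPRO2GO/SEED via the MD5 hash join.
    When trees are supplied, taxon/class ids are checked against them.
    """
    proteins = list(proteins)
    missing = sorted(
        {
            p.gtdb_genome_id
            for p in proteins
            if p.gtdb_genome_id not in tables.genome_taxonomy
        }
    )
    if missing:
        raise RefDbError(f"genomes without a taxonomy row: {missing}")

    transferred = transfer_annotations_by_md5(proteins, catalog)
    db = MappingDatabase()
    for protein in proteins:
        accession = protein.accession
        ncbi_taxon, gtdb_string = tables.genome_taxonomy[protein.gtdb_genome_id]
        gtdb_class = gtdb_deepest_path(gtdb_string)
        if ncbi_tree is not None and ncbi_taxon not in ncbi_tree:
            raise RefDbError(
                f"genome {protein.gtdb_genome_id!r}: taxon {ncbi_taxon!r} "
                "not in the NCBI tree"
            )
        if gtdb_tree is not None and gtdb_class not in gtdb_tree:
            raise RefDbError(
                f"genome {protein.gtdb_genome_id!r}: GTDB path {gtdb_class!r} "
                "not in the GTDB tree"
            )
        classes: dict[str, Optional[str]] = {
            "Taxonomy": ncbi_taxon,
            "GTDB": gtdb_class,
            "KEGG": select_kegg_class(
                protein.gene_id, tables.kegg_candidates.get(protein.gene_id, []), seed
            ),
        }
        classes.update(transferred.get(accession, {}))
        db.add_row(accession, classes)
    return db


# ---------------------------------------------------------------------------
# FASTA I/O


def write_reference_fasta(
    proteins: Iterable[ProteinRecord], sink: str | Path | IO[str]
) -> int:
    """Write one FASTA record per protein, headed by its two-part accession.

    Sequences are wrapped at 80 columns. Returns the record count.
    """
    records = (
        SeqRecord(Seq(p.sequence), id=p.accession, description="") for p in proteins
    )
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as handle:
            return _write_fasta(records, handle)
    return _write_fasta(records, sink)


def _write_fasta(records: Iterable[SeqRecord], handle: IO[str]) -> int:
    writer = FastaWriter(handle, wrap=80)
    return writer.write_file(records)


def read_reference_fasta(source: str | Path | IO[str]) -> list[tuple[str, str]]:
    """Read ``(accession, sequence)`` pairs from a reference FASTA."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(source, "fasta")]


# ---------------------------------------------------------------------------
# mapping store (SQLite single file) and TSV export

_STORE_COLUMNS = ("Accession",) + CLASSIFICATIONS


def save_mapping_store(db: MappingDatabase, path: str | Path) -> None:
    """Persist the mapping database as a single-file SQLite store.

    Rows are written in canonical (sorted-accession) order so equal
    databases produce byte-identical stores.
    """
    path = Path(path)
    if path.exists():
        path.unlink()
    with sqlite3.connect(path) as conn:
        conn.execute(
            "CREATE TABLE mappings ("
            "Accession TEXT PRIMARY KEY, Taxonomy TEXT, GTDB TEXT, EC TEXT, "
            "EGGNOG TEXT, INTERPRO2GO TEXT, KEGG TEXT, SEED TEXT)"
        )
        rows = db.rows()
        conn.executemany(
            "INSERT INTO mappings VALUES (?,?,?,?,?,?,?,?)",
            (
                (accession,)
                + tuple(rows[accession].get(c) for c in CLASSIFICATIONS)
                for accession in sorted(rows)
            ),
        )
        conn.commit()


def load_mapping_store(path: str | Path) -> MappingDatabase:
    """Load a mapping database saved by :func:`save_mapping_store`."""
    path = Path(path)
    if not path.exists():
        raise RefDbError(f"mapping store not found: {path}")
    db = MappingDatabase()
    with sqlite3.connect(path) as conn:
        try:
            cursor = conn.execute(
                "SELECT {} FROM mappings".format(", ".join(_STORE_COLUMNS))
            )
        except sqlite3.DatabaseError as exc:
            raise RefDbError(f"cannot read mapping store {path}: {exc}") from exc
        for record in cursor:
            accession = record[0]
            classes = {
                c: v for c, v in zip(CLASSIFICATIONS, record[1:]) if v is not None
            }
            db.add_row(accession, classes)
    return db


def export_mapping_tsv(db: MappingDatabase, sink: str | Path | IO[str]) -> None:
    """Write the mapping table as TSV with the store's column layout."""
    rows = db.rows()
    frame = pd.DataFrame(
        [
            {"Accession": a, **{c: rows[a].get(c, "") for c in CLASSIFICATIONS}}
            for a in sorted(rows)
        ],
        columns=list(_STORE_COLUMNS),
    )
    frame.to_csv(sink, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tabular input readers


def read_protein_table(source: str | Path | IO[str]) -> list[ProteinRecord]:
    """Read proteins from a TSV with columns gene_id, gtdb_genome_id, sequence."""
    frame = pd.read_csv(source, sep="\t", dtype=str)
    _require_columns(frame, ("gene_id", "gtdb_genome_id", "sequence"), "protein table")
    return [
        ProteinRecord(row.gene_id, row.gtdb_genome_id, row.sequence)
        for row in frame.itertuples(index=False)
    ]


def read_genome_taxonomy(source: str | Path | IO[str]) -> dict[str, tuple[str, str]]:
    """Read genome taxonomy TSV: gtdb_genome_id, ncbi_taxon_id, gtdb_taxonomy."""
    frame = pd.read_csv(source, sep="\t", dtype=str)
    _require_columns(
        frame, ("gtdb_genome_id", "ncbi_taxon_id", "gtdb_taxonomy"), "genome taxonomy"
    )
    return {
        row.gtdb_genome_id: (row.ncbi_taxon_id, row.gtdb_taxonomy)
        for row in frame.itertuples(index=False)
    }


def read_kegg_candidates(source: str | Path | IO[str]) -> dict[str, list[str]]:
    """Read KEGG candidates TSV: gene_id, comma-separated ortholog list."""
    frame = pd.read_csv(source, sep="\t", dtype=str)
    _require_columns(frame, ("gene_id", "kegg_ids"), "KEGG candidates")
    out: dict[str, list[str]] = {}
    for row in frame.itertuples(index=False):
        if isinstance(row.kegg_ids, str) and row.kegg_ids:
            out[row.gene_id] = [k for k in row.kegg_ids.split(",") if k]
    return out


def read_catalog(source: str | Path | IO[str]) -> CrossReferenceCatalog:
    """Read the cross-reference catalog TSV.

    Columns: external_accession, sequence_md5, then one optional column
    per classification in EC/EGGNOG/INTERPRO2GO/SEED (empty = no class).
    """
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, ("external_accession", "sequence_md5"), "catalog")
    rows: CrossReferenceCatalog = []
    for row in frame.itertuples(index=False):
        classes = {
            c: getattr(row, c)
            for c in MD5_CLASSIFICATIONS
            if c in frame.columns and getattr(row, c)
        }
        rows.append(CatalogRow(row.external_accession, row.sequence_md5, classes))
    return rows


def _require_columns(
    frame: pd.DataFrame, columns: Iterable[str], what: str
) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise RefDbError(f"{what} is missing columns {missing}")
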