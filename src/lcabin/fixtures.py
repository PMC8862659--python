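"""Deterministic synthetic data with planted ground truth.

Generates everything the other modules consume — a balanced NCBI/GTDB
taxonomy pair with identical topology, an annotated protein collection
with a cross-reference catalog sharing a configurable fraction of
sequences, and a tabular alignment file whose reads carry a planted
source species — so binning, database construction and comparison are
testable end to end without any downloads.

Reads draw 1–5 alignments to proteins of their source genome at a base
bit score; with probability ``noise_rate`` a read gains one off-source
alignment whose score decays with the number of taxonomic ranks
separating the noise species from the source species. In long-read mode
each alignment occupies its own non-overlapping query window.

All randomness flows from ``seed`` through fixed per-artifact substreams
(taxonomy, reference, reads), so regenerating with the same seed yields
byte-identical files and changing ``n_reads`` does not perturb the
reference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .refdb import (
    MD5_CLASSIFICATIONS,
    AnnotationTables,
    CatalogRow,
    CrossReferenceCatalog,
    ProteinRecord,
    sequence_md5,
)
from .taxonomy import (
    GTDB_PREFIXES,
    NCBI_RANKS,
    TaxonomyNode,
    TaxonomyTree,
    build_gtdb_tree,
    serialize_ncbi_nodes,
)

__all__ = [
    "FixtureConfig",
    "FixtureTaxonomy",
    "GroundTruth",
    "FixtureBundle",
    "generate_taxonomy",
    "generate_reference",
    "generate_alignment_file",
    "generate_bundle",
    "write_fixture",
]

_AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# substream offsets off the master seed
_STREAM_TAXONOMY = 1
_STREAM_REFERENCE = 2
_STREAM_READS = 3


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic world.

    ``children_per_rank`` controls tree shape (2 gives 2^7 = 128 species);
    ``md5_overlap_fraction`` is the share of proteins mirrored into the
    cross-reference catalog; ``annotation_probability`` is the chance a
    catalog row carries a class in each of EC/EGGNOG/INTERPRO2GO/SEED;
    ``kegg_probability`` the chance a gene has a KEGG candidate list
    (of length 1–3). Scores follow a base bit score minus a decay per
    taxonomic rank separating a noise hit from the read's source.
    """

    seed: int
    n_genomes: int = 160
    proteins_per_genome: int = 5
    children_per_rank: int = 2
    kegg_probability: float = 0.7
    annotation_probability: float = 0.9
    md5_overlap_fraction: float = 0.4
    n_reads: int = 1000
    long_read: bool = False
    noise_rate: float = 0.0
    base_bit_score: float = 150.0
    score_decay_per_rank: float = 15.0

    def __post_init__(self) -> None:
        for name in ("kegg_probability", "annotation_probability",
                     "md5_overlap_fraction", "noise_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in ("n_genomes", "proteins_per_genome", "children_per_rank",
                     "n_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), stream])


@dataclass
class FixtureTaxonomy:
    """Generated tree pair plus the genome-to-leaf attachment."""

    ncbi_tree: TaxonomyTree
    gtdb_tree: TaxonomyTree
    species_leaves: list[str]
    leaf_gtdb_string: dict[str, str]
    genome_map: dict[str, str]  # genome_id -> ncbi species leaf

    def gtdb_leaf(self, ncbi_leaf: str) -> str:
        # a fully resolved 7-rank string is its own deepest-path taxon id
        return self.leaf_gtdb_string[ncbi_leaf]


@dataclass
class GroundTruth:
    """What the generator planted, for bookkeeping-style oracles."""

    read_sources: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    #: read_id -> (genome_id, ncbi species taxon, gtdb species path)
    protein_classes: dict[str, dict[str, str]] = field(default_factory=dict)
    planted_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class FixtureBundle:
    """Everything one seeded generation run produced, in memory."""

    config: FixtureConfig
    taxonomy: FixtureTaxonomy
    proteins: list[ProteinRecord]
    tables: AnnotationTables
    catalog: CrossReferenceCatalog
    truth: GroundTruth
    alignment_lines: list[str]


# ---------------------------------------------------------------------------
# taxonomy


def generate_taxonomy(config: FixtureConfig) -> FixtureTaxonomy:
    """Balanced 7-rank tree in both flavors, with genomes on species leaves.

    The NCBI flavor uses numeric taxon ids (root 1) and standard rank
    labels; the GTDB flavor mirrors the topology with prefixed path ids
    derived from the NCBI ids, so every species lineage has length 8
    including the root.
    """
    nodes: dict[str, TaxonomyNode] = {
        "1": TaxonomyNode("1", "1", "no rank", "root")
    }
    counter = 2
    frontier = ["1"]
    component: dict[str, str] = {}
    for level, rank in enumerate(NCBI_RANKS):
        letter = GTDB_PREFIXES[level]
        next_frontier = []
        for parent in frontier:
            for _ in range(config.children_per_rank):
                taxon_id = str(counter)
                counter += 1
                name = f"{rank[:3]}{taxon_id}"
                nodes[taxon_id] = TaxonomyNode(taxon_id, parent, rank, name)
                component[taxon_id] = f"{letter}{name.capitalize()}"
                next_frontier.append(taxon_id)
        frontier = next_frontier
    ncbi_tree = TaxonomyTree(nodes=nodes, root_id="1", flavor="NCBI")

    species_leaves = frontier
    leaf_gtdb_string: dict[str, str] = {}
    for leaf in species_leaves:
        path = ncbi_tree.lineage(leaf)[1:]  # drop root
        leaf_gtdb_string[leaf] = ";".join(component[t] for t in path)
    gtdb_tree = build_gtdb_tree(leaf_gtdb_string[leaf] for leaf in species_leaves)

    rng = config.rng(_STREAM_TAXONOMY)
    genome_map = {
        f"GB_GCA_{i:09d}_1": species_leaves[int(rng.integers(len(species_leaves)))]
        for i in range(1, config.n_genomes + 1)
    }
    return FixtureTaxonomy(
        ncbi_tree=ncbi_tree,
        gtdb_tree=gtdb_tree,
        species_leaves=species_leaves,
        leaf_gtdb_string=leaf_gtdb_string,
        genome_map=genome_map,
    )


# ---------------------------------------------------------------------------
# reference


def generate_reference(
    config: FixtureConfig, taxonomy: FixtureTaxonomy
) -> tuple[list[ProteinRecord], AnnotationTables, CrossReferenceCatalog, GroundTruth]:
    """Random proteins with annotations and a partially overlapping catalog.

    Exactly ``floor(md5_overlap_fraction * n_proteins)`` proteins are
    mirrored into the cross-reference catalog; planted class counts are
    recorded in the returned :class:`GroundTruth`.
    """
    rng = config.rng(_STREAM_REFERENCE)
    proteins: list[ProteinRecord] = []
    kegg_candidates: dict[str, list[str]] = {}
    genome_taxonomy: dict[str, tuple[str, str]] = {}
    truth = GroundTruth()

    gene_counter = 0
    for genome_id in sorted(taxonomy.genome_map):
        leaf = taxonomy.genome_map[genome_id]
        genome_taxonomy[genome_id] = (leaf, taxonomy.leaf_gtdb_string[leaf])
        for _ in range(config.proteins_per_genome):
            gene_counter += 1
            gene_id = f"GENE{gene_counter:06d}_1"
            length = int(rng.integers(80, 401))
            sequence = "".join(rng.choice(_AA_ALPHABET, size=length))
            proteins.append(ProteinRecord(gene_id, genome_id, sequence))
            if rng.random() < config.kegg_probability:
                n_candidates = int(rng.integers(1, 4))
                kegg_candidates[gene_id] = [
                    f"K{int(rng.integers(1, 100)):05d}" for _ in range(n_candidates)
                ]

    n_proteins = len(proteins)
    n_overlap = math.floor(config.md5_overlap_fraction * n_proteins)
    order = rng.permutation(n_proteins)[:n_overlap]
    catalog: CrossReferenceCatalog = []
    planted_md5_counts = {c: 0 for c in MD5_CLASSIFICATIONS}
    for row_index, protein_index in enumerate(sorted(order), start=1):
        protein = proteins[protein_index]
        classes: dict[str, str] = {}
        if rng.random() < config.annotation_probability:
            classes["EC"] = f"2.7.1.{int(rng.integers(1, 200))}"
        if rng.random() < config.annotation_probability:
            classes["EGGNOG"] = f"COG{int(rng.integers(1, 5000)):04d}"
        if rng.random() < config.annotation_probability:
            classes["INTERPRO2GO"] = f"IPR{int(rng.integers(1, 40000)):06d}"
        if rng.random() < config.annotation_probability:
            classes["SEED"] = str(int(rng.integers(1, 1000)))
        catalog.append(
            CatalogRow(
                external_accession=f"NR_{row_index:08d}.1",
                sequence_md5=sequence_md5(protein.sequence),
                classes=classes,
            )
        )
        truth.protein_classes[protein.accession] = dict(classes)
        for classification in classes:
            planted_md5_counts[classification] += 1

    truth.planted_counts = {
        "Taxonomy": n_proteins,
        "GTDB": n_proteins,
        "KEGG": len(kegg_candidates),
        **planted_md5_counts,
    }
    tables = AnnotationTables(
        genome_taxonomy=genome_taxonomy, kegg_candidates=kegg_candidates
    )
    return proteins, tables, catalog, truth


# ---------------------------------------------------------------------------
# alignments


def _rank_separation(tree: TaxonomyTree, a: str, b: str) -> int:
    """Ranks from the LCA down to a species leaf (0 when a == b)."""
    return tree.depth(a) - tree.depth(tree.lca([a, b]))


def generate_alignment_file(
    config: FixtureConfig,
    taxonomy: FixtureTaxonomy,
    proteins: list[ProteinRecord],
    truth: GroundTruth,
) -> list[str]:
    """Emit tabular alignment lines with planted per-read sources.

    Returns the 12-column lines; read sources are appended to
    ``truth.read_sources``. Every read receives at least one on-source
    alignment; noise alignments (probability ``noise_rate``) target a
    different species with a rank-distance-decayed bit score.
    """
    rng = config.rng(_STREAM_READS)
    by_genome: dict[str, list[ProteinRecord]] = {}
    for protein in proteins:
        by_genome.setdefault(protein.gtdb_genome_id, []).append(protein)
    genome_ids = sorted(by_genome)

    lines: list[str] = []
    for i in range(1, config.n_reads + 1):
        read_id = f"read{i:05d}"
        genome_id = genome_ids[int(rng.integers(len(genome_ids)))]
        source_leaf = taxonomy.genome_map[genome_id]
        truth.read_sources[read_id] = (
            genome_id,
            source_leaf,
            taxonomy.leaf_gtdb_string[source_leaf],
        )
        read_length = (
            int(rng.integers(2000, 8001)) if config.long_read else 300
        )
        n_alignments = int(rng.integers(1, 6))
        subjects = [
            by_genome[genome_id][int(rng.integers(len(by_genome[genome_id])))]
            for _ in range(n_alignments)
        ]
        windows = _query_windows(rng, read_length, n_alignments, config.long_read)
        for subject, (start, end) in zip(subjects, windows):
            score = config.base_bit_score + float(rng.normal(0.0, 3.0))
            lines.append(_format_line(rng, read_id, subject, start, end, score))
        if rng.random() < config.noise_rate:
            noise_genome = genome_ids[int(rng.integers(len(genome_ids)))]
            noise_leaf = taxonomy.genome_map[noise_genome]
            separation = _rank_separation(
                taxonomy.ncbi_tree, source_leaf, noise_leaf
            )
            noise_subject = by_genome[noise_genome][
                int(rng.integers(len(by_genome[noise_genome])))
            ]
            score = (
                config.base_bit_score
                - config.score_decay_per_rank * separation
                + float(rng.normal(0.0, 2.0))
            )
            start = int(rng.integers(1, max(2, read_length - 150)))
            end = min(read_length, start + 119)
            lines.append(
                _format_line(rng, read_id, noise_subject, start, end, score)
            )
    return lines


def _query_windows(
    rng: np.random.Generator, read_length: int, n: int, long_read: bool
) -> list[tuple[int, int]]:
    if long_read:
        windows = []
        position = 1
        for _ in range(n):
            span = int(rng.integers(300, 901))
            gap = int(rng.integers(10, 51))
            end = min(read_length, position + span - 1)
            if end <= position:
                break
            windows.append((position, end))
            position = end + 1 + gap
            if position >= read_length:
                break
        return windows or [(1, min(read_length, 300))]
    windows = []
    for _ in range(n):
        start = int(rng.integers(1, max(2, read_length - 120)))
        end = min(read_length, start + 89 + int(rng.integers(0, 21)))
        windows.append((start, end))
    return windows


def _format_line(
    rng: np.random.Generator,
    read_id: str,
    subject: ProteinRecord,
    start: int,
    end: int,
    score: float,
) -> str:
    if rng.random() < 0.3:  # reverse frame
        start, end = end, start
    alen = max(10, (abs(end - start) + 1) // 3)
    pident = float(rng.uniform(80.0, 100.0))
    mismatch = int(rng.integers(0, 6))
    gapopen = int(rng.integers(0, 3))
    evalue = 10.0 ** (-max(score, 1.0) / 10.0)
    return (
        f"{read_id}\t{subject.accession}\t{pident:.1f}\t{alen}\t{mismatch}\t"
        f"{gapopen}\t{start}\t{end}\t1\t{alen}\t{evalue:.2e}\t{score:.1f}"
    )


# ---------------------------------------------------------------------------
# bundle and file emission


def generate_bundle(config: FixtureConfig) -> FixtureBundle:
    """Run all three generators off one config."""
    taxonomy = generate_taxonomy(config)
    proteins, tables, catalog, truth = generate_reference(config, taxonomy)
    lines = generate_alignment_file(config, taxonomy, proteins, truth)
    return FixtureBundle(config, taxonomy, proteins, tables, catalog, truth, lines)


def write_fixture(
    outdir: str | Path, config: FixtureConfig, bundle: Optional[FixtureBundle] = None
) -> dict[str, Path]:
    """Emit every fixture file into ``outdir``; returns name -> path.

    Files: ``nodes.dmp``, ``gtdb_taxonomy.tsv``, ``proteins.tsv``,
    ``genome_taxonomy.tsv``, ``kegg_candidates.tsv``, ``catalog.tsv``,
    ``alignments.tsv``, ``read_truth.tsv``, ``truth_counts.json``.
    """
    bundle = bundle or generate_bundle(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, text: str) -> None:
        path = outdir / name
        path.write_text(text)
        paths[name] = path

    import io as _io

    buffer = _io.StringIO()
    serialize_ncbi_nodes(bundle.taxonomy.ncbi_tree, buffer)
    emit("nodes.dmp", buffer.getvalue())

    emit(
        "gtdb_taxonomy.tsv",
        "".join(
            f"{genome}\t{bundle.taxonomy.leaf_gtdb_string[leaf]}\n"
            for genome, leaf in sorted(bundle.taxonomy.genome_map.items())
        ),
    )
    emit(
        "proteins.tsv",
        "gene_id\tgtdb_genome_id\tsequence\n"
        + "".join(
            f"{p.gene_id}\t{p.gtdb_genome_id}\t{p.sequence}\n"
            for p in bundle.proteins
        ),
    )
    emit(
        "genome_taxonomy.tsv",
        "gtdb_genome_id\tncbi_taxon_id\tgtdb_taxonomy\n"
        + "".join(
            f"{genome}\t{taxon}\t{string}\n"
            for genome, (taxon, string) in sorted(
                bundle.tables.genome_taxonomy.items()
            )
        ),
    )
    emit(
        "kegg_candidates.tsv",
        "gene_id\tkegg_ids\n"
        + "".join(
            f"{gene}\t{','.join(kos)}\n"
            for gene, kos in sorted(bundle.tables.kegg_candidates.items())
        ),
    )
    emit(
        "catalog.tsv",
        "external_accession\tsequence_md5\tEC\tEGGNOG\tINTERPRO2GO\tSEED\n"
        + "".join(
            f"{row.external_accession}\t{row.sequence_md5}\t"
            + "\t".join(row.classes.get(c, "") for c in MD5_CLASSIFICATIONS)
            + "\n"
            for row in bundle.catalog
        ),
    )
    emit("alignments.tsv", "".join(line + "\n" for line in bundle.alignment_lines))
    emit(
        "read_truth.tsv",
        "read_id\tgenome_id\tncbi_taxon\tgtdb_taxonomy\n"
        + "".join(
            f"{read}\t{genome}\t{taxon}\t{string}\n"
            for read, (genome, taxon, string) in sorted(
                bundle.truth.read_sources.items()
            )
        ),
    )
    emit(
        "truth_counts.json",
        json.dumps(bundle.truth.planted_counts, indent=2, sort_keys=True) + "\n",
    )
    return paths
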