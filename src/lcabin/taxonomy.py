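"""Rank-labelled taxonomy trees with LCA and lineage queries.

Two flavors are supported:

* **NCBI** — parsed from the ``nodes.dmp`` dialect of the NCBI taxdump
  (pipe-delimited; the root is the node whose parent is itself,
  conventionally taxon 1).
* **GTDB** — built from 7-rank prefixed strings of the form
  ``d__...;p__...;c__...;o__...;f__...;g__...;s__...``. Node identity is
  the full prefixed path, so identically named genera in different
  families remain distinct nodes. A synthetic ``root`` node sits above
  the domains so every pair of taxa has a lowest common ancestor.

The LCA (lowest common ancestor) of a taxon set is the deepest node that
lies on every member's path to the root; it is the basis of conservative
read placement in alignment-based binning.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "TaxonomyError",
    "TaxonomyNode",
    "TaxonomyTree",
    "PairRelation",
    "parse_ncbi_nodes",
    "serialize_ncbi_nodes",
    "build_gtdb_tree",
    "gtdb_path_components",
    "gtdb_deepest_path",
    "read_gtdb_taxonomy_tsv",
    "lca",
    "lineage",
    "classify_pair",
    "GTDB_PREFIXES",
    "GTDB_RANKS",
    "ROOT_ID",
]

GTDB_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")
GTDB_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
NCBI_RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
ROOT_ID = "root"


class TaxonomyError(ValueError):
    """Structural or lookup error in a taxonomy."""


@dataclass(frozen=True)
class TaxonomyNode:
    """One taxon: opaque id, parent id, rank label and display name."""

    taxon_id: str
    parent_id: str
    rank: str
    name: str = ""


@dataclass
class TaxonomyTree:
    """Rooted taxonomy supporting lineage, depth, LCA and ancestry queries.

    ``nodes`` is keyed by ``taxon_id``; the root's ``parent_id`` equals its
    own ``taxon_id``. ``flavor`` is ``"NCBI"`` or ``"GTDB"``.
    """

    nodes: dict[str, TaxonomyNode]
    root_id: str
    flavor: str = "NCBI"
    _depth: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if self.root_id not in self.nodes:
            raise TaxonomyError(f"root {self.root_id!r} not among nodes")
        roots = [
            t for t, n in self.nodes.items() if n.parent_id == t or not n.parent_id
        ]
        if roots != [self.root_id] and set(roots) != {self.root_id}:
            raise TaxonomyError(f"expected exactly one root, found {sorted(roots)}")
        for node in self.nodes.values():
            if node.taxon_id == self.root_id:
                continue
            if node.parent_id not in self.nodes:
                raise TaxonomyError(
                    f"taxon {node.taxon_id!r} has dangling parent {node.parent_id!r}"
                )
        # every node must reach the root (no cycles)
        for taxon_id in self.nodes:
            self.depth(taxon_id)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def _require(self, taxon_id: str) -> TaxonomyNode:
        try:
            return self.nodes[taxon_id]
        except KeyError:
            raise TaxonomyError(f"unknown taxon {taxon_id!r}") from None

    def parent(self, taxon_id: str) -> str:
        return self._require(taxon_id).parent_id

    def depth(self, taxon_id: str) -> int:
        """Number of edges from the root (root has depth 0)."""
        cached = self._depth.get(taxon_id)
        if cached is not None:
            return cached
        path = []
        current = taxon_id
        seen = set()
        while current not in self._depth:
            if current in seen:
                raise TaxonomyError(f"cycle detected at taxon {current!r}")
            seen.add(current)
            path.append(current)
            node = self._require(current)
            if current == self.root_id:
                self._depth[current] = 0
                path.pop()
                break
            current = node.parent_id
        base = self._depth[current] if current in self._depth else 0
        for offset, taxon in enumerate(reversed(path), start=1):
            self._depth[taxon] = base + offset
        return self._depth[taxon_id]

    # -- queries -----------------------------------------------------------

    def lineage(self, taxon_id: str) -> list[str]:
        """Root-first path of taxon ids ending at ``taxon_id``."""
        self._require(taxon_id)
        path = [taxon_id]
        current = taxon_id
        while current != self.root_id:
            current = self._require(current).parent_id
            path.append(current)
        path.reverse()
        return path

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        """True if ``ancestor`` lies on ``descendant``'s root path (or equals it)."""
        self._require(ancestor)
        current = descendant
        self._require(current)
        while True:
            if current == ancestor:
                return True
            if current == self.root_id:
                return False
            current = self._require(current).parent_id

    def lca(self, taxa: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxa."""
        taxa = list(taxa)
        if not taxa:
            raise TaxonomyError("lca of an empty taxon set is undefined")
        result = taxa[0]
        self._require(result)
        for taxon in taxa[1:]:
            result = self._lca_pair(result, taxon)
        return result

    def _lca_pair(self, a: str, b: str) -> str:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a = self._require(a).parent_id
            da -= 1
        while db > da:
            b = self._require(b).parent_id
            db -= 1
        while a != b:
            a = self._require(a).parent_id
            b = self._require(b).parent_id
        return a

    def classify_pair(self, a: str, b: str) -> "PairRelation":
        """Lineage relation between two taxa (see :class:`PairRelation`)."""
        self._require(a)
        self._require(b)
        if a == b:
            return PairRelation.IDENTICAL
        if self.is_ancestor(b, a):
            return PairRelation.FIRST_MORE_SPECIFIC
        if self.is_ancestor(a, b):
            return PairRelation.SECOND_MORE_SPECIFIC
        return PairRelation.INCOMPATIBLE

    def children_index(self) -> dict[str, list[str]]:
        index: dict[str, list[str]] = {t: [] for t in self.nodes}
        for node in self.nodes.values():
            if node.taxon_id != self.root_id:
                index[node.parent_id].append(node.taxon_id)
        return index

    def subtree(self, taxon_id: str) -> set[str]:
        """All taxa at or below ``taxon_id``."""
        self._require(taxon_id)
        children = self.children_index()
        out: set[str] = set()
        stack = [taxon_id]
        while stack:
            current = stack.pop()
            out.add(current)
            stack.extend(children[current])
        return out


class PairRelation(Enum):
    """How two taxon assignments relate on the tree.

    Two assignments are *compatible* when one lies on the other's root
    path; otherwise their lineages diverge and they are *incompatible*.
    """

    IDENTICAL = "identical"
    FIRST_MORE_SPECIFIC = "first_more_specific"
    SECOND_MORE_SPECIFIC = "second_more_specific"
    INCOMPATIBLE = "incompatible"


# ---------------------------------------------------------------------------
# NCBI nodes.dmp dialect


def _lines(source: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(source, str):
        yield from io.StringIO(source)
    else:
        yield from source


def parse_ncbi_nodes(source: str | IO[str] | Iterable[str]) -> TaxonomyTree:
    """Parse a ``nodes.dmp``-dialect dump into a :class:`TaxonomyTree`.

    Each line carries pipe-delimited fields ``taxon_id | parent_id | rank``;
    fields are split on ``|`` with surrounding tabs/spaces stripped and only
    the first three fields are consumed. A node whose parent is itself is
    the root.

    Raises :class:`TaxonomyError` on duplicate taxon ids, dangling parents
    or a missing/ambiguous root.
    """
    nodes: dict[str, TaxonomyNode] = {}
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.rstrip("\n").rstrip()
        if not line:
            continue
        if line.endswith("|"):
            line = line[:-1]
        fields = [part.strip(" \t") for part in line.split("|")]
        if len(fields) < 3:
            raise TaxonomyError(
                f"line {lineno}: expected at least 3 pipe-delimited fields"
            )
        taxon_id, parent_id, rank = fields[0], fields[1], fields[2]
        if not taxon_id:
            raise TaxonomyError(f"line {lineno}: empty taxon id")
        if taxon_id in nodes:
            raise TaxonomyError(f"duplicate taxon id {taxon_id!r} (line {lineno})")
        nodes[taxon_id] = TaxonomyNode(taxon_id, parent_id, rank)
    if not nodes:
        raise TaxonomyError("empty taxonomy dump")
    roots = [t for t, n in nodes.items() if n.parent_id == t]
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one self-parent root, found {roots}")
    return TaxonomyTree(nodes=nodes, root_id=roots[0], flavor="NCBI")


def serialize_ncbi_nodes(tree: TaxonomyTree, sink: IO[str]) -> None:
    """Write a tree back to the ``nodes.dmp`` dialect (taxid | parent | rank)."""
    for taxon_id in sorted(tree.nodes, key=_taxid_sort_key):
        node = tree.nodes[taxon_id]
        sink.write(f"{node.taxon_id}\t|\t{node.parent_id}\t|\t{node.rank}\t|\n")


def _taxid_sort_key(taxon_id: str) -> tuple[int, object]:
    return (0, int(taxon_id)) if taxon_id.isdigit() else (1, taxon_id)


# ---------------------------------------------------------------------------
# GTDB 7-rank strings


def gtdb_path_components(taxon_string: str) -> list[str]:
    """Validated, truncated components of one 7-rank GTDB string.

    The string must have exactly 7 semicolon-separated components carrying
    the prefixes ``d__,p__,c__,o__,f__,g__,s__`` in order. An empty
    component (prefix only) terminates the path at the last filled rank;
    a filled component below an empty one is a format error.
    """
    parts = [p.strip() for p in taxon_string.split(";")]
    if len(parts) != 7:
        raise TaxonomyError(
            f"expected 7 semicolon-separated ranks, got {len(parts)}: {taxon_string!r}"
        )
    filled: list[str] = []
    truncated = False
    for part, prefix in zip(parts, GTDB_PREFIXES):
        if not part.startswith(prefix):
            raise TaxonomyError(
                f"component {part!r} does not carry expected prefix {prefix!r}"
            )
        if part == prefix:
            truncated = True
            continue
        if truncated:
            raise TaxonomyError(
                f"filled rank {part!r} below an empty rank in {taxon_string!r}"
            )
        filled.append(part)
    return filled


def gtdb_deepest_path(taxon_string: str) -> str:
    """Taxon id (full prefixed path) of the deepest filled rank; ``root`` if none."""
    components = gtdb_path_components(taxon_string)
    if not components:
        return ROOT_ID
    return ";".join(components)


def build_gtdb_tree(taxon_strings: Iterable[str]) -> TaxonomyTree:
    """Build a GTDB-flavor tree from 7-rank strings.

    Every distinct prefixed path prefix becomes one node whose taxon id is
    the full path (components joined by ``;``); strings sharing a path
    prefix share those nodes. A synthetic ``root`` node is added above the
    domains.
    """
    nodes: dict[str, TaxonomyNode] = {
        ROOT_ID: TaxonomyNode(ROOT_ID, ROOT_ID, "root", "root")
    }
    for taxon_string in taxon_strings:
        components = gtdb_path_components(taxon_string)
        parent = ROOT_ID
        for level, component in enumerate(components):
            path = ";".join(components[: level + 1])
            if path not in nodes:
                nodes[path] = TaxonomyNode(
                    taxon_id=path,
                    parent_id=parent,
                    rank=GTDB_RANKS[level],
                    name=component[3:],
                )
            parent = path
    return TaxonomyTree(nodes=nodes, root_id=ROOT_ID, flavor="GTDB")


def read_gtdb_taxonomy_tsv(
    source: str | IO[str] | Iterable[str],
) -> dict[str, str]:
    """Read a two-column TSV of ``genome_id<TAB>7-rank string``."""
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise TaxonomyError(f"line {lineno}: expected 2 tab-separated columns")
        genome_id, taxon_string = fields
        gtdb_path_components(taxon_string)  # validate early
        mapping[genome_id] = taxon_string
    return mapping


# ---------------------------------------------------------------------------
# module-level functional aliases


def lca(tree: TaxonomyTree, taxa: Iterable[str]) -> str:
    return tree.lca(taxa)


def lineage(tree: TaxonomyTree, taxon_id: str) -> list[str]:
    return tree.lineage(taxon_id)


def classify_pair(tree: TaxonomyTree, a: str, b: str) -> PairRelation:
    return tree.classify_pair(a, b)
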