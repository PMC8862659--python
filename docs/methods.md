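# Methods

## Problem setting

Alignment-based microbiome analysis aligns shotgun reads against a
protein reference database and then assigns ("bins") each read to a
taxonomy node and to functional classes using its alignments. This
package implements the three stages surrounding the aligner: building
the reference artifacts from an annotated genome collection,
performing the per-read assignment, and comparing two runs of the
pipeline read by read. The aligner itself (and its binary output
formats) is out of scope; alignments enter as 12-column BLAST tabular
text.

## Taxonomies

Both supported flavors are reduced to one rooted, rank-labelled tree
type with parent pointers.

- **NCBI flavor**: parsed from the `nodes.dmp` dialect (pipe-delimited
  `taxon_id | parent_id | rank`, only the first three fields used).
  The self-parent node is the root. Dangling parents, duplicate ids
  and cycles are structural errors that name the offending taxon.
- **GTDB flavor**: built from 7-rank prefixed strings. Node identity
  is the *full prefixed path* (components joined by `;`), not the bare
  name, so identically named genera in different families remain
  distinct. A synthetic `root` node sits above the domains so every
  taxon pair has an LCA. An empty rank component (prefix only)
  terminates the path at the last filled rank — an assignment to such
  a string resolves to that ancestor — and a filled rank below an
  empty one is rejected as malformed.

LCA is computed by lifting both nodes to equal depth and walking up in
lockstep; depths are memoized. Lineage compatibility of two
assignments is a prefix relation on root paths: identical, one side
more specific (strict ancestor in either direction), or incompatible.

## Reference database construction

Each reference protein is identified by a two-part accession
`gene_id + "__" + genome_id`. Parsing splits at the **first** `__`;
parts containing `__` are rejected at build time rather than guessed
at parse time. The mapping database keys on these accessions and holds
at most one class per classification per accession:

- **Taxonomy / GTDB** come from the genome's taxonomy row, keyed by
  the genome part. The GTDB class id is the deepest filled prefixed
  path of the genome's rank string.
- **KEGG** comes from per-gene candidate lists, keyed by the gene
  part. When several orthologs are listed, one is selected by a keyed
  BLAKE2b hash of `(seed, gene_id)` modulo the candidate count. The
  draw is counter-free, so a rebuild with the same seed selects the
  same ortholog regardless of protein-list order. KEGG ids are
  normalized to `K#####` (optional `ko:` prefix stripped, uppercased,
  zero-padded).
- **EC / EGGNOG / INTERPRO2GO / SEED** are transferred from an
  external cross-reference catalog by joining on the MD5 of the
  protein sequence, computed over the uppercase sequence with
  whitespace and terminal stops (`*`) removed so cosmetic differences
  do not break identity. When several catalog rows share an MD5, the
  earliest row wins per classification and conflicts are logged;
  determinism is preferred over arbitration.

The store is a single-file SQLite table
`mappings(Accession PRIMARY KEY, Taxonomy, GTDB, EC, EGGNOG,
INTERPRO2GO, KEGG, SEED)`, written in sorted-accession order so equal
databases are byte-identical on disk; a TSV export mirrors the layout.
The reference FASTA wraps sequences at 80 columns with the two-part
accession as the header.

## Binning

Retention filters (defaults in parentheses) follow the conventions of
meganization tools: drop alignments with bit score below
`min_bit_score` (50) or e-value above `max_evalue` (0.01), then keep
alignments within `top_percent` (10) of the read's best surviving bit
score, i.e. `bit ≥ (1 − top/100) × best`. Clade restriction, when
requested, is applied *before* the score filters, mirroring aligners
that restrict candidate subjects at alignment time. Reverse-frame
alignments (`qstart > qend`) are normalized to `start < end` for
interval arithmetic; coordinates are 1-based inclusive and interval
length is `end − start + 1`.

Per-read outcomes per classification are a class id or one of two
sentinels: `NO_HITS` (no retained alignments) and `UNASSIGNED`
(retained alignments, but none maps to a class).

- **Naive LCA** (short reads): the LCA of the taxa of all retained,
  mapped subjects. Adding an alignment can only move the placement
  toward the root, never deeper.
- **Interval-union LCA** (long reads): each mapped subject taxon *t*
  is scored by the length `c(t)` of the union of the query intervals
  of its alignments (overlapping or adjacent intervals merged, gap 0).
  Taxa with `c(t) ≥ (percent_to_cover/100) × max c` (default 80%) are
  retained and the read is placed on their LCA. A taxon supported over
  most of a long read therefore dominates one supported by a single
  short segment, while near-tied taxa are resolved conservatively to
  their common ancestor. A per-node subtree cover (union length of
  intervals hitting the node's subtree, monotone up the tree) is
  exposed separately for diagnostics and verification. Tie behavior
  against other interval-union implementations is a known
  compatibility caveat; the rule above is this package's fixed
  definition.
- **Functional classes**: the best *mapped* retained hit — the
  highest bit score among alignments whose subject carries a class in
  the classification, ties broken by lexicographically smallest
  subject accession. An unmapped hit with a better score does not
  block assignment; this maximizes assignment rates, which is the
  behavior observed in practice when mapping coverage, not alignment
  quality, is the limiting factor.
- `min_support` (default 1 = off) exists at the profile level to push
  weakly supported taxa to their parent; it is exposed but not part of
  any default workflow.

Run summaries report, per classification, the assigned-read count, the
percentage of all reads and the percentage of aligned reads, rounded
to one decimal (two decimals available for pooled totals); ratios of
paired counts round likewise. A run with zero aligned reads reports 0
with an explicit flag rather than dividing by zero.

## Run comparison

Two runs over the same read universe are compared per classification
over the union of reads assigned by at least one run; reads
unassigned by both (either sentinel) are excluded from the
denominator. Taxonomic categories map the pair relation of the two
assignments (same taxon, either side more specific, incompatible),
with only-A/only-B for one-sided assignments; root-level assignments
count as assigned and are compatible with anything below them.
Functional comparison is the four-way analogue (same/different class).
Cross-flavor comparison (an NCBI-tree run versus a GTDB-tree run) is
deliberately unsupported: categories are only meaningful on a shared
tree.

Mock-community evaluation takes an observed per-species signal —
assigned bases by default, read counts equally valid — and a reference
species set: detected = signal ≥ threshold, TP/FP/FN by set algebra.
The detection threshold is an explicit parameter with no privileged
default, because published evaluations rarely state one.

Spearman's ρ is the Pearson correlation of mid-ranks (average ranks on
ties), delegated to scipy; p-values use the large-sample approximation
and are reported as approximate. Constant vectors and n < 3 are
errors, not NaNs.

## Synthetic data generator

The generator emulates the complete input surface: a balanced 7-rank
taxonomy in both flavors with identical topology (children-per-rank 2
→ 128 species), genomes attached uniformly to species leaves (160
genomes, 5 proteins each by default), random 80–400 aa protein
sequences over the 20 standard residues, per-gene KEGG candidate lists
(probability 0.7, length 1–3), and a cross-reference catalog sharing
`md5_overlap_fraction` (0.4) of the protein sequences with planted
EC/EGGNOG/INTERPRO2GO/SEED classes (probability 0.9 each). Reads draw
1–5 alignments to proteins of their source genome at a base bit score
of 150 (σ 3); with probability `noise_rate` a read gains one
off-source alignment whose score decays by 15 bits per taxonomic rank
separating the noise species from the source. At that decay, only
near-relatives survive the default filters, which matches the
intuition that confounding hits come from close homologs. Long-read
mode gives each alignment its own non-overlapping 300–900 nt window on
a 2–8 kb read.

Randomness is split into fixed substreams (taxonomy / reference /
reads) derived from the master seed, so the same seed yields
byte-identical files and changing the read count does not perturb the
reference. The generator does **not** emulate sequence evolution,
base-calling error, paired-end structure, or abundance skew: passing
recovery tests demonstrates the correctness of the assignment
machinery on its stated inputs, not classifier accuracy on real reads.

## Verification strategy and problem sizes

Every non-trivial operation is tested against an independent oracle:
LCA against brute-force root-path intersection, pair classification
against lineage-prefix containment, the retention filter against a
two-pass reimplementation, interval-union cover against per-node
position-set counting, the MD5 transfer against a raw-sequence
equality join, and comparison categories against a per-read
reclassification with partition-sum checks. End-to-end, noise-free
fixtures must be recovered species-exactly by both LCA variants
(1,000 short reads, 300 long reads), and noisy fixtures must stay on
the planted lineage. These sizes keep the full suite and the
acceptance script each under a few seconds while exercising every
code path; all are configurable upward.

Published summary arithmetic is verified against the printed
per-dataset and pooled counts of a ten-dataset AnnoTree/NCBI-nr
comparison (bundled as data in `lcabin.published`). Four printed
figures in that source are truncated rather than rounded; the tests
check those to one unit in the last printed digit and everything else
exactly.

## Known limitations

- No DAA/binary alignment input; tabular only.
- No merged/deleted-taxon remapping for NCBI dumps, and no name
  resolution (`names.dmp`).
- The interval-union rule is a fixed, documented choice; other
  implementations may break ties differently.
- `min_support` profile folding is exposed but unexercised by the
  default workflow.
- Cross-taxonomy (NCBI vs GTDB) read comparison is intentionally not
  provided.
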