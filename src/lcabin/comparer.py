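"""Read-level concordance between two binning runs, and profile evaluation.

Two runs of the same pipeline over the same reads (e.g. against two
different reference databases) are compared read by read. For a
taxonomic classification each read in the union of assigned reads falls
into exactly one of six categories: assigned by only one run, by both
runs to the same taxon, to compatible lineages with either side more
specific, or to incompatible lineages. Functional classifications use a
four-way partition (only A / only B / same class / different class).

A mock-community evaluation compares an observed per-species signal
(assigned bases or reads) with a reference profile to call true/false
positives and false negatives at a detection threshold, and Spearman's
rank correlation relates paired per-dataset quantities.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Mapping, Optional

import numpy as np
from scipy import stats

from .binner import NO_HITS, UNASSIGNED, RunResult
from .taxonomy import PairRelation, TaxonomyTree

__all__ = [
    "TaxComparisonCategory",
    "FunComparisonCategory",
    "ComparisonSummary",
    "ProfileEvaluation",
    "ComparerError",
    "compare_taxonomic_runs",
    "compare_functional_runs",
    "evaluate_mock",
    "spearman_rho",
    "spearman_test",
    "write_summary_tsv",
    "write_mock_tsv",
]


class ComparerError(ValueError):
    """Usage error in run comparison."""


class TaxComparisonCategory(Enum):
    """Six-way taxonomic concordance partition over the assigned union."""

    ONLY_A = "only_A"
    ONLY_B = "only_B"
    SAME_TAXON = "same_taxon"
    COMPATIBLE_A_MORE_SPECIFIC = "compatible_A_more_specific"
    COMPATIBLE_B_MORE_SPECIFIC = "compatible_B_more_specific"
    INCOMPATIBLE = "incompatible"


class FunComparisonCategory(Enum):
    """Four-way functional concordance partition."""

    ONLY_A = "only_A"
    ONLY_B = "only_B"
    SAME_CLASS = "same_class"
    DIFFERENT_CLASS = "different_class"


_RELATION_TO_CATEGORY = {
    PairRelation.IDENTICAL: TaxComparisonCategory.SAME_TAXON,
    PairRelation.FIRST_MORE_SPECIFIC: TaxComparisonCategory.COMPATIBLE_A_MORE_SPECIFIC,
    PairRelation.SECOND_MORE_SPECIFIC: TaxComparisonCategory.COMPATIBLE_B_MORE_SPECIFIC,
    PairRelation.INCOMPATIBLE: TaxComparisonCategory.INCOMPATIBLE,
}


@dataclass
class ComparisonSummary:
    """Category counts and proportions over the union of assigned reads."""

    counts: dict[str, int]
    proportions: dict[str, float]
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator:
            assert sum(self.counts.values()) == self.denominator
            assert abs(sum(self.proportions.values()) - 1.0) < 1e-9


@dataclass
class ProfileEvaluation:
    """Detection outcome of an observed profile against a reference."""

    true_positive: set[str]
    false_positive: set[str]
    false_negative: set[str]
    detection_threshold: float


def _assignment_maps(
    run_a: RunResult, run_b: RunResult, classification: str
) -> tuple[dict[str, str], dict[str, str]]:
    map_a = run_a.assignment_map(classification)
    map_b = run_b.assignment_map(classification)
    if set(map_a) != set(map_b):
        examples = sorted(set(map_a) ^ set(map_b))[:5]
        raise ComparerError(
            f"runs cover different read universes; e.g. {examples}"
        )
    return map_a, map_b


def _is_assigned(outcome: Optional[str]) -> bool:
    return outcome is not None and outcome not in (NO_HITS, UNASSIGNED)


def _summary(categories: Mapping[str, Enum], order: Iterable[Enum]) -> ComparisonSummary:
    counts = {category.value: 0 for category in order}
    for category in categories.values():
        counts[category.value] += 1
    denominator = len(categories)
    proportions = {
        name: (count / denominator if denominator else 0.0)
        for name, count in counts.items()
    }
    return ComparisonSummary(counts, proportions, denominator)


def compare_taxonomic_runs(
    run_a: RunResult,
    run_b: RunResult,
    tree: TaxonomyTree,
    classification: str = "Taxonomy",
) -> tuple[dict[str, TaxComparisonCategory], ComparisonSummary]:
    """Categorize every read assigned by at least one run.

    Both runs must cover the same read universe and assign taxa from the
    same tree flavor. Reads unassigned by both runs are excluded from the
    denominator.
    """
    map_a, map_b = _assignment_maps(run_a, run_b, classification)
    categories: dict[str, TaxComparisonCategory] = {}
    for read_id in map_a:
        a, b = map_a[read_id], map_b[read_id]
        assigned_a, assigned_b = _is_assigned(a), _is_assigned(b)
        if not assigned_a and not assigned_b:
            continue
        if assigned_a and not assigned_b:
            categories[read_id] = TaxComparisonCategory.ONLY_A
        elif assigned_b and not assigned_a:
            categories[read_id] = TaxComparisonCategory.ONLY_B
        else:
            categories[read_id] = _RELATION_TO_CATEGORY[tree.classify_pair(a, b)]
    return categories, _summary(categories, TaxComparisonCategory)


def compare_functional_runs(
    run_a: RunResult, run_b: RunResult, classification: str
) -> tuple[dict[str, FunComparisonCategory], ComparisonSummary]:
    """Four-way partition of reads assigned by at least one run."""
    map_a, map_b = _assignment_maps(run_a, run_b, classification)
    categories: dict[str, FunComparisonCategory] = {}
    for read_id in map_a:
        a, b = map_a[read_id], map_b[read_id]
        assigned_a, assigned_b = _is_assigned(a), _is_assigned(b)
        if not assigned_a and not assigned_b:
            continue
        if assigned_a and not assigned_b:
            categories[read_id] = FunComparisonCategory.ONLY_A
        elif assigned_b and not assigned_a:
            categories[read_id] = FunComparisonCategory.ONLY_B
        elif a == b:
            categories[read_id] = FunComparisonCategory.SAME_CLASS
        else:
            categories[read_id] = FunComparisonCategory.DIFFERENT_CLASS
    return categories, _summary(categories, FunComparisonCategory)


# ---------------------------------------------------------------------------
# mock community evaluation


def evaluate_mock(
    observed: Mapping[str, float],
    reference: Mapping[str, float],
    detection_threshold: float = 0.0,
) -> ProfileEvaluation:
    """Call TP/FP/FN species from an observed signal and a reference profile.

    A species is *detected* when its observed signal is at least the
    threshold; true positives are detected reference species, false
    positives detected non-reference species, false negatives reference
    species that were not detected.
    """
    detected = {
        species for species, signal in observed.items() if signal >= detection_threshold
    }
    reference_set = set(reference)
    return ProfileEvaluation(
        true_positive=detected & reference_set,
        false_positive=detected - reference_set,
        false_negative=reference_set - detected,
        detection_threshold=detection_threshold,
    )


# ---------------------------------------------------------------------------
# rank correlation


def spearman_rho(x: Iterable[float], y: Iterable[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Ties receive average ranks. Raises on length mismatch, fewer than 3
    pairs, or a constant vector (the correlation is undefined there).
    """
    return spearman_test(x, y)[0]


def spearman_test(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Spearman rho plus an approximate large-sample p-value."""
    xa, ya = np.asarray(list(x), dtype=float), np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ComparerError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ComparerError("need at least 3 paired observations")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ComparerError("correlation undefined for a constant vector")
    result = stats.spearmanr(xa, ya)
    return float(result.statistic), float(result.pvalue)


# ---------------------------------------------------------------------------
# tabular outputs


def write_summary_tsv(
    summaries: Mapping[str, ComparisonSummary], sink: IO[str]
) -> None:
    """Write category summaries as ``dataset  category  count  proportion``."""
    sink.write("dataset\tcategory\tcount\tproportion\n")
    for dataset, summary in summaries.items():
        for category, count in summary.counts.items():
            sink.write(
                f"{dataset}\t{category}\t{count}\t{summary.proportions[category]:.6f}\n"
            )


def write_mock_tsv(
    observed: Mapping[str, float],
    evaluation: ProfileEvaluation,
    sink: IO[str],
) -> None:
    """Write per-species mock evaluation: species, signal, TP/FP/FN status."""
    sink.write("species\tsignal\tstatus\n")
    status = {}
    for species in evaluation.true_positive:
        status[species] = "TP"
    for species in evaluation.false_positive:
        status[species] = "FP"
    for species in evaluation.false_negative:
        status[species] = "FN"
    for species in sorted(status):
        sink.write(f"{species}\t{observed.get(species, 0.0):g}\t{status[species]}\n")
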