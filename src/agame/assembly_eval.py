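"""Assembly-vs-reference evaluation metrics for pooled insert data.

Given per-insert completeness classifications, contig-to-reference
alignments and all-vs-all protein searches, this module produces one
summary row per pipeline: category counts, N50 and total length of
end-tag-bearing contigs, percent of the reference assembly covered, and
percent of reference proteins recovered as reciprocal best hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .core_io import AlignmentRecord
from .endtag_assign import CATEGORIES, InsertClassification

__all__ = [
    "EvaluationRow",
    "n50",
    "percent_reference_assembled",
    "best_hits",
    "reciprocal_best_hits",
    "summarize_evaluation",
]


@dataclass
class EvaluationRow:
    """One pipeline's evaluation summary (serialized as a TSV row)."""

    label: str
    complete: int
    two_of_two: int
    one_of_one: int
    partial: int
    pct_assembled: float
    pct_ref_proteins: float
    n50: Optional[int]
    total_length: int

    HEADER = (
        "label\tcomplete\ttwo_of_two\tone_of_one\tpartial\t"
        "pct_assembled\tpct_ref_proteins\tn50\ttotal_length"
    )

    def to_tsv(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.label, self.complete, self.two_of_two, self.one_of_one,
                self.partial, f"{self.pct_assembled:.2f}",
                f"{self.pct_ref_proteins:.2f}",
                "NA" if self.n50 is None else self.n50, self.total_length,
            )
        )


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L with descending cumulative sum >= half the total."""
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for x in ordered:
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def percent_reference_assembled(
    alignments: Iterable[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    eligible_contigs: Optional[set[str]] = None,
) -> float:
    """Percent of reference bases covered by the union of alignment spans.

    Subject intervals are strand-normalized and unioned per reference;
    ``eligible_contigs`` restricts the pool side to (typically)
    end-tag-bearing contigs. Returns 100 x covered / total reference bases.
    """
    trees: dict[str, IntervalTree] = {r: IntervalTree() for r in reference_lengths}
    for rec in alignments:
        if eligible_contigs is not None and rec.query_id not in eligible_contigs:
            continue
        if rec.subject_id not in reference_lengths:
            raise ValueError(f"alignment subject {rec.subject_id!r} not a reference")
        lo, hi = rec.subject_interval
        if hi > reference_lengths[rec.subject_id]:
            raise ValueError(
                f"alignment on {rec.subject_id!r} ends at {hi}, beyond "
                f"reference length {reference_lengths[rec.subject_id]}"
            )
        trees[rec.subject_id].addi(lo, hi)
    covered = 0
    for tree in trees.values():
        tree.merge_overlaps(strict=False)
        covered += sum(iv.end - iv.begin for iv in tree)
    total = sum(reference_lengths.values())
    if total == 0:
        raise ValueError("total reference length is zero")
    return 100.0 * covered / total


def best_hits(alignments: Iterable[AlignmentRecord]) -> dict[str, str]:
    """Best subject per query: max bitscore, then min evalue, then the
    lexicographically smallest subject id."""
    best: dict[str, AlignmentRecord] = {}
    for rec in alignments:
        cur = best.get(rec.query_id)
        if cur is None:
            best[rec.query_id] = rec
            continue
        key = (-rec.bitscore, rec.evalue, rec.subject_id)
        cur_key = (-cur.bitscore, cur.evalue, cur.subject_id)
        if key < cur_key:
            best[rec.query_id] = rec
    return {q: r.subject_id for q, r in best.items()}


def reciprocal_best_hits(
    ref_vs_pool: Iterable[AlignmentRecord],
    pool_vs_ref: Iterable[AlignmentRecord],
) -> set[tuple[str, str]]:
    """Pairs (ref protein, pool protein) that are each other's best hit."""
    fwd = best_hits(ref_vs_pool)
    rev = best_hits(pool_vs_ref)
    return {(r, p) for r, p in fwd.items() if rev.get(p) == r}


def summarize_evaluation(
    classifications: Sequence[InsertClassification],
    tagged_contig_lengths: Mapping[str, int],
    pool_vs_ref_alignments: Iterable[AlignmentRecord],
    reference_lengths: Mapping[str, int],
    ref_vs_pool_proteins: Iterable[AlignmentRecord],
    pool_vs_ref_proteins: Iterable[AlignmentRecord],
    n_reference_proteins: int,
    label: str,
) -> EvaluationRow:
    """Combine the component metrics into one evaluation row.

    ``tagged_contig_lengths`` maps end-tag-bearing contig ids to lengths;
    N50 and total length are computed over those contigs only, and the
    reference-coverage metric is restricted to them as well. An empty
    tagged set yields N50 = None (rendered as NA).
    """
    counts = {c: 0 for c in CATEGORIES}
    for cls in classifications:
        counts[cls.category] += 1
    lengths = list(tagged_contig_lengths.values())
    pct_assembled = percent_reference_assembled(
        pool_vs_ref_alignments,
        reference_lengths,
        eligible_contigs=set(tagged_contig_lengths),
    )
    rbh = reciprocal_best_hits(ref_vs_pool_proteins, pool_vs_ref_proteins)
    if n_reference_proteins <= 0:
        raise ValueError("n_reference_proteins must be positive")
    return EvaluationRow(
        label=label,
        complete=counts["complete"],
        two_of_two=counts["two_of_two"],
        one_of_one=counts["one_of_one"],
        partial=counts["partial"],
        pct_assembled=pct_assembled,
        pct_ref_proteins=100.0 * len(rbh) / n_reference_proteins,
        n50=n50(lengths) if lengths else None,
        total_length=sum(lengths),
    )
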