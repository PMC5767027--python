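"""Anchor Sanger end-tags to contig termini and classify insert assembly.

Each pooled insert carries one or two single-pass Sanger reads from its
termini ("end-tags"). Locating those tags at the ends of assembled
contigs anchors contigs to their clone of origin and tells whether an
insert assembled completely (one contig, both tags at opposite termini),
into multiple tagged fragments, or only partially.

Tags are located by local (Smith-Waterman) alignment of the tag against
both strands of each contig — scoring match +1 / mismatch -1 / gap -2 —
via Biopython's PairwiseAligner, or by consuming precomputed tabular
alignments (BLAST ``-outfmt 6``) when an external search was run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Align import PairwiseAligner

from .core_io import AlignmentRecord, Contig, EndTag, reverse_complement

__all__ = [
    "EndTagParams",
    "EndTagHit",
    "InsertClassification",
    "locate_endtag",
    "assign_endtags",
    "hits_from_alignment_records",
    "classify_inserts",
    "group_contigs_by_insert",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)

#: Completeness categories, mutually exclusive and exhaustive per insert:
#: complete     — one contig carries both tags at opposite termini
#: two_of_two   — both tags anchored, but on two contigs (or without the
#:                opposite-termini geometry on one contig)
#: one_of_one   — the single available tag anchored
#: partial      — two tags available, exactly one anchored
#: unassigned   — no tag anchored
CATEGORIES = ("complete", "two_of_two", "one_of_one", "partial", "unassigned")


@dataclass(frozen=True)
class EndTagParams:
    """Thresholds for accepting a tag-to-contig alignment.

    ``terminal_window=None`` means tag length + 500 bp, allowing for the
    tag plus some assembly slop at the contig end.
    """

    min_identity: float = 90.0
    min_aligned_fraction: float = 0.8
    terminal_window: Optional[int] = None

    def window_for(self, tag: EndTag) -> int:
        if self.terminal_window is not None:
            return self.terminal_window
        return len(tag.sequence) + 500


@dataclass(frozen=True)
class EndTagHit:
    insert_id: str
    end_label: str
    contig_id: str
    terminus: str  # "start" | "end" | "internal"
    strand: str  # "+" | "-"
    pct_identity: float
    aligned_fraction: float
    score: float

    @property
    def is_terminal(self) -> bool:
        return self.terminus != "internal"


@dataclass
class InsertClassification:
    insert_id: str
    n_tags_available: int
    category: str
    contigs: set[str] = field(default_factory=set)


def _make_aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )


def _terminus(t_start: int, t_end: int, contig_len: int, window: int) -> str:
    """Classify the contig-side span [t_start, t_end) against the termini."""
    if t_end <= window:
        return "start"
    if t_start >= contig_len - window:
        return "end"
    return "internal"


def locate_endtag(
    tag: EndTag,
    contig: Contig,
    params: EndTagParams = EndTagParams(),
) -> Optional[EndTagHit]:
    """Best qualifying local alignment of a tag against one contig.

    Both strands are tried; the higher-scoring one wins (plus strand on a
    tie). The hit must clear the identity and aligned-fraction thresholds;
    ``terminus`` records whether the contig-side span lies entirely within
    the terminal window of either contig end. Returns None when no
    alignment qualifies.
    """
    aligner = _make_aligner()
    # conservative score floor implied by the thresholds (a qualifying
    # gapless hit scores >= (2*identity - 1) * covered tag bases; halved
    # for gap slack): lets junk alignments be dropped on score alone,
    # without enumerating their (possibly astronomical) co-optimal paths
    score_floor = max(
        1.0,
        0.5
        * (2.0 * params.min_identity / 100.0 - 1.0)
        * params.min_aligned_fraction
        * len(tag.sequence),
    )
    best = None
    for strand, query in (("+", tag.sequence), ("-", reverse_complement(tag.sequence))):
        alns = aligner.align(contig.sequence, query)
        if alns.score < score_floor:
            continue
        aln = alns[0]
        if best is None or aln.score > best[1].score:
            best = (strand, aln)
    if best is None:
        return None
    strand, aln = best
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    pct_identity = 100.0 * counts.identities / columns if columns else 0.0
    aligned_fraction = (counts.identities + counts.mismatches) / len(tag.sequence)
    if pct_identity < params.min_identity:
        return None
    if aligned_fraction < params.min_aligned_fraction:
        return None
    blocks = aln.aligned[0]  # target (contig) side
    t_start, t_end = int(blocks[0][0]), int(blocks[-1][1])
    terminus = _terminus(t_start, t_end, len(contig), params.window_for(tag))
    return EndTagHit(
        insert_id=tag.insert_id,
        end_label=tag.end_label,
        contig_id=contig.id,
        terminus=terminus,
        strand=strand,
        pct_identity=pct_identity,
        aligned_fraction=aligned_fraction,
        score=float(aln.score),
    )


def hits_from_alignment_records(
    records: Iterable[AlignmentRecord],
    tags: Sequence[EndTag],
    contigs: Sequence[Contig],
    params: EndTagParams = EndTagParams(),
) -> list[EndTagHit]:
    """Convert external tag-vs-contig tabular alignments into hits.

    Query ids must follow the ``<insert_id>__<L|R>`` convention; subject
    ids name contigs. The bitscore stands in for the alignment score.
    """
    tag_by_id = {t.tag_id: t for t in tags}
    contig_by_id = {c.id: c for c in contigs}
    hits: list[EndTagHit] = []
    for rec in records:
        tag = tag_by_id.get(rec.query_id)
        contig = contig_by_id.get(rec.subject_id)
        if tag is None or contig is None:
            logger.warning(
                "alignment %s -> %s does not match any tag/contig; skipped",
                rec.query_id, rec.subject_id,
            )
            continue
        aligned_fraction = rec.aln_length / len(tag.sequence)
        if rec.pct_identity < params.min_identity:
            continue
        if aligned_fraction < params.min_aligned_fraction:
            continue
        lo, hi = rec.subject_interval
        terminus = _terminus(lo, hi, len(contig), params.window_for(tag))
        hits.append(
            EndTagHit(
                insert_id=tag.insert_id,
                end_label=tag.end_label,
                contig_id=contig.id,
                terminus=terminus,
                strand="-" if rec.minus_strand else "+",
                pct_identity=rec.pct_identity,
                aligned_fraction=min(aligned_fraction, 1.0),
                score=rec.bitscore,
            )
        )
    return hits


def assign_endtags(
    tags: Sequence[EndTag],
    contigs: Sequence[Contig],
    params: EndTagParams = EndTagParams(),
    precomputed_hits: Optional[Sequence[EndTagHit]] = None,
) -> list[EndTagHit]:
    """Assign each tag its single best terminal hit across all contigs.

    Ties break toward higher identity, then the lexicographically smaller
    contig id. Internal hits never qualify; a tag without a terminal hit
    is simply absent from the result.
    """
    by_tag: dict[tuple[str, str], list[EndTagHit]] = {}
    if precomputed_hits is not None:
        candidates = [h for h in precomputed_hits if h.is_terminal]
    else:
        candidates = []
        for tag in tags:
            for contig in contigs:
                hit = locate_endtag(tag, contig, params)
                if hit is not None and hit.is_terminal:
                    candidates.append(hit)
    for h in candidates:
        by_tag.setdefault((h.insert_id, h.end_label), []).append(h)
    best: list[EndTagHit] = []
    for key in sorted(by_tag):
        hits = by_tag[key]
        hits.sort(key=lambda h: (-h.score, -h.pct_identity, h.contig_id))
        best.append(hits[0])
    return best


def classify_inserts(
    hits: Sequence[EndTagHit],
    tag_inventory: Mapping[str, int],
) -> list[InsertClassification]:
    """Classify each insert's assembly completeness from its assigned hits.

    ``tag_inventory`` maps insert_id -> number of end-tags available (1 or
    2); every insert in the inventory receives exactly one category, so
    the category counts partition the insert set.
    """
    by_insert: dict[str, list[EndTagHit]] = {}
    for h in hits:
        if h.insert_id not in tag_inventory:
            raise ValueError(
                f"hit references insert {h.insert_id!r} absent from inventory"
            )
        by_insert.setdefault(h.insert_id, []).append(h)
    out: list[InsertClassification] = []
    for insert_id in sorted(tag_inventory):
        n_avail = tag_inventory[insert_id]
        if n_avail not in (1, 2):
            raise ValueError(
                f"insert {insert_id!r}: inventory must be 1 or 2 tags, got {n_avail}"
            )
        ihits = by_insert.get(insert_id, [])
        assigned = {h.end_label: h for h in ihits}
        contigs = {h.contig_id for h in ihits}
        if n_avail == 1:
            category = "one_of_one" if assigned else "unassigned"
        elif len(assigned) == 2:
            hl, hr = assigned["L"], assigned["R"]
            same_contig = hl.contig_id == hr.contig_id
            opposite = {hl.terminus, hr.terminus} == {"start", "end"}
            category = "complete" if (same_contig and opposite) else "two_of_two"
        elif len(assigned) == 1:
            category = "partial"
        else:
            category = "unassigned"
        out.append(
            InsertClassification(
                insert_id=insert_id,
                n_tags_available=n_avail,
                category=category,
                contigs=contigs,
            )
        )
    return out


def group_contigs_by_insert(
    classifications: Sequence[InsertClassification],
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Group end-tag-bearing contigs by clone of origin.

    A contig claimed by tags of two different inserts is a conflict: it is
    assigned to neither insert, reported in the second return value
    (contig id -> claiming inserts) and logged.
    """
    claims: dict[str, set[str]] = {}
    for cls in classifications:
        for contig_id in cls.contigs:
            claims.setdefault(contig_id, set()).add(cls.insert_id)
    conflicts = {c: inserts for c, inserts in claims.items() if len(inserts) > 1}
    for contig_id, inserts in sorted(conflicts.items()):
        logger.warning(
            "contig %s is claimed by inserts %s; assigned to none",
            contig_id, ",".join(sorted(inserts)),
        )
    groups = {
        cls.insert_id: {c for c in cls.contigs if c not in conflicts}
        for cls in classifications
    }
    return groups, conflicts
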