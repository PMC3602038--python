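"""Combine evidence tracks into scored, non-overlapping consensus exonic regions.

This is the heart of the array design: gene predictions, transcript
alignments, protein homology and cross-species conservation each vote
for exonic sequence, while repeats vote against it.  Supporting
intervals that overlap by at least one base are clustered transitively;
each cluster becomes one candidate region spanning the union of its
intervals, scored 0-7 by the number of distinct supporting sources with
a one-point penalty for regions shorter than 100 bp.  Filtering then
removes regions supported only by ESTs, ab initio-only predictions that
touch repeats, transposable-element protein matches, and regions more
than 25% covered by repeats (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .repeat_masking import MaskAnnotation, merge_intervals, overlap_fraction
from .seq_formats import DesignParams, GenomicInterval

__all__ = [
    "DEFAULT_SOURCES",
    "SOURCE_PRIORITY",
    "EvidenceTrack",
    "ExonicRegion",
    "ExonEval",
    "build_consensus_regions",
    "filter_regions",
    "flag_te_regions",
    "assign_strand",
    "rank_regions",
    "exon_eval",
]

#: Default configured evidence sources (at most 7; the score scale is 0-7).
DEFAULT_SOURCES = (
    "augustus",
    "fgenesh",
    "tobacco_est",
    "tobacco_cdna",
    "protein_homology",
    "conservation",
    "related_cdna",
)

#: Priority weight per source for strand voting: transcript evidence
#: outranks ab initio predictions, which outrank homology, which
#: outranks conservation.
SOURCE_PRIORITY: Dict[str, int] = {
    "tobacco_est": 4,
    "tobacco_cdna": 4,
    "related_cdna": 4,
    "augustus": 3,
    "fgenesh": 3,
    "protein_homology": 2,
    "conservation": 1,
}

MAX_SCORE = 7


@dataclass
class EvidenceTrack:
    """One evidence source's intervals on the contigs under consideration."""

    source_id: str
    intervals: List[GenomicInterval]
    polarity: str = "supporting"

    def __post_init__(self) -> None:
        if self.polarity not in ("supporting", "negative"):
            raise ValueError(f"invalid polarity {self.polarity!r}")


@dataclass
class ExonicRegion:
    """A strand-annotated consensus interval with its evidence and score."""

    interval: GenomicInterval
    supporting_sources: frozenset
    score: int
    short_penalized: bool
    repeat_overlap_frac: float
    origin: str = "genomic"
    te_protein: bool = False
    region_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.interval)


def _make_region(
    interval: GenomicInterval,
    sources: Iterable[str],
    repeat_frac: float,
    params: DesignParams,
    origin: str = "genomic",
) -> ExonicRegion:
    sources = frozenset(sources)
    short = len(interval) < params.short_exon_penalty_len
    score = len(sources) - (1 if short else 0)
    score = max(0, min(MAX_SCORE, score))
    return ExonicRegion(
        interval=interval,
        supporting_sources=sources,
        score=score,
        short_penalized=short,
        repeat_overlap_frac=repeat_frac,
        origin=origin,
    )


def build_consensus_regions(
    tracks: Sequence[EvidenceTrack],
    params: Optional[DesignParams] = None,
) -> List[ExonicRegion]:
    """Cluster supporting evidence into non-overlapping scored regions.

    Intervals from supporting tracks are clustered transitively when
    their coverage is contiguous (overlapping or directly adjacent;
    strand-agnostic); each cluster yields one region spanning the
    union, supported by every source contributing at least one
    interval, identically to a positionwise coverage-run construction.  Regions shorter than
    ``min_exon_len`` are dropped; regions shorter than
    ``short_exon_penalty_len`` lose one score point.  The repeat overlap
    fraction is computed against the union of negative tracks.
    """
    params = params or DesignParams()
    seen_sources = set()
    for t in tracks:
        if t.source_id in seen_sources:
            raise ValueError(f"duplicate source track {t.source_id!r}")
        seen_sources.add(t.source_id)

    supporting = [(iv, t.source_id) for t in tracks if t.polarity == "supporting"
                  for iv in t.intervals]
    negative_masks = [
        MaskAnnotation(interval=iv, kind="complex", label=t.source_id)
        for t in tracks
        if t.polarity == "negative"
        for iv in t.intervals
    ]

    by_contig: Dict[str, List[Tuple[GenomicInterval, str]]] = {}
    for iv, src in supporting:
        by_contig.setdefault(iv.seq_id, []).append((iv, src))

    regions: List[ExonicRegion] = []
    for contig in sorted(by_contig):
        items = sorted(by_contig[contig], key=lambda x: (x[0].start, x[0].end))
        cluster: List[Tuple[GenomicInterval, str]] = []
        cluster_end = None
        for iv, src in items:
            if cluster and iv.start > cluster_end:
                regions.extend(
                    _finish_cluster(contig, cluster, negative_masks, params)
                )
                cluster = []
            cluster.append((iv, src))
            cluster_end = iv.end if cluster_end is None or len(cluster) == 1 else max(cluster_end, iv.end)
        if cluster:
            regions.extend(_finish_cluster(contig, cluster, negative_masks, params))
    regions.sort(key=lambda r: (r.interval.seq_id, r.interval.start))
    return regions


def _finish_cluster(
    contig: str,
    cluster: List[Tuple[GenomicInterval, str]],
    negative_masks: List[MaskAnnotation],
    params: DesignParams,
) -> List[ExonicRegion]:
    start = min(iv.start for iv, _ in cluster)
    end = max(iv.end for iv, _ in cluster)
    if end - start < params.min_exon_len:
        return []
    interval = GenomicInterval(contig, start, end)
    frac = overlap_fraction(interval, negative_masks)
    return [_make_region(interval, (src for _, src in cluster), frac, params)]


def flag_te_regions(
    regions: Sequence[ExonicRegion], te_track: Sequence[GenomicInterval]
) -> List[ExonicRegion]:
    """Mark regions overlapping a precomputed transposable-element label track."""
    out = []
    for r in regions:
        hit = any(r.interval.overlaps(iv) for iv in te_track)
        out.append(replace(r, te_protein=hit) if hit != r.te_protein else r)
    return out


def filter_regions(
    regions: Sequence[ExonicRegion],
    params: Optional[DesignParams] = None,
    est_source: str = "tobacco_est",
    ab_initio_only_source: str = "fgenesh",
) -> Tuple[List[ExonicRegion], List[Tuple[ExonicRegion, str]]]:
    """Apply the evidence-based removal rules; returns (kept, removals).

    Rules, first match logged:
      a. genomic regions with no supporting evidence other than ESTs;
      b. regions supported only by the ab initio predictor that overlap
         a repeat at all;
      c. regions flagged as transposable-element protein matches;
      d. regions overlapping repeats by strictly more than the maximum
         repeat overlap fraction.
    """
    params = params or DesignParams()
    kept: List[ExonicRegion] = []
    removed: List[Tuple[ExonicRegion, str]] = []
    for r in regions:
        if r.origin == "genomic" and r.supporting_sources <= {est_source}:
            removed.append((r, "a_est_only"))
        elif r.supporting_sources == {ab_initio_only_source} and r.repeat_overlap_frac > 0:
            removed.append((r, "b_fgenesh_only_on_repeat"))
        elif r.te_protein:
            removed.append((r, "c_te_protein"))
        elif r.repeat_overlap_frac > params.max_repeat_overlap_frac:
            removed.append((r, "d_repeat_overlap"))
        else:
            kept.append(r)
    return kept, removed


def assign_strand(
    region: ExonicRegion,
    tracks: Sequence[EvidenceTrack],
    priority: Optional[Dict[str, int]] = None,
) -> str:
    """Majority strand vote over supporting intervals, priority-weighted.

    Each stranded supporting interval overlapping the region contributes
    its source's priority weight to its strand; the heavier strand wins,
    with exact ties broken by the single highest-priority stranded
    source.  ``?`` is returned only when no stranded evidence overlaps.
    """
    priority = priority or SOURCE_PRIORITY
    votes = {"+": 0, "-": 0}
    best_priority_strand: Tuple[int, str] = (0, "?")
    for t in tracks:
        if t.polarity != "supporting" or t.source_id not in region.supporting_sources:
            continue
        w = priority.get(t.source_id, 1)
        for iv in t.intervals:
            if iv.strand in ("+", "-") and iv.overlaps(region.interval):
                votes[iv.strand] += w
                if w > best_priority_strand[0]:
                    best_priority_strand = (w, iv.strand)
    if votes["+"] == votes["-"] == 0:
        return "?"
    if votes["+"] > votes["-"]:
        return "+"
    if votes["-"] > votes["+"]:
        return "-"
    return best_priority_strand[1]


def rank_regions(
    regions: Sequence[ExonicRegion], target_count: Optional[int] = None
) -> List[ExonicRegion]:
    """Stable sort by (score desc, length desc, contig, start); optional cut."""
    if target_count is not None and target_count < 0:
        raise ValueError("target_count must be >= 0")
    ranked = sorted(
        regions,
        key=lambda r: (-r.score, -len(r), r.interval.seq_id, r.interval.start),
    )
    if target_count is not None:
        ranked = ranked[:target_count]
    return ranked


@dataclass(frozen=True)
class ExonEval:
    """Exon-level evaluation: Sn = matched/|truth|, Sp = matched/|predicted|.

    "Specificity" follows the gene-prediction convention (it is a
    precision).  When there are no predictions Sp is undefined and
    reported as 0 with ``predicted_empty`` set.
    """

    sensitivity: float
    specificity: float
    n_matched: int
    n_truth: int
    n_predicted: int
    predicted_empty: bool = False


def exon_eval(
    predicted: Sequence[GenomicInterval],
    truth: Sequence[GenomicInterval],
    tolerance: int = 0,
) -> ExonEval:
    """Evaluate predicted exons against truth by boundary matching.

    With ``tolerance`` 0 matching is exact on (seq_id, start, end);
    otherwise a truth exon matches a predicted exon when both boundaries
    agree within ``tolerance`` bp (one-to-one greedy matching).
    """
    if not truth:
        raise ValueError("empty truth set: sensitivity undefined")
    if tolerance == 0:
        pred_keys = {(iv.seq_id, iv.start, iv.end) for iv in predicted}
        truth_keys = {(iv.seq_id, iv.start, iv.end) for iv in truth}
        matched = len(pred_keys & truth_keys)
    else:
        used = [False] * len(predicted)
        matched = 0
        for t in truth:
            for i, p in enumerate(predicted):
                if used[i] or p.seq_id != t.seq_id:
                    continue
                if abs(p.start - t.start) <= tolerance and abs(p.end - t.end) <= tolerance:
                    used[i] = True
                    matched += 1
                    break
    n_pred = len(predicted)
    return ExonEval(
        sensitivity=matched / len(truth),
        specificity=(matched / n_pred) if n_pred else 0.0,
        n_matched=matched,
        n_truth=len(truth),
        n_predicted=n_pred,
        predicted_empty=n_pred == 0,
    )
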