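"""EST-contig branch: repeat/TE filtering, redundancy removal, ORF search.

Assembled EST contigs contribute transcript fragments that the genomic
assembly misses.  Each contig is first screened against the same
repeat/transposable-element criteria as the genomic candidates, then
dropped when it is redundant with a genomic exon candidate (98%
identity, genomic precedence), and finally required to contain an open
reading frame of at least 150 bp from which its coding strand is
inferred.  Every status transition is tallied in a ledger that
conserves totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib

from ._align import revcomp
from .repeat_masking import MaskAnnotation, find_tandem_repeats, mask_with_library, overlap_fraction
from .seq_formats import DesignParams, GenomicInterval

__all__ = [
    "ESTContig",
    "Orf",
    "CandidateSet",
    "est_accounting",
    "longest_orf",
    "redundancy_filter",
    "te_repeat_filter",
    "build_candidate_set",
    "run_est_pipeline",
    "sequence_identity",
]

STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated, stop-terminated reading frame.

    Coordinates are on the forward strand, half-open, stop codon
    included; ``frame`` is the codon phase (0-2) on the reading strand.
    """

    start: int
    end: int
    strand: str
    frame: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ESTContig:
    """An EST contig with its pipeline status and (when kept) its ORF."""

    id: str
    seq: str
    status: str = "kept"  # kept | te_filtered | redundant | no_orf
    orf: Optional[Orf] = None


def longest_orf(seq: str, min_orf_len: int = 150) -> Optional[Orf]:
    """Longest ATG→stop span over 3 frames x 2 strands, or None.

    The stop codon counts toward the length; ties are broken in favor of
    the + strand, then the smallest forward-strand start.  Within one
    frame segment (between stops) the reported ORF starts at the first
    ATG, which is the longest choice.
    """
    candidates: List[Orf] = []
    n = len(seq)
    for strand in ("+", "-"):
        s = seq.upper() if strand == "+" else revcomp(seq.upper())
        for frame in range(3):
            first_atg = None
            for pos in range(frame, n - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOPS:
                    if first_atg is not None:
                        a, b = first_atg, pos + 3  # stranded coords
                        if b - a >= min_orf_len:
                            if strand == "+":
                                candidates.append(Orf(a, b, "+", frame))
                            else:
                                candidates.append(Orf(n - b, n - a, "-", frame))
                        first_atg = None
                elif codon == "ATG" and first_atg is None:
                    first_atg = pos
    if not candidates:
        return None
    return max(candidates, key=lambda o: (len(o), o.strand == "+", -o.start))


def sequence_identity(a: str, b: str) -> float:
    """Identity of the shorter sequence aligned end-to-end into the longer.

    Uses a glocal (infix) edit-distance alignment on the better of the
    two orientations: identity = 1 - dist / len(shorter).  This is the
    redundancy notion used throughout: a full-length high-identity copy
    scores near 1 even when embedded in a longer partner, while a
    sequence of which only a small part matches scores low.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    short, long_ = short.upper(), long_.upper()
    best = 0.0
    for query in (short, revcomp(short)):
        dist = edlib.align(query, long_, mode="HW", task="distance")["editDistance"]
        if dist >= 0:
            best = max(best, 1 - dist / len(short))
    return best


def _shares_kmer(a: str, b: str, k: int = 12) -> bool:
    a, b = a.upper(), b.upper()
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    rc = revcomp(a)
    kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def redundancy_filter(
    est_contigs: Sequence[ESTContig],
    genomic_region_seqs: Dict[str, str],
    redundancy_identity: float = 0.98,
) -> List[ESTContig]:
    """Flag ESTs redundant with a genomic exon candidate; genomic wins.

    An EST is redundant when some genomic candidate sequence matches it
    at identity >= the threshold over the full length of the shorter
    partner (either orientation).  Only contigs still in status ``kept``
    are reconsidered; the decision is per-contig, hence independent of
    input order.
    """
    out: List[ESTContig] = []
    for est in est_contigs:
        if est.status != "kept":
            out.append(est)
            continue
        redundant = False
        for gseq in genomic_region_seqs.values():
            if not _shares_kmer(est.seq, gseq):
                continue
            if sequence_identity(est.seq, gseq) >= redundancy_identity:
                redundant = True
                break
        out.append(
            ESTContig(est.id, est.seq, "redundant" if redundant else "kept", est.orf)
        )
    return out


def te_repeat_filter(
    est_contigs: Sequence[ESTContig],
    repeat_masks: Dict[str, List[MaskAnnotation]],
    te_labels: Optional[set] = None,
    max_repeat_overlap_frac: float = 0.25,
) -> List[ESTContig]:
    """Flag contigs >25% repeat-masked (strict) or labeled as TE proteins."""
    te_labels = te_labels or set()
    out: List[ESTContig] = []
    for est in est_contigs:
        if est.status != "kept":
            out.append(est)
            continue
        whole = GenomicInterval(est.id, 0, len(est.seq))
        frac = overlap_fraction(whole, repeat_masks.get(est.id, []))
        filtered = est.id in te_labels or frac > max_repeat_overlap_frac
        out.append(
            ESTContig(est.id, est.seq, "te_filtered" if filtered else "kept", est.orf)
        )
    return out


def run_est_pipeline(
    est_contigs: Sequence[ESTContig],
    genomic_region_seqs: Dict[str, str],
    repeat_library: Optional[Dict[str, str]] = None,
    te_labels: Optional[set] = None,
    params: Optional[DesignParams] = None,
) -> Tuple[List[ESTContig], Dict[str, int]]:
    """Full EST branch: TE/repeat filter → redundancy → ORF requirement.

    Repeat masks are computed per contig (tandem arrays plus repeat
    library matches).  Returns contigs with final statuses and a ledger
    whose counts conserve the input total.
    """
    params = params or DesignParams()
    masks: Dict[str, List[MaskAnnotation]] = {}
    for est in est_contigs:
        m = find_tandem_repeats(est.seq, seq_id=est.id)
        if repeat_library:
            m = m + mask_with_library(est.seq, repeat_library, seq_id=est.id)
        masks[est.id] = m
    staged = te_repeat_filter(
        est_contigs, masks, te_labels, params.max_repeat_overlap_frac
    )
    staged = redundancy_filter(staged, genomic_region_seqs, params.redundancy_identity)
    final: List[ESTContig] = []
    for est in staged:
        if est.status != "kept":
            final.append(est)
            continue
        orf = longest_orf(est.seq, params.min_orf_len)
        if orf is None:
            final.append(ESTContig(est.id, est.seq, "no_orf", None))
        else:
            final.append(ESTContig(est.id, est.seq, "kept", orf))
    ledger = {"input": len(est_contigs)}
    for status in ("te_filtered", "redundant", "no_orf", "kept"):
        ledger[status] = sum(1 for e in final if e.status == status)
    assert ledger["input"] == sum(ledger[s] for s in ("te_filtered", "redundant", "no_orf", "kept"))
    return final, ledger


def est_accounting(total: int, te_filtered: int, redundant: int) -> int:
    """Contigs entering the ORF search after TE and redundancy removal."""
    remaining = total - te_filtered - redundant
    if remaining < 0:
        raise ValueError("removals exceed total")
    return remaining


@dataclass
class CandidateSet:
    """The merged genomic + EST exon-candidate set with its ledger."""

    members: List[Tuple[str, str, str]] = field(default_factory=list)
    #: each member is (member_id, origin, sequence)
    ledger: Dict[str, int] = field(default_factory=dict)


def build_candidate_set(
    genomic_regions: Dict[str, str],
    genomic_scores: Optional[Dict[str, int]] = None,
    est_contigs: Sequence[ESTContig] = (),
    params: Optional[DesignParams] = None,
) -> CandidateSet:
    """Join genomic and EST candidates; drop intra-set redundancy at 98%.

    Precedence among redundant members: genomic origin first, then
    higher evidence score, then longer sequence, then lexicographic id
    (deterministic).  Only EST contigs in status ``kept`` (ORF-screened)
    are merged.  The ledger records inputs, every EST status, and the
    number of redundancy casualties during the join.
    """
    params = params or DesignParams()
    genomic_scores = genomic_scores or {}
    entries: List[Tuple[str, str, str]] = [
        (gid, "genomic", seq) for gid, seq in genomic_regions.items()
    ]
    est_in = list(est_contigs)
    entries += [(e.id, "est", e.seq) for e in est_in if e.status == "kept"]

    def precedence(entry):
        mid, origin, seq = entry
        return (0 if origin == "genomic" else 1, -genomic_scores.get(mid, 0), -len(seq), mid)

    ordered = sorted(entries, key=precedence)
    kept: List[Tuple[str, str, str]] = []
    dropped = 0
    for entry in ordered:
        _, _, seq = entry
        redundant = False
        for _, _, kseq in kept:
            if not _shares_kmer(seq, kseq):
                continue
            if sequence_identity(seq, kseq) >= params.redundancy_identity:
                redundant = True
                break
        if redundant:
            dropped += 1
        else:
            kept.append(entry)

    ledger = {
        "genomic_in": len(genomic_regions),
        "est_in": len(est_in),
        "est_te_filtered": sum(1 for e in est_in if e.status == "te_filtered"),
        "est_redundant": sum(1 for e in est_in if e.status == "redundant"),
        "est_no_orf": sum(1 for e in est_in if e.status == "no_orf"),
        "est_kept": sum(1 for e in est_in if e.status == "kept"),
        "join_redundant": dropped,
        "final": len(kept),
    }
    assert ledger["est_in"] == (
        ledger["est_te_filtered"] + ledger["est_redundant"]
        + ledger["est_no_orf"] + ledger["est_kept"]
    )
    assert ledger["final"] == ledger["genomic_in"] + ledger["est_kept"] - dropped
    return CandidateSet(members=kept, ledger=ledger)
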