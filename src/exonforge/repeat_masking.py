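"""Tandem-repeat detection, library-based repeat masking and overlap math.

Repeats are negative evidence for exons.  Simple repeats are perfect
tandem arrays (period 1-6 by default); complex repeats are matches to a
library of known repeat families.  Masking is soft: positions are
lowercased, sequence content and length are preserved, and the same
intervals travel as explicit annotations for overlap arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from . import _align
from .seq_formats import GenomicInterval

__all__ = [
    "MaskAnnotation",
    "find_tandem_repeats",
    "mask_with_library",
    "apply_softmask",
    "overlap_fraction",
    "merge_intervals",
]


@dataclass(frozen=True)
class MaskAnnotation:
    """A masked interval with its repeat class and a family/period label."""

    interval: GenomicInterval
    kind: str  # "simple" or "complex"
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("simple", "complex"):
            raise ValueError(f"invalid mask kind {self.kind!r}")


def merge_intervals(spans: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of (start, end) spans as a sorted list of disjoint spans."""
    spans = sorted(spans)
    if not spans:
        return []
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def find_tandem_repeats(
    seq: str,
    seq_id: str = "seq",
    min_period: int = 1,
    max_period: int = 6,
    min_total_len: int = 18,
    min_copies: int = 4,
) -> List[MaskAnnotation]:
    """Maximal perfect tandem arrays with short periods.

    An array of period p is a maximal run where ``seq[i] == seq[i - p]``;
    its total length must reach ``min_total_len`` and span at least
    ``min_copies`` repeat units (copies may be fractional for the final
    partial unit, so the requirement is total length >= min_copies * p).
    Overlapping qualifying arrays (across periods and phases) are merged;
    the label records the smallest contributing period.
    """
    n = len(seq)
    b = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    raw: List[Tuple[int, int, int]] = []  # (start, end, period)
    for p in range(min_period, max_period + 1):
        if n < p + 1:
            break
        eq = b[p:] == b[:-p]
        # runs of True in eq; a run over eq-indices [i, j) covers seq [i, j + p)
        if not eq.any():
            continue
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        for i, j in zip(starts, ends):
            total = (j - i) + p
            if total >= min_total_len and total >= min_copies * p:
                raw.append((int(i), int(i) + total, p))
    merged = merge_intervals((s, e) for s, e, _ in raw)
    annotations = []
    for s, e in merged:
        periods = sorted(p for rs, re, p in raw if rs < e and s < re)
        annotations.append(
            MaskAnnotation(
                interval=GenomicInterval(seq_id, s, e),
                kind="simple",
                label=f"period={periods[0]}",
            )
        )
    return annotations


def mask_with_library(
    seq: str,
    repeat_library: Dict[str, str],
    seq_id: str = "seq",
    min_identity: float = 0.8,
    min_len: int = 50,
    kmer: int = 12,
) -> List[MaskAnnotation]:
    """Intervals matching known repeat families, both strands, labeled by family.

    Hits are maximum-scoring ungapped windows, so mask boundaries hug
    the repeat copy instead of bleeding into flanking sequence.
    Overlapping hits from the same family are merged; hits from
    different families are kept as separate annotations (their union is
    what overlap arithmetic consumes).
    """
    if not repeat_library:
        return []
    hits = _align.find_mask_hits(seq, repeat_library, min_identity, min_len, k=kmer)
    by_family: Dict[str, List[Tuple[int, int]]] = {}
    for h in hits:
        by_family.setdefault(h.ref_id, []).append((h.q_start, h.q_end))
    annotations: List[MaskAnnotation] = []
    for family in sorted(by_family):
        for s, e in merge_intervals(by_family[family]):
            annotations.append(
                MaskAnnotation(
                    interval=GenomicInterval(seq_id, s, e),
                    kind="complex",
                    label=family,
                )
            )
    annotations.sort(key=lambda a: (a.interval.start, a.interval.end))
    return annotations


def apply_softmask(seq: str, masks: Sequence[MaskAnnotation]) -> str:
    """Lowercase masked positions; letters and length are preserved."""
    if not masks:
        return seq
    flags = np.zeros(len(seq), dtype=bool)
    for m in masks:
        if m.interval.start < 0 or m.interval.end > len(seq):
            raise ValueError(
                f"mask [{m.interval.start}, {m.interval.end}) outside sequence "
                f"of length {len(seq)}"
            )
        flags[m.interval.start : m.interval.end] = True
    chars = list(seq)
    for i in np.nonzero(flags)[0]:
        chars[i] = chars[i].lower()
    return "".join(chars)


def overlap_fraction(
    interval: GenomicInterval, masks: Sequence[MaskAnnotation]
) -> float:
    """Fraction of ``interval`` covered by the union of mask intervals.

    Masks on other sequences are ignored; union means no double counting
    when masks overlap each other.
    """
    spans = [
        (max(interval.start, m.interval.start), min(interval.end, m.interval.end))
        for m in masks
        if m.interval.seq_id == interval.seq_id
        and m.interval.start < interval.end
        and interval.start < m.interval.end
    ]
    covered = sum(e - s for s, e in merge_intervals(spans))
    return covered / len(interval)
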