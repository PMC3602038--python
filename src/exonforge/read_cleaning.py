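"""Genome-survey-sequence cleaning cascade with conservation-checked accounting.

Single-pass genomic reads from methyl-filtered libraries carry cloning
vector, bacterial contamination and organellar DNA that must be removed
before assembly and gene prediction.  The cascade applies, in a fixed
order, a vector screen, a contaminant screen, an organelle screen, a
minimum-length rule, an undetermined-base rule and end trimming, and
tallies every removal in a ledger whose counts always conserve the
input total (input = kept + sum of removals).  Because the order is
fixed and the first matching category wins, the per-category counts are
disjoint and well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from . import _align
from .seq_formats import DesignParams, Read

__all__ = [
    "CATEGORIES",
    "CleaningLedger",
    "ScreenHit",
    "ScreenParams",
    "screen_vector",
    "screen_reference",
    "ambiguity_fraction",
    "trim_ends",
    "clean_reads",
]

#: Removal categories, in cascade order.
CATEGORIES = ("vector", "contaminant", "organelle", "short", "ambiguous", "trim_casualty")


@dataclass
class CleaningLedger:
    """Per-category removal counts with a conservation guarantee."""

    input_count: int = 0
    removed: Dict[str, int] = field(default_factory=lambda: {c: 0 for c in CATEGORIES})
    kept_count: int = 0

    def __post_init__(self) -> None:
        for c in CATEGORIES:
            self.removed.setdefault(c, 0)

    @property
    def total_removed(self) -> int:
        return sum(self.removed.values())

    def conserves(self) -> bool:
        return (
            self.input_count == self.kept_count + self.total_removed
            and self.kept_count >= 0
            and all(v >= 0 for v in self.removed.values())
        )

    @classmethod
    def from_counts(cls, input_count: int, removed: Dict[str, int]) -> "CleaningLedger":
        """Build a ledger from an input total and removal counts.

        ``kept_count`` is derived so conservation holds by construction;
        negative results raise ``ValueError``.
        """
        full = {c: 0 for c in CATEGORIES}
        for key, value in removed.items():
            if key not in full:
                raise ValueError(f"unknown removal category {key!r}")
            if value < 0:
                raise ValueError(f"negative count for {key!r}")
            full[key] = int(value)
        kept = input_count - sum(full.values())
        if kept < 0:
            raise ValueError("removals exceed input count")
        return cls(input_count=int(input_count), removed=full, kept_count=kept)

    def as_dict(self) -> Dict[str, int]:
        d = {"input": self.input_count}
        d.update({f"removed_{c}": self.removed[c] for c in CATEGORIES})
        d["kept"] = self.kept_count
        return d


@dataclass(frozen=True)
class ScreenHit:
    """Best library match explaining a read's removal."""

    read_id: str
    library_record_id: str
    start: int
    end: int
    identity: float
    kind: str  # "vector", "contaminant" or "organelle"

    def __post_init__(self) -> None:
        if not (0 <= self.identity <= 1):
            raise ValueError(f"identity {self.identity} outside [0, 1]")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("hit interval invalid")


@dataclass(frozen=True)
class ScreenParams:
    """Similarity-screen thresholds (seqclean-like defaults).

    A vector/contaminant hit qualifies at ``min_hit_len_internal`` bp
    anywhere in the read, or at the laxer ``min_hit_len_end`` bp when it
    touches the terminal ``end_zone`` bp of the read, where vector
    splices live.  Reference (contaminant/organelle) screening instead
    requires the read itself to be covered to ``min_cov`` by qualifying
    matches.
    """

    min_identity: float = 0.96
    min_hit_len_end: int = 30
    min_hit_len_internal: int = 60
    end_zone: int = 60
    min_cov: float = 0.8
    kmer: int = 12


def screen_vector(
    read: Read,
    vector_library: Dict[str, str],
    min_identity: float = 0.96,
    min_hit_len: int = 30,
    screen: Optional[ScreenParams] = None,
) -> Optional[ScreenHit]:
    """Best vector match in the read, on either strand, or None.

    With the default ``min_hit_len`` the end-zone rule is implied; pass
    a :class:`ScreenParams` to distinguish end and internal thresholds.
    """
    if not read.bases:
        raise ValueError(f"read {read.id!r} is empty")
    if not vector_library:
        raise ValueError("empty vector library")
    sp = screen or ScreenParams(min_identity=min_identity, min_hit_len_end=min_hit_len)
    short_min = min(sp.min_hit_len_end, sp.min_hit_len_internal)
    hits = _align.find_hits(
        read.bases, vector_library, sp.min_identity, short_min, k=sp.kmer
    )
    n = len(read.bases)
    qualifying = [
        h
        for h in hits
        if h.length >= sp.min_hit_len_internal
        or (h.q_start < sp.end_zone or h.q_end > n - sp.end_zone)
    ]
    if not qualifying:
        return None
    best = max(qualifying, key=lambda h: (h.length, h.identity, h.ref_id, -h.q_start))
    return ScreenHit(
        read_id=read.id,
        library_record_id=best.ref_id,
        start=best.q_start,
        end=best.q_end,
        identity=best.identity,
        kind="vector",
    )


def screen_reference(
    read: Read,
    reference_set: Dict[str, str],
    min_identity: float = 0.96,
    min_cov: float = 0.8,
    kind: str = "contaminant",
    kmer: int = 12,
) -> Optional[ScreenHit]:
    """Call the read a reference copy when matches cover >= min_cov of it."""
    if not read.bases:
        raise ValueError(f"read {read.id!r} is empty")
    if not reference_set:
        return None
    min_len = min(60, len(read.bases))
    hits = _align.find_hits(read.bases, reference_set, min_identity, min_len, k=kmer)
    if not hits:
        return None
    if _align.query_coverage(len(read.bases), hits) < min_cov:
        return None
    best = max(hits, key=lambda h: (h.length, h.identity, h.ref_id, -h.q_start))
    return ScreenHit(
        read_id=read.id,
        library_record_id=best.ref_id,
        start=best.q_start,
        end=best.q_end,
        identity=best.identity,
        kind=kind,
    )


def ambiguity_fraction(read: Read) -> float:
    """Fraction of bases that are not A/C/G/T (case-insensitive).

    The removal rule is a strict inequality: a read at exactly the
    threshold (e.g. 3 N in 100 bp at 3%) is kept.
    """
    if not read.bases:
        raise ValueError(f"read {read.id!r} is empty")
    upper = read.bases.upper()
    acgt = sum(upper.count(b) for b in "ACGT")
    return (len(upper) - acgt) / len(upper)


def trim_ends(read: Read, end_trim: int, min_read_len: int = 100) -> Optional[Read]:
    """Trim ``end_trim`` bases from each end; drop the read if too little remains.

    Trimming is unconditional (applied whether or not the ends are
    masked); a remainder shorter than ``min_read_len`` returns None and
    is accounted as a trimming casualty by the cascade.
    """
    remainder = len(read.bases) - 2 * end_trim
    if remainder < min_read_len:
        return None
    bases = read.bases[end_trim : end_trim + remainder]
    quals = None
    if read.quals is not None:
        quals = read.quals[end_trim : end_trim + remainder]
    return replace(read, bases=bases, quals=quals)


def clean_reads(
    reads: Sequence[Read],
    vector_library: Optional[Dict[str, str]] = None,
    contaminant_refs: Optional[Dict[str, str]] = None,
    organelle_refs: Optional[Dict[str, str]] = None,
    params: Optional[DesignParams] = None,
    screen: Optional[ScreenParams] = None,
) -> Tuple[List[Read], CleaningLedger]:
    """Run the full cascade; returns kept reads and the removal ledger.

    Order: vector → contaminant → organelle → short → ambiguous → trim.
    Each read falls into exactly one category (first match wins), so the
    ledger counts are disjoint and conserve the input total.  Screens
    whose library is None are skipped.
    """
    params = params or DesignParams()
    screen = screen or ScreenParams()
    seen = set()
    for r in reads:
        if r.id in seen:
            raise ValueError(f"duplicate read id {r.id!r}")
        seen.add(r.id)

    ledger = CleaningLedger(input_count=len(reads))
    kept: List[Read] = []
    for read in reads:
        if vector_library and screen_vector(read, vector_library, screen=screen):
            ledger.removed["vector"] += 1
            continue
        if contaminant_refs and screen_reference(
            read, contaminant_refs, screen.min_identity, screen.min_cov, "contaminant",
            kmer=screen.kmer,
        ):
            ledger.removed["contaminant"] += 1
            continue
        if organelle_refs and screen_reference(
            read, organelle_refs, screen.min_identity, screen.min_cov, "organelle",
            kmer=screen.kmer,
        ):
            ledger.removed["organelle"] += 1
            continue
        if len(read.bases) < params.min_read_len:
            ledger.removed["short"] += 1
            continue
        if ambiguity_fraction(read) > params.max_ambiguity_frac:
            ledger.removed["ambiguous"] += 1
            continue
        trimmed = trim_ends(read, params.end_trim, params.min_read_len)
        if trimmed is None:
            ledger.removed["trim_casualty"] += 1
            continue
        kept.append(trimmed)
    ledger.kept_count = len(kept)
    assert ledger.conserves()
    return kept, ledger
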