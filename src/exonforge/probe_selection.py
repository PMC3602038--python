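"""Probe selection: a fixed number of probes per exon candidate, with accounting.

Each exon candidate receives four 25-mer probes (defaults).  Windows
containing soft-masked or ambiguous bases, or k-mers flagged non-unique
in a background index, are ineligible.  Selection spreads probes evenly
across the exon, prefers moderate GC content (0.3-0.7) and keeps probes
non-overlapping whenever the exon is long enough; shorter exons get
overlapping probes and the probeset is flagged.  Selection is
deterministic and uses no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .seq_formats import DesignParams

__all__ = ["Probe", "Probeset", "select_probes", "probeset_accounting", "expected_probe_count"]

GC_RANGE = (0.3, 0.7)


@dataclass(frozen=True)
class Probe:
    probeset_id: str
    offset: int
    length: int
    sequence: str
    gc_frac: float

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"probe at {self.offset} contains non-ACGT bases")
        if len(self.sequence) != self.length:
            raise ValueError("probe length mismatch")


@dataclass
class Probeset:
    """The probes interrogating one exon candidate."""

    exon_id: str
    probes: List[Probe] = field(default_factory=list)
    complete: bool = False
    overlapping: bool = False


def _valid_offsets(
    exon_seq: str, probe_len: int, background_kmer_index: Optional[set], background_k: int
) -> np.ndarray:
    """Offsets whose window is uppercase ACGT and free of banned k-mers."""
    n = len(exon_seq)
    ok_base = np.array([c in "ACGT" for c in exon_seq], dtype=bool)
    # window valid iff all probe_len bases are ok
    csum = np.concatenate(([0], np.cumsum(ok_base.astype(np.int64))))
    n_off = n - probe_len + 1
    offs = np.arange(n_off)
    valid = (csum[offs + probe_len] - csum[offs]) == probe_len
    if background_kmer_index:
        for i in np.nonzero(valid)[0]:
            window = exon_seq[i : i + probe_len]
            for j in range(probe_len - background_k + 1):
                if window[j : j + background_k] in background_kmer_index:
                    valid[i] = False
                    break
    return offs[valid]


def select_probes(
    exon_id: str,
    exon_seq: str,
    params: Optional[DesignParams] = None,
    background_kmer_index: Optional[set] = None,
    background_k: int = 16,
) -> Probeset:
    """Pick ``probes_per_exon`` windows spread across the exon.

    Target positions are evenly spaced over the eligible offset range;
    for each target the nearest valid window is chosen, preferring
    windows with GC fraction in [0.3, 0.7].  When the exon can hold all
    probes without overlap the choice is constrained to be
    non-overlapping; otherwise overlap is permitted and the probeset is
    flagged.  An exon fully masked yields an empty, incomplete probeset.
    """
    params = params or DesignParams()
    plen, n_probes = params.probe_len, params.probes_per_exon
    L = len(exon_seq)
    if L < plen:
        raise ValueError(f"exon {exon_id!r} shorter ({L}) than probe length {plen}")
    valid = _valid_offsets(exon_seq, plen, background_kmer_index, background_k)
    if valid.size == 0:
        return Probeset(exon_id=exon_id, probes=[], complete=False)

    gc = np.array(
        [
            sum(1 for c in exon_seq[i : i + plen] if c in "GC") / plen
            for i in valid
        ]
    )
    gc_ok = (gc >= GC_RANGE[0]) & (gc <= GC_RANGE[1])
    span = L - plen
    if n_probes == 1:
        targets = [span // 2]
    else:
        targets = [round(i * span / (n_probes - 1)) for i in range(n_probes)]

    nonoverlap_feasible = L >= n_probes * plen and valid.size >= n_probes
    chosen = _pick(valid, gc_ok, targets, plen, nonoverlap=nonoverlap_feasible)
    if chosen is None and nonoverlap_feasible:
        # validity gaps defeated the non-overlap layout; allow overlap
        chosen = _pick(valid, gc_ok, targets, plen, nonoverlap=False)
    if chosen is None:
        chosen = []

    probes = [
        Probe(
            probeset_id=exon_id,
            offset=int(off),
            length=plen,
            sequence=exon_seq[off : off + plen],
            gc_frac=float(sum(1 for c in exon_seq[off : off + plen] if c in "GC")) / plen,
        )
        for off in sorted(chosen)
    ]
    overlapping = any(
        b.offset < a.offset + plen
        for a, b in zip(probes, probes[1:])
    )
    return Probeset(
        exon_id=exon_id,
        probes=probes,
        complete=len(probes) == n_probes,
        overlapping=overlapping,
    )


def _pick(
    valid: np.ndarray,
    gc_ok: np.ndarray,
    targets: Sequence[int],
    plen: int,
    nonoverlap: bool,
) -> Optional[List[int]]:
    """Greedy left-to-right assignment of targets to valid offsets."""
    chosen: List[int] = []
    used = set()
    min_next = 0
    remaining = len(targets)
    max_off = int(valid.max())
    for t in targets:
        if nonoverlap:
            ceiling = max_off - (remaining - 1) * plen
            mask = (valid >= min_next) & (valid <= ceiling)
        else:
            mask = np.array([v not in used for v in valid])
        cand = valid[mask]
        if cand.size == 0:
            return None if nonoverlap else (chosen or None)
        cand_gc = gc_ok[mask]
        # prefer GC-acceptable windows, then proximity to target, then leftmost
        order = sorted(
            range(cand.size), key=lambda i: (not cand_gc[i], abs(int(cand[i]) - t), int(cand[i]))
        )
        off = int(cand[order[0]])
        chosen.append(off)
        used.add(off)
        if nonoverlap:
            min_next = off + plen
        remaining -= 1
    return chosen


def probeset_accounting(probesets: Sequence[Probeset]) -> Tuple[int, int]:
    """(number of probesets, total number of probes)."""
    return len(probesets), sum(len(ps.probes) for ps in probesets)


def expected_probe_count(n_complete_probesets: int, params: Optional[DesignParams] = None) -> int:
    """Probe total implied by a count of complete probesets."""
    params = params or DesignParams()
    return n_complete_probesets * params.probes_per_exon
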