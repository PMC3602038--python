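"""Internal ungapped sequence matching used by the screening steps.

The cleaning and masking screens all answer the same question: does a
query contain a window that matches some library record at a minimum
identity over a minimum length?  Library insertions here are near-exact
(vector splices, organellar fragments, repeat copies), so matching is
ungapped: a hit lives on a single alignment diagonal.  Candidate
diagonals are found by exact shared k-mers (k=12 by default); on each
seeded diagonal the longest window whose identity meets the threshold is
located exactly with a prefix-sum argument.

With identity threshold >= 0.95 and a window of at least 30 bp, a
mismatch-free run of >= 12 bp is guaranteed by pigeonhole, so the k-mer
seeding loses no qualifying hit at the default thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVNacgturyswkmbdhvn",
                            "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn")

_ACGT = frozenset(b"ACGT")
_ACGT_LUT = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _ACGT_LUT[_b] = True


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """An ungapped match between a query window and a library window.

    Reference coordinates are on the forward strand of the library
    record; ``strand`` says which library strand matched the query.
    """

    ref_id: str
    strand: str
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    identity: float

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def _kmer_positions(seq: str, k: int) -> Dict[str, List[int]]:
    index: Dict[str, List[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer.encode()) <= _ACGT:
            index.setdefault(kmer, []).append(i)
    return index


def _seeded_diagonals(query: str, ref: str, k: int) -> set:
    """Diagonals (q_pos - r_pos) sharing at least one exact k-mer."""
    if len(query) < k or len(ref) < k:
        return set()
    index = _kmer_positions(ref, k)
    diags = set()
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        for j in index.get(kmer, ()):
            diags.add(i - j)
    return diags


def _best_window(match: np.ndarray, theta: float, min_len: int) -> Optional[Tuple[int, int, float]]:
    """Longest window of ``match`` with mean >= theta and length >= min_len.

    Returns (start, end, identity) or None.  Uses the prefix-sum trick:
    with a_i = match_i - theta, a window [i, j) qualifies iff
    P_j >= P_i; the prefix minima of P are non-increasing, so for each j
    the earliest admissible i is found by binary search.
    """
    L = len(match)
    if L < min_len:
        return None
    a = match.astype(np.float64) - theta
    P = np.concatenate(([0.0], np.cumsum(a)))
    M = np.minimum.accumulate(P)
    # earliest i with M[i] <= P[j] + eps, vectorized over j
    idx = np.searchsorted(-M, -(P + 1e-9), side="left")
    js = np.arange(L + 1)
    lens = js - idx
    lens[lens < min_len] = 0
    j = int(np.argmax(lens))
    if lens[j] == 0:
        return None
    i = int(idx[j])
    C = np.concatenate(([0], np.cumsum(match.astype(np.int64))))
    ident = (C[j] - C[i]) / (j - i)
    return i, j, float(ident)


def _diagonal_match(query_b: np.ndarray, ref_b: np.ndarray, d: int) -> Optional[Tuple[int, np.ndarray]]:
    """Boolean match array along diagonal d; returns (q_offset, match)."""
    q0 = max(0, d)
    q1 = min(len(query_b), len(ref_b) + d)
    if q1 <= q0:
        return None
    qa = query_b[q0:q1]
    ra = ref_b[q0 - d : q1 - d]
    match = (qa == ra) & _ACGT_LUT[qa] & _ACGT_LUT[ra]
    return q0, match


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def find_hits(
    query: str,
    library: Dict[str, str],
    min_identity: float,
    min_len: int,
    k: int = 12,
    both_strands: bool = True,
) -> List[AlignmentHit]:
    """All qualifying ungapped hits of ``query`` against ``library``.

    One hit (the best window) is reported per seeded diagonal per
    library strand.  Hits are returned unsorted.
    """
    hits: List[AlignmentHit] = []
    query_u = query.upper()
    qb = _as_bytes(query_u)
    for ref_id, ref_seq in library.items():
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            oriented = ref_seq.upper() if strand == "+" else revcomp(ref_seq.upper())
            rb = _as_bytes(oriented)
            for d in _seeded_diagonals(query_u, oriented, k):
                dm = _diagonal_match(qb, rb, d)
                if dm is None:
                    continue
                q0, match = dm
                win = _best_window(match, min_identity, min_len)
                if win is None:
                    continue
                wi, wj, ident = win
                q_start, q_end = q0 + wi, q0 + wj
                ro_start, ro_end = q_start - d, q_end - d
                if strand == "+":
                    r_start, r_end = ro_start, ro_end
                else:
                    r_start = len(ref_seq) - ro_end
                    r_end = len(ref_seq) - ro_start
                hits.append(
                    AlignmentHit(
                        ref_id=ref_id,
                        strand=strand,
                        q_start=q_start,
                        q_end=q_end,
                        r_start=r_start,
                        r_end=r_end,
                        identity=ident,
                    )
                )
    return hits


def _max_score_window(
    match: np.ndarray, match_score: float, mismatch_score: float
) -> Optional[Tuple[int, int, float]]:
    """Maximum-scoring window (Kadane) with +match/-mismatch scoring.

    Unlike the longest-window-at-threshold search, the scoring window
    snaps to the boundaries of a planted copy: extending into unrelated
    flanking sequence (~25% chance agreement) has negative expected
    score.  Returns (start, end, identity) of the best window, or None
    when no window has positive score.
    """
    scores = np.where(match, match_score, mismatch_score)
    best_sum = 0.0
    best = None
    cur_sum = 0.0
    cur_start = 0
    for j, s in enumerate(scores):
        if cur_sum <= 0:
            cur_sum = 0.0
            cur_start = j
        cur_sum += s
        if cur_sum > best_sum:
            best_sum = cur_sum
            best = (cur_start, j + 1)
    if best is None:
        return None
    i, j = best
    ident = float(match[i:j].mean())
    return i, j, ident


def find_mask_hits(
    query: str,
    library: Dict[str, str],
    min_identity: float,
    min_len: int,
    k: int = 12,
    match_score: float = 1.0,
    mismatch_score: float = -3.0,
) -> List[AlignmentHit]:
    """Boundary-snapped library hits for repeat masking.

    Per seeded diagonal the maximum-scoring window is taken and kept
    when it meets the length and identity thresholds, so masks hug the
    planted repeat copy rather than absorbing flanking sequence.
    """
    hits: List[AlignmentHit] = []
    query_u = query.upper()
    qb = _as_bytes(query_u)
    for ref_id, ref_seq in library.items():
        for strand in ("+", "-"):
            oriented = ref_seq.upper() if strand == "+" else revcomp(ref_seq.upper())
            rb = _as_bytes(oriented)
            for d in _seeded_diagonals(query_u, oriented, k):
                dm = _diagonal_match(qb, rb, d)
                if dm is None:
                    continue
                q0, match = dm
                win = _max_score_window(match, match_score, mismatch_score)
                if win is None:
                    continue
                wi, wj, ident = win
                if wj - wi < min_len or ident < min_identity:
                    continue
                q_start, q_end = q0 + wi, q0 + wj
                ro_start, ro_end = q_start - d, q_end - d
                if strand == "+":
                    r_start, r_end = ro_start, ro_end
                else:
                    r_start = len(ref_seq) - ro_end
                    r_end = len(ref_seq) - ro_start
                hits.append(
                    AlignmentHit(
                        ref_id=ref_id,
                        strand=strand,
                        q_start=q_start,
                        q_end=q_end,
                        r_start=r_start,
                        r_end=r_end,
                        identity=ident,
                    )
                )
    return hits


def best_hit(
    query: str,
    library: Dict[str, str],
    min_identity: float,
    min_len: int,
    k: int = 12,
) -> Optional[AlignmentHit]:
    """Best qualifying hit by (length, identity), or None."""
    hits = find_hits(query, library, min_identity, min_len, k=k)
    if not hits:
        return None
    return max(hits, key=lambda h: (h.length, h.identity, h.ref_id, -h.q_start))


def query_coverage(query_len: int, hits: Sequence[AlignmentHit]) -> float:
    """Fraction of the query covered by the union of hit windows."""
    if not hits or query_len == 0:
        return 0.0
    spans = sorted((h.q_start, h.q_end) for h in hits)
    covered = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return covered / query_len
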