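"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its plan (including the seed) and
returns both the data and exact ground-truth labels, so every pipeline
stage can be tested against planted truth without any downloads.  Read
lengths mimic Sanger-era survey reads (normal(650, 100) truncated to
[100, 1000]); assembly fragments follow a log-normal with median near
990 bp; field trials plant additive genotype, environment, interaction,
block and smooth spatial components at configurable effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._align import revcomp
from .est_pipeline import ESTContig, STOPS
from .evidence_integration import EvidenceTrack
from .seq_formats import GenomicInterval, Read

__all__ = [
    "GSSPlan",
    "ContigPlan",
    "ESTPlan",
    "FieldPlan",
    "GSSFixture",
    "ContigFixture",
    "ESTFixture",
    "FieldFixture",
    "generate_gss_reads",
    "generate_annotated_contigs",
    "truncate_contigs",
    "generate_est_contigs",
    "generate_field_trial",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply exactly n_subs substitutions at distinct positions."""
    if n_subs == 0:
        return seq
    chars = list(seq)
    positions = rng.choice(len(chars), size=n_subs, replace=False)
    for pos in positions:
        old = chars[pos]
        choices = [b for b in "ACGT" if b != old.upper()]
        chars[pos] = choices[rng.integers(0, 3)]
    return "".join(chars)


def _read_length(rng: np.random.Generator, lo: int = 100, hi: int = 1000,
                 mean: float = 650.0, sd: float = 100.0) -> int:
    while True:
        n = int(round(rng.normal(mean, sd)))
        if lo <= n <= hi:
            return n


# ---------------------------------------------------------------------------
# GSS reads


@dataclass(frozen=True)
class GSSPlan:
    """Counts per removal category plus reference-set sizes."""

    seed: int = 0
    counts: Dict[str, int] = field(
        default_factory=lambda: {
            "vector": 5, "contaminant": 2, "organelle": 3,
            "short": 4, "ambiguous": 2, "clean": 84,
        }
    )
    n_vectors: int = 3
    vector_len: int = 1500
    contaminant_len: int = 20000
    organelle_len: int = 15000
    ambiguous_frac: float = 0.05
    read_mean: float = 650.0
    read_sd: float = 100.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("category counts must be >= 0")
        if not (0 <= self.ambiguous_frac <= 1):
            raise ValueError("ambiguous_frac must be in [0, 1]")


@dataclass
class GSSFixture:
    reads: List[Read]
    truth: Dict[str, str]  # read id -> category ("clean" for survivors)
    vector_library: Dict[str, str]
    contaminant_refs: Dict[str, str]
    organelle_refs: Dict[str, str]


def generate_gss_reads(plan: GSSPlan) -> GSSFixture:
    """Reads with planted removal categories and the matching libraries.

    Clean reads are drawn long enough (>= 220 bp) to survive the 60 bp
    end trimming with at least 100 bp remaining, so in the noiseless
    setting the cleaning ledger equals the plan exactly.  Reads are
    emitted shuffled so category and input order are independent.
    """
    rng = np.random.default_rng(plan.seed)
    unknown = set(plan.counts) - {"vector", "contaminant", "organelle", "short",
                                  "ambiguous", "clean"}
    if unknown:
        raise ValueError(f"unknown plan categories {sorted(unknown)}")

    vectors = {f"vec{i}": _rand_seq(rng, plan.vector_len) for i in range(plan.n_vectors)}
    contaminants = {"contam_ref": _rand_seq(rng, plan.contaminant_len)}
    organelles = {
        "mito_ref": _rand_seq(rng, plan.organelle_len),
        "plastid_ref": _rand_seq(rng, plan.organelle_len),
    }

    reads: List[Read] = []
    truth: Dict[str, str] = {}
    serial = 0

    def emit(category: str, bases: str) -> None:
        nonlocal serial
        rid = f"gss{serial:05d}"
        serial += 1
        quals = rng.integers(15, 55, len(bases)).tolist()
        reads.append(Read(id=rid, bases=bases, quals=quals))
        truth[rid] = category

    for _ in range(plan.counts.get("vector", 0)):
        n = _read_length(rng, 220, 1000, plan.read_mean, plan.read_sd)
        vec_id = f"vec{rng.integers(0, plan.n_vectors)}"
        vec = vectors[vec_id]
        seg_len = int(rng.integers(120, 200))
        off = int(rng.integers(0, len(vec) - seg_len))
        seg = vec[off : off + seg_len]
        if rng.random() < 0.5:
            seg = revcomp(seg)
        rest = _rand_seq(rng, max(0, n - seg_len))
        emit("vector", seg + rest)

    for _ in range(plan.counts.get("contaminant", 0)):
        n = _read_length(rng, 150, 1000, plan.read_mean, plan.read_sd)
        off = int(rng.integers(0, plan.contaminant_len - n))
        seg = contaminants["contam_ref"][off : off + n]
        emit("contaminant", seg if rng.random() < 0.5 else revcomp(seg))

    for _ in range(plan.counts.get("organelle", 0)):
        n = _read_length(rng, 150, 1000, plan.read_mean, plan.read_sd)
        ref_id = "mito_ref" if rng.random() < 0.5 else "plastid_ref"
        off = int(rng.integers(0, plan.organelle_len - n))
        seg = organelles[ref_id][off : off + n]
        emit("organelle", seg if rng.random() < 0.5 else revcomp(seg))

    for _ in range(plan.counts.get("short", 0)):
        emit("short", _rand_seq(rng, int(rng.integers(40, 100))))

    for _ in range(plan.counts.get("ambiguous", 0)):
        n = _read_length(rng, 220, 1000, plan.read_mean, plan.read_sd)
        bases = list(_rand_seq(rng, n))
        n_amb = max(int(np.ceil(plan.ambiguous_frac * n)), int(0.03 * n) + 1)
        for pos in rng.choice(n, size=n_amb, replace=False):
            bases[pos] = "N"
        emit("ambiguous", "".join(bases))

    for _ in range(plan.counts.get("clean", 0)):
        n = _read_length(rng, 220, 1000, plan.read_mean, plan.read_sd)
        emit("clean", _rand_seq(rng, n))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return GSSFixture(
        reads=reads,
        truth=truth,
        vector_library=vectors,
        contaminant_refs=contaminants,
        organelle_refs=organelles,
    )


# ---------------------------------------------------------------------------
# Annotated contigs with planted exons and noisy evidence


@dataclass(frozen=True)
class SourceNoise:
    """Per-source corruption: drop rate, false discoveries, boundary jitter."""

    sensitivity: float = 1.0
    fdr: float = 0.0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.fdr < 1):
            raise ValueError("rates must be in [0, 1] (fdr < 1)")


@dataclass(frozen=True)
class ContigPlan:
    seed: int = 0
    n_contigs: int = 5
    contig_len: int = 8000
    exons_per_contig: int = 4
    exon_len_range: Tuple[int, int] = (60, 400)
    min_gap: int = 120
    sources: Dict[str, SourceNoise] = field(
        default_factory=lambda: {
            "augustus": SourceNoise(),
            "tobacco_est": SourceNoise(),
            "conservation": SourceNoise(),
        }
    )
    repeats_per_contig: int = 0
    repeat_len: int = 200


@dataclass
class ContigFixture:
    contigs: Dict[str, str]
    truth_exons: List[GenomicInterval]
    tracks: List[EvidenceTrack]
    repeat_track: Optional[EvidenceTrack]


def generate_annotated_contigs(plan: ContigPlan) -> ContigFixture:
    """Contigs with planted exons and per-source corrupted evidence.

    Exons (each with a planted strand) are placed with generous gaps so
    distinct exons never merge.  Per source, each exon is reported with
    probability ``sensitivity``, its boundaries jittered by a Gaussian
    (sd ``jitter_sd``, clipped to stay within the gap); false intervals
    are added in intergenic space at the planted false-discovery rate.
    Repeats, when requested, are planted in intergenic space and
    reported as a negative track.
    """
    rng = np.random.default_rng(plan.seed)
    contigs: Dict[str, str] = {}
    truth: List[GenomicInterval] = []
    free_space: List[GenomicInterval] = []  # intergenic, for FPs and repeats

    for ci in range(plan.n_contigs):
        cid = f"contig{ci:03d}"
        contigs[cid] = _rand_seq(rng, plan.contig_len)
        pos = plan.min_gap
        for _ in range(plan.exons_per_contig):
            elen = int(rng.integers(plan.exon_len_range[0], plan.exon_len_range[1] + 1))
            if pos + elen + plan.min_gap > plan.contig_len:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            truth.append(GenomicInterval(cid, pos, pos + elen, strand))
            gap_start = pos + elen
            pos = gap_start + plan.min_gap + int(rng.integers(0, plan.min_gap))
            free_space.append(
                GenomicInterval(cid, gap_start + 20, min(pos, plan.contig_len) - 20)
                if min(pos, plan.contig_len) - 20 > gap_start + 20
                else GenomicInterval(cid, gap_start, gap_start + 1)
            )

    tracks: List[EvidenceTrack] = []
    max_jitter = plan.min_gap // 2 - 1
    for source, noise in plan.sources.items():
        intervals: List[GenomicInterval] = []
        for exon in truth:
            if rng.random() > noise.sensitivity:
                continue
            if noise.jitter_sd > 0:
                js = int(np.clip(round(rng.normal(0, noise.jitter_sd)), -max_jitter, max_jitter))
                je = int(np.clip(round(rng.normal(0, noise.jitter_sd)), -max_jitter, max_jitter))
            else:
                js = je = 0
            start = max(0, exon.start + js)
            end = min(plan.contig_len, exon.end + je)
            if end - start < 1:
                continue
            strand = exon.strand if source != "conservation" else "?"
            intervals.append(GenomicInterval(exon.seq_id, start, end, strand))
        if noise.fdr > 0 and intervals:
            n_false = int(round(noise.fdr / (1 - noise.fdr) * len(intervals)))
            candidates = [g for g in free_space if len(g) >= 60]
            for _ in range(n_false):
                if not candidates:
                    break
                gap = candidates[int(rng.integers(0, len(candidates)))]
                flen = min(len(gap), int(rng.integers(60, 200)))
                off = int(rng.integers(0, len(gap) - flen + 1))
                intervals.append(
                    GenomicInterval(gap.seq_id, gap.start + off, gap.start + off + flen)
                )
        intervals.sort(key=lambda iv: (iv.seq_id, iv.start))
        tracks.append(EvidenceTrack(source_id=source, intervals=intervals))

    repeat_track = None
    if plan.repeats_per_contig > 0:
        rep_intervals = []
        gaps = [g for g in free_space if len(g) >= plan.repeat_len]
        for _ in range(plan.repeats_per_contig * plan.n_contigs):
            if not gaps:
                break
            gap = gaps.pop(int(rng.integers(0, len(gaps))))
            rep_intervals.append(
                GenomicInterval(gap.seq_id, gap.start, gap.start + plan.repeat_len)
            )
        repeat_track = EvidenceTrack(
            source_id="repeats", intervals=rep_intervals, polarity="negative"
        )
    return ContigFixture(
        contigs=contigs, truth_exons=truth, tracks=tracks, repeat_track=repeat_track
    )


def truncate_contigs(
    contigs: Dict[str, str],
    truth_exons: Sequence[GenomicInterval],
    length_sampler: Optional[Callable[[np.random.Generator], int]] = None,
    seed: int = 0,
) -> Tuple[Dict[str, str], List[GenomicInterval]]:
    """Cut each contig to a sampled length at a uniform random offset.

    Emulates the fragmented draft assembly: a sampled length longer than
    the contig leaves it whole.  Planted exons are clipped into the kept
    window (coordinates shifted); exon fragments shorter than 1 bp are
    dropped.  The default length distribution is log-normal with median
    ~990 bp (a typical draft-assembly contig scale).
    """
    rng = np.random.default_rng(seed)
    if length_sampler is None:
        def length_sampler(r: np.random.Generator) -> int:
            return max(100, int(round(r.lognormal(mean=np.log(990), sigma=0.7))))
    out: Dict[str, str] = {}
    new_truth: List[GenomicInterval] = []
    for cid in sorted(contigs):
        seq = contigs[cid]
        want = length_sampler(rng)
        if want >= len(seq):
            out[cid] = seq
            new_truth.extend(iv for iv in truth_exons if iv.seq_id == cid)
            continue
        off = int(rng.integers(0, len(seq) - want + 1))
        out[cid] = seq[off : off + want]
        for iv in truth_exons:
            if iv.seq_id != cid:
                continue
            s = max(iv.start, off) - off
            e = min(iv.end, off + want) - off
            if e - s >= 1:
                new_truth.append(GenomicInterval(cid, s, e, iv.strand))
    return out, new_truth


# ---------------------------------------------------------------------------
# EST contigs


@dataclass(frozen=True)
class ESTPlan:
    seed: int = 0
    counts: Dict[str, int] = field(
        default_factory=lambda: {"orf_ok": 10, "orf_short": 5, "redundant": 8, "repeat": 4}
    )
    n_genomic: int = 12
    genomic_len_range: Tuple[int, int] = (200, 400)
    mutation_frac: float = 0.01
    repeat_family_len: int = 400


@dataclass
class ESTFixture:
    ests: List[ESTContig]
    truth: Dict[str, str]  # est id -> planted category
    genomic_seqs: Dict[str, str]
    repeat_library: Dict[str, str]


_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS and a + b + c != "ATG"
]


def _codon_run(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _naive_has_orf(seq: str, min_len: int) -> bool:
    """Independent 6-frame check used only to enforce planted truth."""
    for s in (seq.upper(), revcomp(seq.upper())):
        for frame in range(3):
            first_atg = None
            for pos in range(frame, len(s) - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOPS:
                    if first_atg is not None and pos + 3 - first_atg >= min_len:
                        return True
                    first_atg = None
                elif codon == "ATG" and first_atg is None:
                    first_atg = pos
    return False


def generate_est_contigs(plan: ESTPlan) -> ESTFixture:
    """EST contigs with planted pipeline outcomes, plus their genomic partners.

    Categories: ``orf_ok`` contigs carry a planted ATG...stop frame of at
    least 150 bp; ``orf_short`` contigs are rejection-sampled to contain
    no qualifying frame on either strand; ``redundant`` contigs are >=99%
    copies of a genomic candidate; ``repeat`` contigs carry a repeat-
    family insertion covering well over 25% of their length.
    """
    rng = np.random.default_rng(plan.seed)
    genomic = {
        f"gexon{i:03d}": _rand_seq(
            rng, int(rng.integers(plan.genomic_len_range[0], plan.genomic_len_range[1] + 1))
        )
        for i in range(plan.n_genomic)
    }
    repeat_library = {
        "repfamA": _rand_seq(rng, plan.repeat_family_len),
        "repfamB": _rand_seq(rng, plan.repeat_family_len),
    }
    ests: List[ESTContig] = []
    truth: Dict[str, str] = {}
    serial = 0

    def emit(category: str, seq: str) -> None:
        nonlocal serial
        eid = f"est{serial:04d}"
        serial += 1
        ests.append(ESTContig(id=eid, seq=seq))
        truth[eid] = category

    for _ in range(plan.counts.get("orf_ok", 0)):
        n_codons = int(rng.integers(50, 110))  # 150-330 bp coding
        orf = "ATG" + _codon_run(rng, n_codons - 2) + STOPS[rng.integers(0, 3)]
        flank5 = _rand_seq(rng, int(rng.integers(20, 60)))
        flank3 = _rand_seq(rng, int(rng.integers(20, 60)))
        seq = flank5 + orf + flank3
        if rng.random() < 0.5:
            seq = revcomp(seq)
        emit("orf_ok", seq)

    for _ in range(plan.counts.get("orf_short", 0)):
        while True:
            seq = _rand_seq(rng, int(rng.integers(200, 320)))
            if not _naive_has_orf(seq, 150):
                break
        emit("orf_short", seq)

    gids = sorted(genomic)
    for _ in range(plan.counts.get("redundant", 0)):
        gid = gids[int(rng.integers(0, len(gids)))]
        src = genomic[gid]
        n_subs = int(np.floor(len(src) * plan.mutation_frac))
        seq = _mutate(rng, src, n_subs)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        emit("redundant", seq)

    for _ in range(plan.counts.get("repeat", 0)):
        family = "repfamA" if rng.random() < 0.5 else "repfamB"
        rep = repeat_library[family]
        seg_len = int(rng.integers(250, plan.repeat_family_len))
        seg = rep[:seg_len]
        total = int(seg_len / 0.4)  # ~40% repeat coverage
        flank = _rand_seq(rng, total - seg_len)
        emit("repeat", flank[: len(flank) // 2] + seg + flank[len(flank) // 2 :])

    order = rng.permutation(len(ests))
    ests = [ests[i] for i in order]
    return ESTFixture(
        ests=ests, truth=truth, genomic_seqs=genomic, repeat_library=repeat_library
    )


# ---------------------------------------------------------------------------
# Field trials


@dataclass(frozen=True)
class FieldPlan:
    """Additive field-trial simulation on a rows x columns grid per environment.

    value = mu + G + E + GxE + spatial(row, col) + block + noise.  The
    spatial surface is amplitude * sin(pi r / (R-1)) * cos(pi c / (C-1)
    + phase_e) with a per-environment random phase.  Defaults mirror a
    realistic leaf-cadmium trial: 45 varieties, 8 environments, a 6-row
    by 45-column layout with rows as blocks, trait mean ~3 mg/kg.
    """

    seed: int = 0
    n_varieties: int = 45
    n_envs: int = 8
    n_rows: int = 6
    n_cols: int = 45
    mu: float = 3.0
    g_sd: float = 0.6
    e_sd: float = 0.5
    gxe_sd: float = 0.15
    block_sd: float = 0.1
    spatial_amplitude: float = 1.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols % self.n_varieties != 0:
            raise ValueError("grid size must be a multiple of the variety count")


@dataclass
class FieldFixture:
    plots: pd.DataFrame
    g_effects: pd.Series
    e_effects: pd.Series
    gxe: pd.DataFrame
    spatial_truth: Dict[str, np.ndarray]  # env -> per-plot surface, plot order


def generate_field_trial(plan: FieldPlan) -> FieldFixture:
    """Simulate the multi-environment trial with recorded truth components."""
    rng = np.random.default_rng(plan.seed)
    varieties = [f"V{i + 1}" for i in range(plan.n_varieties)]
    envs = [f"E{i + 1}" for i in range(plan.n_envs)]
    g = pd.Series(rng.normal(0, plan.g_sd, plan.n_varieties), index=varieties)
    e = pd.Series(rng.normal(0, plan.e_sd, plan.n_envs), index=envs)
    gxe = pd.DataFrame(
        rng.normal(0, plan.gxe_sd, (plan.n_varieties, plan.n_envs)),
        index=varieties, columns=envs,
    )
    reps = plan.n_rows * plan.n_cols // plan.n_varieties

    rows_out: List[dict] = []
    spatial_truth: Dict[str, np.ndarray] = {}
    R, C = plan.n_rows, plan.n_cols
    for env in envs:
        phase = rng.uniform(0, 2 * np.pi)
        blocks = rng.normal(0, plan.block_sd, reps)
        # one block per replicate; blocks tile the grid in row-major stripes
        assignment = np.concatenate(
            [rng.permutation(plan.n_varieties) for _ in range(reps)]
        )
        surf = np.empty(R * C)
        idx = 0
        for r in range(R):
            for c in range(C):
                s = plan.spatial_amplitude * np.sin(np.pi * r / max(R - 1, 1)) * np.cos(
                    np.pi * c / max(C - 1, 1) + phase
                )
                surf[idx] = s
                block = idx // plan.n_varieties
                v = varieties[assignment[idx]]
                value = (
                    plan.mu + g[v] + e[env] + gxe.loc[v, env]
                    + s + blocks[block] + rng.normal(0, plan.noise_sd)
                )
                rows_out.append(
                    {
                        "env": env, "row": r, "column": c, "block": block,
                        "variety": v, "value": value,
                    }
                )
                idx += 1
        spatial_truth[env] = surf - surf.mean()
    plots = pd.DataFrame(rows_out)
    return FieldFixture(
        plots=plots, g_effects=g, e_effects=e, gxe=gxe, spatial_truth=spatial_truth
    )
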