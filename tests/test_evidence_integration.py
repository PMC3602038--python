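"""Consensus-region construction, filter rules, strand calls, evaluation."""

import numpy as np
import pytest

from exonforge.evidence_integration import (
    EvidenceTrack,
    assign_strand,
    build_consensus_regions,
    exon_eval,
    filter_regions,
    flag_te_regions,
    rank_regions,
)
from exonforge.seq_formats import DesignParams, GenomicInterval
from exonforge.synthetic_fixtures import ContigPlan, SourceNoise, generate_annotated_contigs


def track(source, spans, contig="c1", strand="?", polarity="supporting"):
    return EvidenceTrack(
        source_id=source,
        intervals=[GenomicInterval(contig, a, b, strand) for a, b in spans],
        polarity=polarity,
    )


def oracle_regions(tracks, params=None):
    """Positionwise oracle: union bitmap of supporting evidence; covered runs
    become regions; sources = tracks with an interval overlapping the run."""
    params = params or DesignParams()
    supporting = [t for t in tracks if t.polarity == "supporting"]
    contigs = sorted({iv.seq_id for t in supporting for iv in t.intervals})
    out = []
    for contig in contigs:
        end = max(iv.end for t in supporting for iv in t.intervals if iv.seq_id == contig)
        bitmap = np.zeros(end + 1, dtype=bool)
        for t in supporting:
            for iv in t.intervals:
                if iv.seq_id == contig:
                    bitmap[iv.start : iv.end] = True
        padded = np.concatenate(([False], bitmap, [False]))
        d = np.diff(padded.astype(np.int8))
        for s, e in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
            if e - s < params.min_exon_len:
                continue
            sources = frozenset(
                t.source_id
                for t in supporting
                if any(iv.seq_id == contig and iv.start < e and s < iv.end for iv in t.intervals)
            )
            out.append((contig, int(s), int(e), sources))
    return out


class TestBuildConsensusRegions:
    def test_three_source_cluster(self):
        tracks = [
            track("augustus", [(100, 250)]),
            track("tobacco_est", [(120, 260)]),
            track("conservation", [(110, 240)]),
        ]
        (r,) = build_consensus_regions(tracks)
        assert (r.interval.start, r.interval.end) == (100, 260)
        assert r.supporting_sources == {"augustus", "tobacco_est", "conservation"}
        assert r.score == 3 and not r.short_penalized

    def test_below_min_len_dropped(self):
        assert build_consensus_regions([track("augustus", [(10, 69)])]) == []

    def test_short_region_penalized_to_zero(self):
        (r,) = build_consensus_regions([track("augustus", [(10, 90)])])
        assert r.short_penalized and r.score == 0

    def test_duplicate_source_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_consensus_regions([track("augustus", [(0, 100)]), track("augustus", [(200, 300)])])

    def test_touching_intervals_merge_as_contiguous_coverage(self):
        tracks = [track("augustus", [(0, 100), (100, 200)])]
        regions = build_consensus_regions(tracks)
        assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 200)]

    def test_gapped_intervals_stay_separate(self):
        tracks = [track("augustus", [(0, 100), (101, 201)])]
        regions = build_consensus_regions(tracks)
        assert [(r.interval.start, r.interval.end) for r in regions] == [(0, 100), (101, 201)]

    def test_repeat_overlap_fraction_from_negative_track(self):
        tracks = [
            track("augustus", [(0, 200)]),
            track("repeats", [(150, 250)], polarity="negative"),
        ]
        (r,) = build_consensus_regions(tracks)
        assert r.repeat_overlap_frac == pytest.approx(0.25)

    def test_matches_positionwise_oracle_on_random_evidence(self, rng):
        sources = ["augustus", "fgenesh", "tobacco_est", "conservation"]
        for _ in range(10):
            n = int(rng.integers(2000, 20000))
            tracks = []
            for src in sources:
                spans = []
                for _ in range(int(rng.integers(1, 25))):
                    a = int(rng.integers(0, n - 500))
                    spans.append((a, a + int(rng.integers(30, 500))))
                tracks.append(track(src, spans))
            regions = build_consensus_regions(tracks)
            got = [
                (r.interval.seq_id, r.interval.start, r.interval.end, r.supporting_sources)
                for r in regions
            ]
            assert got == oracle_regions(tracks)
            # non-overlap and sortedness
            for a, b in zip(regions, regions[1:]):
                assert a.interval.end <= b.interval.start or a.interval.seq_id != b.interval.seq_id

    def test_score_monotone_in_sources(self):
        base = [track("augustus", [(0, 200)])]
        more = base + [track("conservation", [(50, 150)])]
        (r1,) = build_consensus_regions(base)
        (r2,) = build_consensus_regions(more)
        assert r2.score >= r1.score
        assert 0 <= r1.score <= 7 and 0 <= r2.score <= 7


class TestFilterRegions:
    def _regions(self, tracks):
        return build_consensus_regions(tracks)

    def test_est_only_removed(self):
        regions = self._regions([track("tobacco_est", [(0, 200)])])
        kept, removed = filter_regions(regions)
        assert kept == [] and removed[0][1] == "a_est_only"

    def test_fgenesh_only_on_repeat_removed_but_supported_kept(self):
        tracks = [
            track("fgenesh", [(0, 200)]),
            track("repeats", [(0, 20)], polarity="negative"),
        ]
        kept, removed = filter_regions(self._regions(tracks))
        assert kept == [] and removed[0][1] == "b_fgenesh_only_on_repeat"
        tracks2 = [
            track("fgenesh", [(0, 200)]),
            track("conservation", [(0, 200)]),
            track("repeats", [(0, 20)], polarity="negative"),
        ]
        kept2, removed2 = filter_regions(self._regions(tracks2))
        assert len(kept2) == 1 and removed2 == []

    def test_te_protein_flag_removes(self):
        regions = self._regions([track("augustus", [(0, 200)]), track("conservation", [(0, 200)])])
        flagged = flag_te_regions(regions, [GenomicInterval("c1", 50, 80)])
        kept, removed = filter_regions(flagged)
        assert kept == [] and removed[0][1] == "c_te_protein"

    def test_repeat_overlap_strictly_above_quarter(self):
        # 200 bp region with exactly 50 bp repeat overlap (0.25) is kept
        tracks = [
            track("augustus", [(0, 200)]),
            track("conservation", [(0, 200)]),
            track("repeats", [(0, 50)], polarity="negative"),
        ]
        kept, removed = filter_regions(self._regions(tracks))
        assert len(kept) == 1
        # 51 bp (0.255) is removed
        tracks[2] = track("repeats", [(0, 51)], polarity="negative")
        kept2, removed2 = filter_regions(self._regions(tracks))
        assert kept2 == [] and removed2[0][1] == "d_repeat_overlap"


class TestAssignStrand:
    def test_unanimous(self):
        tracks = [track("augustus", [(0, 200)], strand="+"),
                  track("tobacco_est", [(0, 200)], strand="+")]
        (r,) = build_consensus_regions(tracks)
        assert assign_strand(r, tracks) == "+"

    def test_priority_breaks_conflict(self):
        tracks = [track("augustus", [(0, 200)], strand="+"),
                  track("conservation", [(0, 200)], strand="-")]
        (r,) = build_consensus_regions(tracks)
        assert assign_strand(r, tracks) == "+"

    def test_unstranded_only_gives_unknown(self):
        tracks = [track("conservation", [(0, 200)], strand="?")]
        (r,) = build_consensus_regions(tracks)
        assert assign_strand(r, tracks) == "?"


class TestRankRegions:
    def _region_with(self, score, length, start=0):
        tracks = [track(s, [(start, start + length)]) for s in
                  ["augustus", "fgenesh", "tobacco_est", "tobacco_cdna", "protein_homology",
                   "conservation", "related_cdna"][:score]]
        (r,) = build_consensus_regions(tracks)
        assert r.score == score
        return r

    def test_score_descending(self):
        regions = [self._region_with(2, 200), self._region_with(7, 200), self._region_with(5, 200)]
        assert [r.score for r in rank_regions(regions)] == [7, 5, 2]

    def test_length_breaks_score_ties(self):
        short = self._region_with(3, 150)
        long_ = self._region_with(3, 400)
        assert rank_regions([short, long_])[0] is long_

    def test_truncation_and_negative_rejected(self):
        regions = [self._region_with(2, 200), self._region_with(3, 200)]
        assert rank_regions(regions, target_count=0) == []
        assert len(rank_regions(regions, target_count=1)) == 1
        with pytest.raises(ValueError):
            rank_regions(regions, target_count=-1)


class TestExonEval:
    def _ivs(self, spans):
        return [GenomicInterval("c", a, b) for a, b in spans]

    def test_perfect(self):
        t = self._ivs([(0, 100), (200, 300), (400, 500)])
        ev = exon_eval(t, t)
        assert (ev.sensitivity, ev.specificity) == (1.0, 1.0)

    def test_two_of_three_plus_spurious(self):
        truth = self._ivs([(0, 100), (200, 300), (400, 500)])
        pred = self._ivs([(0, 100), (200, 300), (600, 700)])
        ev = exon_eval(pred, truth)
        assert ev.sensitivity == pytest.approx(2 / 3)
        assert ev.specificity == pytest.approx(2 / 3)

    def test_empty_predictions_flagged(self):
        ev = exon_eval([], self._ivs([(0, 100)]))
        assert ev.sensitivity == 0 and ev.specificity == 0 and ev.predicted_empty

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            exon_eval(self._ivs([(0, 100)]), [])


class TestPipelineOnNoisyFixtures:
    def test_jitter_tolerant_beats_exact_matching(self):
        plan = ContigPlan(
            seed=9, n_contigs=10, exons_per_contig=5,
            sources={"augustus": SourceNoise(sensitivity=0.8, fdr=0.1, jitter_sd=10)},
        )
        fx = generate_annotated_contigs(plan)
        regions = build_consensus_regions(fx.tracks)
        pred = [r.interval for r in regions]
        exact = exon_eval(pred, fx.truth_exons, tolerance=0)
        tolerant = exon_eval(pred, fx.truth_exons, tolerance=30)
        assert tolerant.sensitivity > exact.sensitivity
        assert tolerant.specificity >= exact.specificity

    def test_single_source_sensitivity_recovered(self):
        plan = ContigPlan(
            seed=9, n_contigs=25, exons_per_contig=8, contig_len=12000,
            sources={"augustus": SourceNoise(sensitivity=0.8, fdr=0.1, jitter_sd=0)},
        )
        fx = generate_annotated_contigs(plan)
        regions = build_consensus_regions(fx.tracks)
        ev = exon_eval([r.interval for r in regions], fx.truth_exons)
        n = len(fx.truth_exons)
        assert n >= 150
        # within 3 binomial sigmas of the planted per-source sensitivity
        sigma = np.sqrt(0.8 * 0.2 / n)
        assert abs(ev.sensitivity - 0.8) < 3 * sigma + 0.01
        # single configured source: scores can only be 0 or 1
        assert all(r.score in (0, 1) for r in regions)
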