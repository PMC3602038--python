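# Methods

This note records the models, parameter choices and numerical decisions
behind `exonforge`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Read cleaning

The cascade applies six rules in a fixed order — vector screen,
contaminant screen, organelle screen, minimum length, undetermined-base
fraction, end trimming — and attributes each removed read to the *first*
matching category. Published cleaning reports give disjoint per-category
counts without defining precedence; a fixed first-match-wins order is the
only way to make such counts well-defined, and it makes the ledger
conservation identity (input = kept + Σ removed) hold structurally. The
cascade is order-stable: permuting input reads permutes the survivors but
cannot change the ledger.

Thresholds (all in `DesignParams`): reads shorter than 100 bp are
removed; reads with strictly more than 3% non-ACGT bases are removed (a
read at exactly 3% is kept); 60 bp are trimmed from each end, and a read
whose remainder falls below 100 bp is removed as a `trim_casualty` — a
category the published ledgers fold into other counts. Trimming is
unconditional; the alternative reading (trim only when terminal bases are
masked) would make the kept count depend on the masking state, and the
unconditional rule is the reproducible one.

Similarity screens default to seqclean-like thresholds: 96% identity,
with a 30 bp minimum for hits touching the terminal 60 bp of a read
(where vector splices live) and 60 bp internally. Reference screens
(bacterial, organellar) additionally require the matches to cover ≥80%
of the read, since a read *is* contamination only when it is mostly
reference. Matching is ungapped: hits are found by exact shared 12-mers
(for ≥95% identity over ≥30 bp a clean 12-mer run exists by pigeonhole,
so seeding loses nothing at the default thresholds) and the longest
window meeting the identity threshold on each seeded diagonal is located
exactly by a prefix-sum argument. Tests verify the hit/no-hit decision
against an exhaustive naive diagonal-scan oracle.

## Repeat masking

Simple repeats are *perfect* tandem arrays with period 1–6, total length
≥18 bp and ≥4 copies; detection is exact and verified against an
exhaustive period×phase oracle. Alignment-scored degenerate arrays (what
Tandem Repeats Finder reports beyond perfect arrays) are out of scope:
the thresholds here are configurable, and perfect-array detection has a
checkable ground truth.

Library (complex-repeat) masking uses a different window criterion than
the screens: on each seeded diagonal the *maximum-scoring* window
(+1 match / −3 mismatch, Kadane's algorithm) is kept when it reaches
50 bp and 80% identity. A longest-window-at-threshold rule would absorb
flanking sequence that matches ~25% by chance — inflating masks by tens
of bp and letting sub-threshold copies qualify — whereas the scoring
window snaps to the copy boundaries, which is what overlap fractions
(the 25% filter rule) should be computed from.

Masking is soft (lowercase) and idempotent; all overlap arithmetic runs
on the explicit intervals, as a union (no double counting), and is
verified against a positionwise bitmap oracle.

## Evidence integration

Supporting intervals from all sources are merged wherever their coverage
is contiguous — overlapping *or directly adjacent* — and each maximal
covered run becomes one candidate region spanning the union. This makes
the construction identical to a positionwise union + connected-components
procedure, which is the oracle the tests compare against exactly.
Boundary refinement by re-running a gene predictor with hints is an
external-tool step and out of scope; the union span is deterministic and
checkable.

Scoring: score = number of distinct supporting sources (the default
configuration names seven: two ab initio predictors, three transcript
sources, protein homology, conservation), minus 1 when the region is
shorter than 100 bp, clamped to [0, 7]. The size of the short-region
penalty is a package choice (the design rule names a penalty without
quantifying it); one point is the smallest penalty expressible on an
integer evidence-count scale. Regions shorter than 60 bp are dropped
outright.

Filters, applied in order with the first matching rule logged:
(a) genomic regions supported only by ESTs; (b) regions supported only
by the ab initio predictor run without hints that overlap a repeat at
all; (c) regions matching transposable-element proteins (consumed as a
precomputed label track — protein search is out of scope); (d) regions
with repeat overlap strictly greater than 25% of their length (a region
at exactly 25% survives).

Strand is assigned by a majority vote over stranded supporting intervals
weighted by source class — transcript 4, ab initio 3, homology 2,
conservation 1 — with exact ties broken by the single highest-priority
stranded source, and `?` only when no stranded evidence overlaps.
Exon-level evaluation follows the gene-prediction convention:
sensitivity = exactly-matched/|truth|, "specificity" =
exactly-matched/|predicted| (a precision); an optional boundary tolerance
supports evaluating jittered evidence.

## EST branch

An ORF is ATG-initiated, stop-terminated, with the stop codon counted in
the length; the 150 bp minimum is exactly 50 codons. The longest ORF over
3 frames × 2 strands wins, ties going to the + strand and then the
smallest forward-strand coordinate. The search is verified against a
brute-force 6-frame enumeration on 1,000 seeded sequences.

Redundancy between an EST and a genomic candidate is called at ≥98%
identity of the shorter sequence aligned end-to-end (glocal edit
distance, either orientation) into the longer, i.e. identity
= 1 − dist/len(shorter); a sequence only partially similar dilutes its
identity below threshold and is kept. Genomic candidates always take
precedence; within the final join the precedence order is genomic origin,
then higher evidence score, then longer sequence, then id — fully
deterministic and order-independent.

## Probe selection

Each exon candidate receives `probes_per_exon` = 4 probes of
`probe_len` = 25 (the classic short-oligo array geometry; the probe
length is a configurable package default, not a published value).
Windows containing lowercase (masked) or ambiguous bases, or a k-mer
present in a background non-uniqueness index, are ineligible. Target
positions are spread evenly across the exon; each target takes the
nearest eligible window, preferring GC fraction in [0.3, 0.7]; probes
are non-overlapping whenever the exon is at least 100 bp, otherwise the
probeset is flagged as overlapping (a 60 bp exon can hold at most two
disjoint 25-mers). Selection is deterministic and seedless.

## Field-trial statistics

**Spatial correction.** Within one environment,
`value ~ 1 + Variety + s(row, column)` with `s` a tensor product of
cubic B-splines. Default 5 interior knots per dimension at coordinate
quantiles, automatically capped at (number of distinct coordinate values
− 4): a 6-row × 45-column field gets a 6×9-function basis, since more
functions than distinct coordinates are unidentifiable. The penalty is
the sum of squared second differences of the coefficient grid along each
dimension plus a 1e-8 ridge (absorbing the penalty null space), and the
smoothing weight λ is chosen by generalized cross-validation,
GCV(λ) = n·RSS/(n − edf)², over a 29-point log grid from 1e-8 to 1e6.
The fitted spatial component is centered to mean zero (its level belongs
to the intercept) and subtracted from the observations. With a noiseless
surface inside the basis span the fit is exact to numerical tolerance;
with the default simulation (amplitude 1 surface, noise sd 0.3 on a 6×45
grid) the recovered surface correlates with truth at ~0.96 (median over
20 seeds).

**Scaling and GGE.** Corrected plot values are aggregated to genotype
means per environment and divided by that environment's standard
deviation (ddof = 1) of genotype means, giving every environment unit
spread. Column (environment) centering then removes the environment main
effect, so the SVD axes carry G + G×E; both sides are scaled by √σᵢ
(symmetric biplot scaling, f = 0.5). Variance explained per axis is
100·σᵢ²/Σσⱼ² over the full spectrum and sums to 100 by construction;
keeping all axes reconstructs the centered matrix to machine precision.

**Ideal-cultivar ranking.** The average-environment axis is the mean of
the environment loading vectors; a genotype's projection on it is its
trait level and the norm of the orthogonal remainder its instability.
Ranking is by level with instability as tie-break, where levels within
1e-3 of the observed level range count as tied — without that tolerance
two genotypes with identical means can differ in projected level by
~1e-4 from the asymmetries of symmetric scaling, and stability would
never participate.

**Contrasts.** Welch's unequal-variance t-test (two-sided) with
per-group t-based 95% confidence intervals, and the relative decrease
100·(1 − mean_A/mean_B). The decrease is antisymmetric under group swap
via d ↔ 100·(1 − 1/(1 − d/100)). Degenerate zero-variance groups with
equal means report p = 1.

## Synthetic data: what it does and does not show

The generators are pure functions of (plan, seed); every record carries
exactly one truth label. Read lengths follow normal(650, 100) truncated
to [100, 1000] bp (Sanger survey reads); clean reads are drawn at
≥220 bp so they survive end-trimming, making the noiseless ledger equal
the plan exactly. Contig-truncation lengths default to a log-normal with
median ≈990 bp, the scale of a sparse draft assembly. Evidence
corruption is parameterized per source by sensitivity, false-discovery
rate and Gaussian boundary jitter. Field trials plant additive G
(sd 0.6), E (sd 0.5), G×E (sd 0.15), block (sd 0.1) effects, a smooth
sinusoidal surface (amplitude 1) and noise (sd 0.3) around a mean of
3 mg/kg — the scale of leaf-cadmium measurements.

Planted contamination is substitution-only (the screens are ungapped by
design), repeats are exact or near-exact library copies, and evidence
errors are independent across sources. Real survey data adds indels,
diverged repeat families, chimeric reads and correlated evidence errors;
passing these tests therefore demonstrates correctness of the
accounting, interval algebra, search algorithms and statistical recovery
under the stated model, not the end-to-end yield on real archives.
Dataset-scale published counts (hundreds of thousands of candidates)
depend on the real sequence archives and external predictors and are not
reproduced here; the accounting identities that connect them are.

## Problem sizes

The test suite and acceptance script run at desk scale: 100-read
cleaning fixtures, 50 random contigs up to 50 kb for the
consensus-region oracle, 1,000 sequences for the ORF oracle, 2 kb
sequences for the tandem oracle, and 20 seeded 6×45 field simulations —
sizes chosen so every oracle comparison is exhaustive and the whole
suite completes in well under a minute per property.
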