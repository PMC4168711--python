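# Methods

## Model

A paired-end fragment is summarized by its midpoint µᵢ (the dyad estimate)
and insert size wᵢ. The caller models the uncertainty of each dyad estimate
as a Gaussian centered at µᵢ whose standard deviation α·wᵢ grows with the
insert size: a long template constrains the dyad loosely, a short one
tightly. The scale parameter α plays the role of a smoothing bandwidth, but
rather than choosing one value the caller evaluates a whole family,
α ∈ [0.05, 0.63] on an arithmetic grid of m = 40 values (both endpoints
included). In the α → 0 limit the profile degenerates to a histogram of
midpoint counts; large α merges neighboring nucleosomes.

Profiles are normalized into landscapes N_α = log((S_α+ε)/(S_A+ε)) by a
single low-resolution profile at A = 1.5. Because A exceeds every grid α by
roughly 2.4–30×, S_A acts as a local background: the log-ratio amplifies
candidate peaks in low-coverage regions, damps them in high-coverage ones,
and cancels multiplicative biases (mappability, digestion preference) that
multiply numerator and denominator alike.

Candidates are the strict local maxima of each landscape; a peak's width s
is the distance to its nearest local minimum, and its basin is the interval
between the two flanking minima. Each candidate is recentered on the
unweighted centroid of the fragment midpoints falling in its basin (basins
partition a chromosome at each scale, using half-open intervals so a
midpoint on a shared minimum belongs to exactly one basin). The consensus is
assembled from fine to coarse scale under the rule that two candidates
closer than 146 bp overlap: a candidate is admitted only if it overlaps no
other candidate of its own scale and no accepted call; accepted calls are
never removed. Overlap is always evaluated on recentered positions, since
those are the reported coordinates that must honor the non-overlap
guarantee.

## Parameters

| parameter | default | meaning |
|---|---|---|
| m | 40 | number of smoothing scales |
| α range | [0.05, 0.63] | kernel sd per bp of insert; 0.05·146 ≈ 7 bp to 0.63·146 ≈ 92 bp |
| A | 1.5 | background scale (σ ≈ 220 bp for a 146 bp insert) |
| ε | 1e-6 | log-ratio pseudocount; far below any profile value at realistic coverage, so it only regularizes exact zeros |
| nucleosome size | 146 bp | overlap threshold and the knee of the weight penalty |
| γ(w) | min(1, w/146) | short-fragment penalty: the simplest nondecreasing weight reaching 1 at the nucleosome size; configurable |
| insert filter | [40, 1000] bp | retained bounds inclusive |
| truncation | 6σ | per-fragment kernel support; lost mass < 2e-9 |

## Numerical choices

* Profiles are sampled at integer base positions; kernels are tabulated once
  per (α, insert size) and shared across fragments, so each insert-size
  class is accumulated as an impulse train convolved with its kernel.
  Midpoints of odd-length fragments are half-integers; their kernels are
  tabulated with a half-base shift rather than rounded, avoiding a
  systematic half-bp bias in the centroids.
* Where S_α and S_A are bitwise equal (e.g. both zero far from any data) the
  landscape is exactly 0, so empty stretches are perfectly flat.
* Extrema are found in one linear scan. A flat plateau that is a maximum
  contributes one extremum at its floored midpoint; region endpoints count
  as minima, which makes s and basins well-defined for edge peaks.
* Candidates whose landscape height is ≤ 0 are discarded. A non-positive
  maximum means the fine-scale profile is not enriched over the background
  there; such maxima arise in coverage gaps purely from the shape of S_A
  (the log-ratio is locally −log(S_A+ε) where S_α = 0) and would otherwise
  be admitted as support-free calls between distant clusters.
* Within one scale, surviving candidates are processed left to right. Under
  the admission rule, order cannot change which candidates survive the
  within-set check (a candidate is vetoed by *any* same-scale neighbor
  closer than 146 bp, vetoed or not), so this only fixes output numbering.
* The weight denominator n is the per-processed-region fragment count.
  Landscapes are invariant to this choice because S_α and S_A share it.
* A chromosome's region, when not given, is the fragment span padded by the
  background kernel support (6·A·max w), so no probability mass is clipped.
* If recentering leaves a candidate with an empty basin, its position stays
  at the raw maximum and a warning is logged.

## Synthetic benchmark

`simulate_toy` emulates a single nucleosome probed at low coverage: 146 bp
fragments, midpoints Normal(300, 40), 20 reads (≈20-fold coverage).

`synthetic_nuc_map` emulates the standard regular-array benchmark:
well-positioned nucleosomes (midpoint sd 30) on a grid with 147 bp cores and
20 bp linkers (167 bp period), a configurable number deleted at random, and
fuzzy nucleosomes (midpoint sd 50) dropped uniformly anywhere, overlaps
allowed. The per-nucleosome read count is drawn Uniform{⌈max_cover/2⌉ ..
max_cover}; the exact count law of the original generator is not published,
so this package uses the simplest law for which max_cover (default 70) is a
per-nucleosome coverage ceiling — verified as such (≤1.2× slack) by a
property test. Chromosome length is wp_num·(nuc_len+lin_len)+lin_len.

The generator omits sequencing error, base quality, mappability structure,
GC bias and duplicate reads. Passing benchmarks therefore demonstrates
correct recovery of positional signal from midpoint scatter — not robustness
to alignment artifacts; on real data the insert filter and the S_A
normalization carry that burden, and duplicates are deliberately retained
(no deduplication step).

Positioning error matches calls to truths greedily by increasing distance,
each used at most once, capped at 100 bp; unmatched items on either side are
reported separately. The over-reporting readout chains consecutive calls
≤148 bp apart and counts each chain once.

The experiment grids reproduce two protocols: a fuzzy-fraction sweep
(r = 0…1, replicated maps with wp_num = 1100, wp_del = 100 + 1000r,
fuz_num = 1000r, each scalable down by a single factor for desk runs) and a
subsampling sweep (fractions of a fragment set, calls per fraction).
Per-replicate seeds are spawned as SeedSequence(master, spawn_key=(condition,
replicate)), so any replicate reruns in isolation; every reported summary is
recomputable from the stored per-replicate values.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run the array benchmark at 1/10
scale (110 grid positions, 10 deleted, coverage 70 → ≈5,300 fragments over
≈18 kb), which this package treats as its standard desk-scale configuration;
the full-scale map (1,000 nucleosomes) is exercised for generation counts.
The adjacent-distance readout aggregates ten replicate datasets, mirroring
the ten-replicates-per-condition design of the sweep protocol: a single
1/10-scale dataset yields only ~99 adjacent spacings, too few to identify a
5 bp modal bin stably (call centroids carry ~4 bp standard error, so
adjacent spacings scatter with sd ≈ 7 bp around 167 bp).

## Known limitations

* Strict monotonicity of candidate counts in α is guaranteed (heat-kernel
  causality) only when all fragments share one insert size; with mixed
  lengths each fragment diffuses at its own rate and rare violations occur.
  The property tests exercise the shared-length regime.
* The caller reports dyad positions and a fixed 147 bp footprint; it does
  not estimate per-nucleosome fuzziness or occupancy, and provides no
  significance testing or control-track normalization.
* Greedy truth-call matching is not globally optimal assignment; for
  well-separated maps (spacing ≫ the 100 bp cap) the two coincide, which is
  the regime of the benchmark.
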