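# puffin-nucleosomes

Parameter-free nucleosome positioning from paired-end MNase-seq / ChIP-seq
reads.

Nucleosomes — ~147 bp of DNA wrapped around a histone octamer — are mapped
experimentally by sequencing the MNase-protected fragments; the midpoint of a
paired-end fragment estimates a nucleosome dyad. Turning millions of noisy
midpoints into a set of non-overlapping nucleosome calls usually requires the
user to pick a smoothing kernel, a bandwidth, and legal fragment-size ranges,
and the "right" values differ between loci because MNase digestion is
sequence-dependent. This package implements a multi-resolution caller that
removes those choices: it examines every locus at a whole family of smoothing
scales at once and lets each nucleosome be called at whichever scale resolves
it best. It is intended for genomicists analyzing paired-end MNase-seq or
histone ChIP-seq data without a control track.

## Method

Each mapped fragment *i* (midpoint µᵢ, insert size wᵢ) is replaced by a
Gaussian with mean µᵢ and standard deviation α·wᵢ, so loosely constrained
(long) fragments spread their evidence wider than tight ones. The profile at
scale α is the weighted sum

    S_α(x) = Σᵢ βᵢ 𝒩(x; µᵢ, α·wᵢ),    βᵢ = γ(wᵢ)/n,

where γ(w) = min(1, w/146) down-weights sub-nucleosomal fragments. A family
of m = 40 profiles over α ∈ [0.05, 0.63] is normalized by a very smooth
reference profile (A = 1.5) into landscapes

    N_α(x) = log (S_α(x)+ε)/(S_A(x)+ε),

which equalizes peak heights across coverage levels and cancels slowly
varying biases shared by numerator and denominator. Candidate nucleosomes are
the local maxima of each landscape (recentered on the centroid of their
supporting fragment midpoints), and the final map is built greedily from the
finest scale to the coarsest: a candidate is admitted if it is at least
146 bp from every other candidate of its own scale and from every call
already accepted. Well-positioned nucleosomes enter at fine scales; fuzzy
ones, whose fine-scale sub-peaks collide and annihilate, are rescued at
coarser scales. The output is guaranteed non-overlapping, and total work is
linear in reads and region length.

## Worked example

Simulate a 1/10-scale regular nucleosome array (110 grid positions of 147 bp
cores separated by 20 bp linkers, 10 deleted at random, per-nucleosome
coverage ≤ 70), call it, and score the calls against the truth:

```
$ puffin simulate map --wp-num 110 --wp-del 10 --seed 1 \
      --out frags.bed --truth-out truth.bed
wrote 5340 fragments for 100 nucleosomes to frags.bed

$ puffin call --bed-fragments frags.bed --out calls.bed
wrote 100 nucleosome calls to calls.bed

$ puffin evaluate --truth truth.bed --calls calls.bed
matched 100 calls; 0 calls and 0 truths unmatched; mean positioning error 4.12 bp
```

All 100 true nucleosomes are recovered, each to within a few bp (the centroid
of ~50 midpoints with sd 30 has a ~4 bp standard error, so this is at the
information limit of the data). `calls.bed` is BED6, one 147 bp feature per
call, score = landscape height scaled to [0, 1000]:

```
chrS    18     165    nuc1    928    .
chrS    187    334    nuc2    787    .
```

Real alignments are consumed the same way via `puffin call --bam sorted.bam`
(properly paired, uniquely mapped templates with inserts in [40, 1000] bp).
Sweep experiments are available as `puffin sweep-fuzzy` and
`puffin sweep-coverage`; both write TSV summaries.

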