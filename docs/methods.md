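# Methods

## Statistical model of the classification

Each feature (protein/transcript pair) is measured in five layers — protein
intensity, total mRNA, free mRNA, monosome-fraction mRNA, polysome-fraction
mRNA — across paired units (cell lines) in two conditions. The pipeline
treats abundances as continuous positive quantities and works on per-feature
replicate vectors; no count model or variance shrinkage is applied (that is
a deliberate non-goal: the calls are meant to reproduce plain multiple
t-testing, not moderated differential expression).

### Direction calls

Control and treated replicates are compared with a two-tailed two-sample
t test (pooled variance by default; Welch and paired variants are flags —
the units are matched, so a paired analysis is defensible, but the default
follows the plain reading of "two-tailed t tests" on independent group
means). Significance defaults to raw *p* < α = 0.05; a Benjamini–Hochberg
gate at *q* = 0.05 is selectable (`gate="bh"`), and each output row records
which gate produced it. Both gates exist because both conventions are
common; the BH gate is never more permissive than the raw gate on the same
data.

Significant features are `up` or `down` by the treated/control ratio of
means (a linear fold change; the control mean must be positive).
Non-significant features are `stable` only under equivalence by CI
containment: with control CI (L, H) and treated CI (l, h), stable requires

    0.70 · max(L, 0) ≤ l  and  h ≤ 1.30 · H.

The 95% CIs are the usual t intervals, mean ± t₀.₉₇₅,ₙ₋₁·sd/√n. The low
end is clamped to zero before the 70% factor because abundances are
nonnegative and a negative low end would invert the band. Features that
are neither significant nor contained are `other`; so are features that
cannot be tested (missing replicates, zero control mean), with the reason
logged and recorded. Two zero-variance vectors with equal means are stable
with *p* = 1 by convention.

### Polysome/monosome shift

PM ratios are formed per sample — (polysome + ε)/(monosome + ε) with a
symmetric pseudocount ε = 0.5 by default — then tested across samples.
Forming the ratio within a sample first preserves replicate variance and
cancels sequencing depth, so no library-size normalization is applied
inside the ratio (an optional per-fraction column scaling exists for
grossly unequal fraction depths). The X statistic is the ratio of the mean
PM ratios (treated over control), not the mean of paired ratios. Verdicts
mirror the direction calls: significant and X > 1 → `m_to_p`, significant
and X < 1 → `p_to_m`, non-significant and PM-ratio CIs contained →
`stable`, else `other`. Features detected in only one fraction are
excluded and counted.

Under the generator's conservation property, X estimates the allocation
odds ratio: with polysome fraction θ moving from θc to θt, noiseless data
give X = [θt/(1−θt)]/[θc/(1−θc)] exactly (0.5 → 0.8 implies X = 4).

### Group taxonomy

The triple of calls indexes the 27 groups by `9·p + 3·r + s + 1`
(protein, RNA ∈ {up 0, stable 1, down 2}; shift ∈ {m_to_p 0, stable 1,
p_to_m 2}). This numbering is fixed by requiring several named anchors to
hold at once — group 4 = (up, stable, m_to_p), group 7 = (up, down,
m_to_p), group 13 = (stable, stable, m_to_p), group 14 all-stable, groups
19–27 protein-down, and the protein/mRNA mismatch set exactly
{4–12} ∪ {16–24} — and those anchors are asserted jointly in the tests.
Any `other` call leaves the feature unassigned, with the offending layer
recorded. The within-group association between translation shift and
protein change is summarized by the correlation of log X with the log
protein fold change; Spearman by default (robust on the ratio scale),
Pearson as an option.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: 4 paired
units × 2 conditions × 5 layers, one replicate column per unit. Each
feature draws a lognormal baseline (default log-mean 6, log-sd 1, i.e.
abundances of a few hundred with a 10-fold spread) and realizes its group's
template: RNA effect on the total pool (fold 2 up / 0.5 down), a fixed
fractionation efficiency (0.8) splitting the pool into monosome + polysome
by an allocation θ (base 0.5; 0.8 for m_to_p features, 0.2 for p_to_m),
and a protein effect (fold 2 / 0.5). The free-mRNA layer carries the
remaining 20% of the pool and no effect template; the classification
ignores it. Replicate noise is multiplicative lognormal with CV 0.1
(mean-preserving); a negative-binomial mode exists for the RNA layers as a
robustness check. Defaults were chosen once, for testability at the
study's scale — the underlying experiments publish no effect-size or
dispersion estimates — and are not tuned thereafter.

With `couple_protein_to_shift`, each shifted feature's treated allocation
is jittered on the logit scale (sd 0.25) and, where the protein template
agrees in sign with the shift, the protein fold change follows the
realized allocation odds ratio raised to a power chosen so the template
odds ratio maps to the template fold change. This produces the positive
log X / log protein-ratio correlation the correlation analysis is meant to
detect, without disturbing any other group's defining triple.

Motifs and uORFs are planted by verbatim substring replacement at a
recorded position inside a named region; `rate` < 1 selects exactly
`round(rate·n)` targets deterministically from the seed. Generated 5′UTRs
are scrubbed of incidental ATGs so planted uORFs dominate the ATG-only
mode. All randomness flows from a single `numpy` Generator seeded by the
configuration, so identical configurations are bit-reproducible.

What the generator does **not** emulate: raw reads or spectra, library-prep
and coverage biases, missing-not-at-random proteomics dropout, correlated
features, or realistic transcript composition. Passing tests therefore
demonstrate that the statistical machinery recovers known structure under
its own assumptions, not that those assumptions hold for any particular
real dataset.

## Motif discovery and scanning

The ZOOPS model: a sequence carries a motif site with prior γ (uniform
over eligible positions) emitted by a 4×W position probability matrix,
otherwise pure 0-order background (estimated from the input set). EM
alternates posterior site probabilities with PWM/γ updates; the M-step
adds a 0.01 pseudocount per cell, making the fit a MAP estimate. The
exactly monotone quantity under MAP-EM is the penalized objective
(log-likelihood plus the Dirichlet log-prior); `loglik_path` stores it and
the fit asserts it never decreases, while `loglik` reports the plain
observed-data value at convergence. Starting points are MEME-like: every
data W-mer is evaluated as a candidate consensus (as a 0.7-match PWM its
ZOOPS score reduces, up to a per-window constant, to a Hamming-similarity
matrix — one one-hot matmul), the top distinct W-mers seed EM, padded with
random Dirichlet starts; everything is deterministic given the seed.

Width selection over 10–25 nt maximizes the log-likelihood ratio against
the background-only model, penalized BIC-style by the parameter count
3W + 1 with the **total nucleotide count** as the sample size. The
sequence-count convention under-penalizes: one lucky random flank column
(a χ²₃ tail event per extra width) could then out-score its penalty and
inflate the width. No MEME E-value is computed; the selection makes no
compatibility claim with MEME's statistic.

Scanning is sense-strand only (these are mRNA motifs). Window scores are
integer-rescaled log-odds (step 10⁻³ nats); the null distribution of a
background W-mer's total score is built by exact dynamic programming over
the per-column score distributions, and each window's p-value is the
lattice survival probability — identical to exhaustive 4^W enumeration, as
the tests verify. Windows at p ≤ 10⁻⁴ (a flag; no canonical threshold
exists) are reported, greedily made non-overlapping by ascending p-value
with leftmost tie-break, and labeled with their annotated region
(`spanning` across a boundary). Coordinates are 1-based inclusive
throughout; CDS-local positions are global minus the 5′UTR length.

## uORF detection

Every active start codon whose first base lies in the 5′UTR opens a
candidate, extended in frame to the first TAA/TAG/TGA: `contained` if the
stop precedes the CDS, `overlapping` if it falls inside it, `no_stop`
otherwise. The alternative-initiation set defaults to {CTG, GTG, TTG} and
is configurable and echoed in output headers, since ORF-finder tools do
not document a single canonical set; ATG-only results are always a subset
of the alternative mode. No minimum length is imposed by default and
nested starts are reported independently — prevalence ("≥ 1 uORF") is
insensitive to nesting. Cross-group prevalence is compared with a
chi-square test of homogeneity on the with/without counts, excluding empty
groups.

## Numerical and degenerate-input choices

- Zero-variance CIs collapse to a point; identical vectors are stable.
- Zero control mean → `other` (ratio undefined), logged; all-zero control
  PM ratios → error at the single-feature level, `other` in table scans.
- γ is clipped to [10⁻⁴, 1−10⁻⁴]; PWM entries are floored by the M-step
  pseudocount, so log-odds are always finite.
- The score lattice refuses to allocate above 5·10⁷ cells and suggests a
  coarser precision instead.
- Equivalence comparisons use closed intervals (boundary containment
  counts as contained).

## Problem sizes

The validation suite runs at deliberately small scale — hundreds of
features, 20 sequences of 100 nt for discovery, widths 10–25, 4³–4⁸
enumerations — chosen so every check (including the exact-enumeration
oracles) completes in seconds while leaving the statistical effects far
from their decision boundaries (e.g. ~90% group recovery against an 85%
bar, planted-motif log-likelihood gains ~25× the selection penalty).

## Known limitations

- The equivalence band (70%/130%) is asymmetric on the ratio scale and
  anchored on the control CI, so `stable` is not symmetric under swapping
  condition labels (only the significant verdicts are).
- Raw-p gating at α = 0.05 leaves ~5% false significants per layer; fully
  stable features are recovered at ≈ 0.95³ ≈ 86–91% by construction.
- The ratio-of-means X and the pooled t test assume roughly homoscedastic,
  approximately normal replicate noise on the ratio scale; heavy-tailed
  dispersion would call for the Welch or paired flags.
- Motif discovery fits one motif per run (no multi-motif erasure) and no
  RNA secondary structure; E-values are not computed.
- The free-mRNA layer is generated but unused, mirroring the analysis
  design it emulates.
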