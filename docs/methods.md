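# Methods

## Sequence model

The data are *n* sequences over {A,C,G,T} (ambiguous `N` permitted; any
width-*w* window containing `N` gets prior and likelihood zero and can
never be selected as a site).  A motif of width *w* is a column-stochastic
PSPM θ.  Hidden indicators `Z[i,j]` mark a site starting at position *j*
of sequence *i*; OOPS fixes exactly one site per sequence, ZOOPS allows
zero or one with site frequency γ.  The letters outside a site follow a
background model; inside a site, column *k* of θ.

A position-specific prior supplies `P[i,j]` (prior probability of a site
of design width `w0` starting at *j*) and a no-site mass `P[i,0]`, with
`P[i,0] + Σ_j P[i,j] = 1` per sequence, `P[i,j] = 0` where a site cannot
fit, and `P[i,0] = 0` under OOPS.  On double-stranded DNA the prior is
strand-symmetric by construction: only the forward array is stored and a
reverse-strand site takes the forward value at its leftmost forward
coordinate.  In the E-step the prior factorizes with γ:

    Pr(site at (j, strand)) = γ · q[i,j] / n_strands,
    q[i,j] = P[i,j] / (1 − P[i,0]),      Pr(no site) = 1 − γ.

This reduces to the plain uniform-prior model when the PSP is uniform and
to the OOPS case when γ = 1 and `P[i,0] = 0`.  "No prior supplied" is
implemented as the uniform prior at the smallest search width, so the two
code paths are literally the same and agree bitwise.

### Width renormalization

A width-`w0` prior searched at width `w > w0` is renormalized: the raw
prior of a wide site is the geometric mean of the priors of the
`c = min(w − w0 + 1, w0)` contained design-width sites left-aligned at
its start, after which the positional mass is rescaled per sequence to
`1 − P[i,0]` (an open choice; preserving the user's site/no-site balance
seemed the least surprising).  If every raw value vanishes the prior
falls back to uniform over legal positions, with a warning.  For
`w < w0` the prior is reused unchanged, leaving the trailing
newly-legal start positions at prior zero.  Log-addends of each
geometric mean are sorted before summation, which makes renormalization
exactly equivariant under mirroring the prior (needed for exact strand
symmetry below); the rescaling denominator uses exact (`fsum`)
summation for the same reason.

## The three phases

**Phase I (starting points).**  Candidate starting matrices are built
from width-*w* subsequences of the data: the word's letter gets
probability β = 0.55 per column, the rest spread evenly (β must exceed
1/4; 0.55 is a moderate sharpening that lets one EM step move freely).
Every legal site is scored by `Pr(window|θ_candidate) × P[i,j]`; under
OOPS the best site per sequence is taken, under ZOOPS sites are sorted by
that posterior product, at most one per sequence, and prefixes of size
*t* from the schedule {2, 4, 8, ..., n} are formed.  Each site set is
scored by the weighted LLR: site counts are weighted by
`b[i,j] = P[i,j]/max_j P[i,j]` (all 1 under a uniform prior), counts are
normalized to frequencies, and the score is
`Σ_k Σ_a c[a,k] log2(f[a,k]/p_a)` in bits with `0·log 0 = 0`.  The best
candidate per (width, t) seeds EM.

At desk scale evaluating *every* subsequence as a candidate is quadratic
in the dataset; the engine therefore screens a deterministic,
evenly-spaced subsample of at most `max_starts` (default 500) candidate
words.  Datasets below the cap are screened exhaustively, so the small
test fixtures exercise the full search.

**Phase II (EM).**  The E-step computes the posterior `Z` from the prior
factorization above, normalizing per sequence over both strands plus the
no-site outcome; likelihood ratios against the zero-order background
marginals keep everything in well-scaled linear arithmetic.  The M-step
re-estimates θ from Z-weighted letter counts with a background-
proportional pseudocount `δ_a = 0.01·p_a` (a Dirichlet smoothing; the
objective below includes the matching `Σ δ_a log θ` term so EM is a MAP
ascent), and γ (ZOOPS) as the mean posterior site probability clamped to
[1/n, 1].  The PSP is held fixed throughout.  Iteration stops when
`max |Δθ| < 1e-3` or after 50 iterations; the observed-data log posterior
is recorded each iteration and is non-decreasing (this is asserted in the
tests at relative tolerance 1e-8).

**Phase III (scoring).**  The motif's sites are those with the largest
final Z (one per sequence at most; ZOOPS scores every prefix of the
Z-ranked list from 2 to n).  Each column of the (unweighted) site
alignment gets a p-value `Pr(column LLR ≥ observed)` under i.i.d.
background draws — computed by exact enumeration of all multinomial
compositions for up to 200 sites, and by a dynamic program on a
discretized score lattice (2^14 bins spanning the achievable score range,
floor-binned so tails are never under-counted) above that.  The product
of the *w* column p-values *p* is corrected for multiplicity with the
exact distribution of a product of independent uniforms,
`p · Σ_{i<w} (ln 1/p)^i / i!`, evaluated in log space.  The E-value
multiplies this by the number of ways to place the sites:
`Π_i (strands·m_i)` for OOPS and `C(n,t) · Π_{chosen} (strands·m_i)` for
ZOOPS with *t* sites (unordered placement; `m_i = L_i − w + 1`).  The
candidate with the smallest E-value over all widths and site counts is
reported; E-values are compared in log10 space throughout.

The *reported* motif matrix is the empirical frequency matrix of the
selected sites (exact rationals `counts/t`).  This makes the report a
discrete object: two runs that select the same sites report bitwise
identical motifs, which is what lets the strand-symmetry guarantee hold
exactly rather than to rounding error.  The smoothed EM matrix θ is also
returned and is the right choice for scanning (AMA), where exact zeros
would be pathological.

**Erasing.**  After a motif is reported, every position is down-weighted
by `Π (1 − Z)` over the site starts covering it; later passes multiply
the site prior mass at each start by the retained weight and renormalize
per sequence.  Retention weights are non-increasing across motifs.

**Ties.**  All orderings are stable sorts over (sequence, strand,
position), and "better" is always a strict inequality, so discovery is
fully deterministic given its inputs; the `seed` argument exists for
interface stability and influences nothing.

## Background models

Order-k Markov chains with per-context conditionals; the zero-order
marginals `p_a` are what enter LLRs, column p-values and the E-step (the
significance machinery is defined against the letter null).  The full
chain is used for window null probabilities in AMA scoring.  Estimation
from data pools both strands in double-strand mode (a strand-symmetric
null, which also makes background estimation invariant under
reverse-complementing the input) and adds `0.01 · total/cells` to every
count cell so no probability is zero.  The default background is the
zero-order letter composition of the input.

## Evaluation metrics

`scaled_distance` implements
`D = (1/w) Σ_i ||f_·,i − g_·,i||_2 / √2 ∈ [0, 1]`.
`aligned_distance` minimizes the per-overlap-column mean over all offsets
with overlap ≥ the shorter width and over the reverse complement; the
per-overlap normalization (rather than by the shorter motif's full
width) is a documented choice — it treats every aligned column equally
and cannot reward short accidental overlaps because the overlap is
bounded below.  With the IC filter on, a reported motif lacking a
6-column window of ≥ 1 bit mean information content against a uniform
background scores the maximal distance 1.0; success is the strict
`D < 0.25`.  AMA is the mean over all legal (position, strand) windows of
`Pr(window|θ)/Pr(window|background)`, with N-containing windows excluded
from the average.  Spearman correlation uses mid-ranks (scipy), returning
NaN with a warning for constant input; the sign test is the exact
two-sided binomial test at probability 1/2 with ties removed beforehand.

## Synthetic data

`generate_dataset` draws background residues from the stated background
model and plants one PSPM-sampled site at a uniform legal position in
`floor(φ_site · n)` randomly chosen sequences (strand chosen uniformly
under the "both" policy), recording the truth.  One site per sequence at
most, matching the OOPS/ZOOPS scope.  The default regime — n = 50
sequences of 200 bp, a width-8 motif with one dominant letter at
probability 0.87 per column (~1.2 bits mean IC) planted in half the
sequences — is deliberately weak: strong motifs are found with or without
a prior, so this is the regime where a prior's benefit is measurable.
`generate_psp` builds an idealized informative prior from the truth:
mass `concentration` on the true start spread ±1 by a triangular kernel,
the remainder uniform; siteless sequences get `P[i,0] = concentration`
under ZOOPS.  Concentration 0 reproduces the uniform prior exactly.

What this emulates — and does not.  The generator reproduces the
*structure* of a ChIP positive set (a planted, possibly reverse-strand,
weak motif in a fraction of sequences) and of an informative prior
anchored near true sites.  It does not reproduce genomic base
composition, repeats, multi-site sequences, correlated prior errors, or
the imperfect, conservation-derived priors used on real data — so
passing the directional benchmark here shows the machinery exploits a
good prior correctly, not how large the benefit is on any real dataset.

## Numerical choices and edge cases

- Bits (log base 2) for all user-facing scores; natural logs internally.
- Column p-value threshold comparisons use `observed − 1e-9` so ties at
  the observed score are always included.
- Degenerate inputs: empty sequence sets, sequences shorter than the
  motif, all-zero priors, and zero-site columns raise informative errors
  (or return the defined boundary value, e.g. p = 1 for zero sites).
- `renormalize_psp` is idempotent at fixed width and maps constant
  priors to constant priors.
- Exact composition enumeration is O(t³) in the site count and is capped
  at 200 sites, far above the benchmark sizes used here (n = 50).

## Known limitations

- The ANR model (any number of repeats per sequence) is out of scope.
- Protein alphabets are supported by the containers and likelihoods, but
  column p-values for 20 letters always use the lattice approximation,
  and Phase I/EM defaults are tuned for DNA.
- The IC filter applies to the reported motif only, against a uniform
  background, matching the benchmark convention rather than adapting to
  skewed genomes.
- Phase I's candidate subsample can in principle miss the best starting
  word on very large inputs; raise `max_starts` to trade time for
  thoroughness.
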