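# Methods

## Problem and model

Given reads R sampled uniformly from an unknown haploid genome G, the
assembler must decide, for every de Bruijn graph edge, whether the one-base
extension it represents is *unique* in G — i.e. whether every genomic copy
of the k-mer S is followed by the same base c. Using a non-unique extension
can create a chimeric contig, because the graph carries no information about
which copy of S a walk is in.

The decision is probabilistic. If S is unique in G, a non-unique extension
is impossible and the misassembly probability is 0. If S is an α-repeat
(α ≥ 2 genomic copies) with abundance a in the reads, the worst case for a
wrongly-confident extension is α−1 copies agreeing on c and one copy
differing: the abundance of Sc is then Binomial(a, (α−1)/α), and the chance
that a *non-unique* extension nevertheless reaches abundance ℓ is the
binomial right tail. Since any of the α extensions can be the majority one,
the tail is scaled by α and clamped at 1. The repeat multiplicity is not
observed, so the per-α probabilities are mixed over a posterior P(α | a)
derived from the k-mer abundance histogram; classes α = 0 (sequencing-error
k-mers) and α = 1 contribute nothing to the mixture. α is capped at 5; mass
beyond that is absorbed into the α = 5 class with no open-ended tail
correction, which slightly understates risk for very high-copy repeats —
a deliberate trade for a bounded class set.

Two tail evaluators are provided:

* `exact` (default): log-space summation of the binomial pmf via log-gamma
  terms and logsumexp. Exact to floating precision and cheap at desk scale.
* `ferrante`: the Chernoff-type right-tail upper bound
  (1/(1−r)) · (2π x(1−x) a)^(−1/2) · exp(−a D(x‖p)) with x = ℓ/a,
  p = (α−1)/α, odds ratio r = p(1−x)/(x(1−p)) and Bernoulli KL divergence
  D(x‖p) = x ln(x/p) + (1−x) ln((1−x)/(1−p)). It is valid only for
  x > p and ℓ < a; outside that region the implementation falls back to the
  exact tail (at ℓ = a the closed form p^a *is* the exact tail). The bound
  dominates the exact tail everywhere on its validity region (verified
  exhaustively for a ≤ 60 in the test suite), so using `exact` by default
  preserves or improves the guarantee while giving tighter thresholds.

## Thresholds

Rather than scoring every edge, the pipeline tabulates once per node
abundance a the minimal extension abundance ℓ*(a) whose total mixed
probability falls below the user bound ε, then applies the table to all
edges. The scan runs over ℓ ∈ [⌊a/2⌋+1, a]; if even ℓ = a fails, the entry
is *absent* and no extension from abundance-a nodes is ever trusted. The
scan floor structurally enforces ℓ*(a) > a/2. Combined with the fact that
the edge abundances on one side of a node sum to at most the node abundance,
this makes two qualifying edges on one side impossible: traversal needs no
branch resolution. The monotone consequences — ℓ* non-increasing in ε,
`exact` thresholds never above `ferrante` thresholds — are asserted in the
tests.

## Mixture fit

The repeat-multiplicity posterior is obtained by fitting the abundance
histogram with a six-component mixture: an error component (α = 0) with its
own small mean, and components α = 1..5 with means α·λ sharing one
variance-to-mean dispersion d. Components are negative binomial,
zero-truncated because abundance-0 k-mers are unobservable. Histogram bins
are weighted by their k-mer counts and the fit is EM:

* E-step and the weight update are standard and closed-form.
* The (error mean, λ, d) update is a Nelder–Mead maximisation of the
  expected complete-data log-likelihood in log-parameter space, started at
  the current values and accepted only if it does not decrease the
  objective — a generalised EM step, so the observed log-likelihood is
  non-decreasing (asserted in tests).

Initialisation: λ ← the histogram mode restricted to a ≥ 5 (global mode as
fallback, floored at 2); weights ← (0.1, 0.7, 0.1, 0.05, 0.03, 0.02); error
mean ← 1; d ← a moment estimate of variance/mean in a window around the
mode, floored at 1.05. Convergence at relative log-likelihood change
≤ 1e-6, at most 500 iterations (flagged if hit). The initialisation is
deterministic; the `seed` argument exists for interface stability. On
histograms simulated from known parameters the fit recovers λ within 5% and
weights within 0.1 absolute across seeds (tested over 10 seeds).

A posterior can also be supplied as TSV (`abundance p0 .. p5`, rows from
abundance 1 with no gaps, each summing to 1 within 1e-6), allowing estimates
from external multiplicity tools to replace the built-in fit.

## Graph construction

Canonical form is the lexicographic minimum of a k-mer and its reverse
complement; k is restricted to odd values in [3, 31] so no k-mer is its own
reverse complement and a (k+1)-mer packs into 64 bits. Counting is a
vectorised numpy pass: reads are concatenated with `N` separators, all
windows 2-bit encoded in O(k) array operations, canonicalised numerically
and tallied with `np.unique`; windows containing `N` are skipped (with a
logged count). The graph is an in-memory hash map — nodes, edges, and a
bidirected adjacency where each node has a *forward* side (extensions
appended to the canonical string) and a *backward* side (prepended), and
each edge records its entry side at both endpoints. Palindromic (k+1)-mers
(possible since k+1 is even) produce a single hairpin incidence. No
abundance cut-off is applied at construction; filtering happens only at
traversal (the abundance-5 node filter), so the histogram fed to the
mixture fit sees the full error spike.

## Traversal

Walks are seeded from unmarked eligible nodes (abundance ≥ 5, a tunable
flag) in lexicographic order — any order would do; fixing it makes runs
byte-reproducible. A walk extends right, then left, across edges that pass
the threshold in *both* directions, stops at nodes already marked by earlier
contigs (strict partition; a junction touched by an earlier traversal can
therefore shorten a later contig) and at revisits within the current walk
(cycle guard: circular components yield one linear contig without closing
the loop). Every eligible node ends up in exactly one contig, singletons
included. Junction annotations report the worse (maximum) of the two
directional probabilities, so the per-position estimate reflects the weaker
direction; by construction every annotated probability is below ε. Contigs
shorter than 100 bp are flagged `short=yes` in the FASTA header but still
written; filtering is the caller's decision.

## Synthetic data

`make_genome` plants each requested repeat as α exact copies of one random
template at non-overlapping uniform positions in an i.i.d. uniform
background; `simulate_reads` draws uniform start positions, a random strand
per read, and i.i.d. substitution errors. This exercises exactly the
structures the model reasons about — exact repeats of multiplicity 2..5,
coverage fluctuation, error k-mers below the abundance filter — but not:
inexact (diverged) repeats, coverage bias, indels, quality scores, diploidy,
or circular chromosomes (the cycle guard is tested on a hand-built circular
fixture instead). Passing tests therefore demonstrate the probability
machinery and traversal guarantees under the model's own assumptions, not
performance on real instrument data. `validate_contigs` declares a contig
correct iff it is an exact substring of the genome or its reverse
complement — appropriate for error-free reads where the guarantee is
absolute — and measures genome fraction over all placements of correct
contigs.

Default study conditions used by the tests and the acceptance script:
100 kb genome, planted (α=2, 5 kb) and (α=3, 2 kb) repeats, error-free 40x
reads of 150 bp, k = 31, ε = 0.01, ten seeds; the noisy contiguity sweep
uses a 30 kb genome with 1% substitutions across
ε ∈ {0.0001, 0.001, 0.01, 0.1, 0.2, 0.4}. Genome sizes were chosen as the
smallest that still separate the repeat classes cleanly in the abundance
spectrum (hundreds of distinct abundance values, thousands of repeat
k-mers).

## Numerical choices and degenerate inputs

* Tails and mixtures are computed in log space throughout; probabilities
  are clamped into [0, 1] after the α-scaling.
* ε must lie strictly in (0, 1); k must be odd.
* A histogram with a single distinct abundance raises a fit error; an empty
  read set yields an empty graph and an empty contig set.
* Absent threshold entries are values (`None` / `NA` in TSV), not errors; a
  node abundance missing from the threshold table at assembly time is a
  hard error naming the abundance.
* Dispersion is parameterised as 1 + exp(θ) during optimisation, keeping
  the negative binomial proper while allowing near-Poisson fits.

## Known limitations

Single haploid genomes only; α capped at 5; substitution-only error model
in the simulator; no scaffolding, gap filling, or read-level repeat
resolution; in-memory graph suitable for genomes up to a few megabases, not
external-memory scale.
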