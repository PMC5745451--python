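# Methods

This note documents the models and procedures implemented in `boolstab`,
the parameters that matter, the numerical conventions that make runs
bit-reproducible, and the known limits of what the synthetic tests show.

## Binarization by optimal step functions

For a gene with values v₁..vₙ (n ≥ 3), sort ascending to u₁ ≤ … ≤ uₙ.
The *initial step function* is the sorted data itself (n−1 breaks,
SSE 0). For every break count d = 1..n−2, dynamic programming finds the
placement of d breaks minimizing the summed squared distance between the
data and the per-segment means — equivalently, the step function of that
complexity closest (in Euclidean distance) to the initial one. The DP is
exact; tests verify it against exhaustive enumeration for n ≤ 10.

Each optimal step function votes for its *strongest discontinuity*: a
break's score is its jump height divided by the approximation error of
the single-break two-level step function at the same position (plus
machine epsilon); ties go to the lowest break index. The binarization
threshold is the midpoint of the two sorted values flanking the lower
median of the voted break ranks; values strictly above the threshold map
to 1. The lower median keeps the voted rank an integer when the number
of depths is even, making the rule deterministic.

Both the discontinuity score and the significance test are documented
stand-ins for the original published step-function binarizer, whose full
details live in its own reference implementation; run manifests record
the active variants (`jump/error`, `uniform-bootstrap`).

**Significance.** The test statistic is the median over d of the
strongest break's jump height, divided by the data range — scale- and
shift-invariant, so the binary output and p-value are unchanged under
strictly increasing affine transforms of the data (a tested property).
The null draws n values uniformly on [min, max] of the observed data;
p = (1 + #{null ≥ observed}) / (1 + B) with B = 1000 by default. Because
the statistic is scale-free, the null distribution depends only on n, so
the matrix transformer draws one shared null sample per fit — identical
in distribution to per-gene draws and ~86× cheaper on the default panel.
Constant genes have no threshold and report p = 1. One threshold per
gene is computed over all samples pooled across groups; the young/aged
split happens after binarization. Genes with p ≥ α (default 0.05) are
dropped, with no multiple-testing correction — the retention filter is a
screening device, not an inference.

## Best-fit network inference

Within one group's binary series, the m timepoints give m−1 transition
pairs (x(t), x(t+1)); pairs never span the group boundary. For target
gene i and candidate regulator set X′ (|X′| = k), observed input
patterns are collected into multisets T (target next-value 1) and F
(next-value 0). The error of X′ is ε = Σ_s min(count_T(s), count_F(s)),
the number of observations any single Boolean function on X′ must
misclassify; it reduces to |T ∩ F| when every pattern occurs once, the
regime of series this short. The search enumerates all sets of size
0..max_k (default 5) and keeps every set of the *smallest* cardinality
achieving the global minimum ε; supersets of a zero-error set are thus
excluded, which avoids a combinatorial blow-up of spurious candidates.
Exhaustive-oracle tests confirm minimal ε against enumeration of all
functions on all input sets for small problems.

Each kept set yields a truth table: observed patterns get their majority
label (ties resolve to 0 — any fixed rule works, determinism is what
matters); unobserved patterns are don't-cares. When the number of
completions 2^q is at most the expansion cap (default 2¹⁰), all
completions become distinct equal-weight candidates; beyond the cap, a
canonical all-zero completion plus the don't-care template are kept and
the template's entries are instantiated by fair coins at
network-sampling time, preserving the uniform semantics. Truth tables
index patterns with the first input as the most significant bit — fixed
so rule files round-trip.

Rule files serialize each candidate as `target, expression` in
full-support disjunctive normal form (operators `!`, `&`, `|`,
parentheses); every minterm names all inputs, so input sets survive the
round trip except for the all-zero table, which canonicalizes to
`target, 0`. Dynamics round-trip exactly.

## Synchronous dynamics and the perturbation protocol

Networks update synchronously; each state has exactly one successor, and
trajectories enter recurrent cycles (attractors) found by a forward walk
with a visited map — the sampling-based semantics appropriate at n = 22,
where exhaustive 2²² state-graph construction is unnecessary. Walk-based
detection is tested against exhaustive enumeration for n ≤ 12. States
encode as unsigned integers with gene 0 as the most significant bit.

The stability protocol samples, per group, `n_networks` concrete
networks (default 1000) by drawing one candidate per gene uniformly.
Per network and per start-state class — uniform random states,
successors of uniform draws, and uniform members of attractor cycles
reached from uniform draws ("random attractor state" is read as a
uniform draw from the reached cycle) — `n_states` trials (default 1000)
flip one uniformly chosen bit (distinct positions when flipping more),
advance both trajectories h ∈ {1, 5} steps, and record the normalized
Hamming distance. The flip is temporary; nothing is re-flipped en route.
Per-network means are aggregated as min/max/mean over networks per
(class, horizon) cell — the boxplot semantics — and a pooled per-network
mean across the three classes is also available. Damage means match an
exhaustive expectation oracle (all states × all flip positions) within
three standard errors in tests.

Group comparison uses the two-sided Wilcoxon rank-sum test (SciPy's
Mann–Whitney U, asymptotic normal approximation with tie correction) on
the two vectors of per-network means, per cell.

**Randomness.** One master seed; every (network, class) cell derives its
own counter-based stream via `numpy.random.SeedSequence` spawn keys, so
results are independent of iteration order and individual cells are
reproducible in isolation.

## Synthetic studies

The generator emulates the structure of a two-group human muscle
time-series design: 86 genes of which 22 are binarizable, 7 young and 8
aged samples (columns in age order), per-group ground-truth networks
with in-degree 2 and unbiased random truth tables. Binarizable genes
emit values from a two-component location model on a log2-like scale
(low mean 6.0, high mean 10.0, spread 0.3 — separation far above
spread, so binarization is exact in the noise-free regime);
non-binarizable genes emit from a single overlapping component at the
midpoint (spread 0.7). All values are clipped to a small positive floor
because downstream geometric-mean aggregation requires positivity.
Optional observation noise flips each observed bit independently;
optional constant-zero planting overrides chosen aged-network rules with
the constant 0, mimicking genes that fall below threshold with age.

What the generator does *not* emulate: probe-level microarray artifacts,
age-dependent continuous drift, autocorrelated noise, and — importantly —
the richness of real trajectories. Short random-network trajectories
often settle quickly, so some planted genes are constant over all 15
samples; such genes are not bimodal, are correctly dropped by the
significance filter, and are excluded from "every planted bimodal gene
is retained" claims. Passing tests therefore demonstrate correctness of
the algorithms under controlled conditions, not that real data will
yield any particular retention or dependency count.

## Problem sizes and runtime choices

Unit and property tests run at deliberately small scales (n ≤ 12 for
exhaustive state-space oracles, n ≤ 10 for step-function enumeration).
The acceptance script runs the full pipeline at the design scale of the
study it emulates (86 genes, 22 binarizable, 7 + 8 samples) with 300
networks × 300 states per class — the package's default demonstration
scale, completing in well under a minute on one CPU; the full
1000 × 1000 protocol is a config change (`PerturbationConfig`) and runs
in a few minutes.

## Known limitations

- The step-function discontinuity score and the bootstrap significance
  test are principled stand-ins (flagged in manifests), not re-derivations
  of the original binarizer's exact scoring; threshold locations agree
  wherever a single dominant gap exists, which is the operative regime.
- Function counts per gene depend on the don't-care expansion policy and
  the smallest-cardinality preference; they are reported but should be
  read as ensemble sizes, not biological quantities.
- Inference treats the sample order as a homogeneous time series; with
  cross-sectional samples ordered by age this is a modeling assumption
  inherited from the study design, not a property the package can check.
- The rank-sum comparison inherits the usual caveat that per-network
  means within a group share the inferred function ensemble, so
  "significance" quantifies separation of the two Monte-Carlo
  distributions, not independent biological replicates.
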