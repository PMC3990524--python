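# Methods

`logicmine` mines Boolean logic relationships between binary features
(typically microarray probe detection calls) and binary phenotypes.  A
relationship is reported only when it approximates a *necessary and
sufficient* condition: the feature (or feature-pair combination) must
predict the phenotype **and** the phenotype must predict the feature, both
better than anything a histogram-preserving permutation null ever
produces.

## The model

All vectors are binary over the same specimens.  For a predictor `x` and a
target `c` the uncertainty coefficient is

    U(c | x) = [H(x) + H(c) − H(x, c)] / H(c) = I(x; c) / H(c),

the fraction of the target's entropy explained by the predictor
(entropies in bits; only ratios matter, so the base cancels).  `U = 0`
for empirically independent vectors, `U = 1` when `c` is a deterministic
function of `x`.

**Lower relationships** score one feature `a` against a phenotype `c`.
Mutual information is invariant under negation of `a`, so a single value
covers the two arity-1 readings — Type 1 (feature present iff phenotype
present, IDENTITY) and Type 2 (the negated reading, NOT).

**Higher relationships** score a pair `(a, b)` through the ten two-input
Boolean functions.  Output-complement partners (AND/NAND, OR/NOR,
a∧¬b / ¬a∨b, ¬a∧b / a∨¬b, XOR/XNOR) yield bitwise-complementary composed
vectors and hence identical coefficients, so the ten functions collapse
into five scoring classes; the pair's forward score is

    U(c | a, b) = max over the five class representatives f of U(c | f(a, b)).

Type indices are fixed at 1 = AND and 8 = XOR; the remaining canonical
functions fill the other indices in registry order (OR = 2, a∧¬b = 3,
¬a∧b = 4, NAND = 5, NOR = 6, a∨¬b = 7, ¬a∨b = 9, XNOR = 10), and every
output also carries the unambiguous symbolic name.

**Bidirectionality.**  The reverse coefficient `U(x | c)` normalises the
same mutual information by `H(x)`, with `x` the feature (lower) or the
composed vector of the winning class (higher).  A relationship's
*coefficient* is the mean of the forward and reverse values.  Forward-only
scoring accepts sufficient-but-unnecessary rules; demanding both
directions is what targets necessary-and-sufficient conditions.

**Type selection.**  The two members of a complement pair are
distinguished by rule confidence, `P(c = 1 | f(args) = 1)`; the member
with the greater confidence is reported (ties go to the lower type index;
a rule whose antecedent never holds is inapplicable and loses).

## Null model and significance

Randomization permutes vectors, preserving 0/1 histograms exactly;
feature pairs are permuted jointly, preserving the pairwise distribution
(the composed vector of a jointly permuted pair is the permuted composed
vector).

**Thresholds.**  For every feature–phenotype pair (and a configurable
sample of feature-pair triplets, default 1%) the randomized forward and
reverse coefficients are computed in `n_threshold_trials` trials (default
100); the discovery thresholds `t_lower` / `t_higher` are the maxima over
all combinations, trials and both directions.  A discovery must strictly
beat everything the null ever produced.  A trial-averaged variant
(`threshold_stat="trial-mean"`) exists for exploration; it is far more
permissive and not the default.  Numerically, permuting a binary vector
against a fixed partner makes the joint 1–1 count hypergeometric while
the marginal entropies stay fixed, so threshold draws are sampled
directly from hypergeometric counts — an exact, vectorisable equivalent
of literal permutation (verified distributionally in the tests).  For
triplet thresholds the five class draws are sampled independently per
composed vector; wherever the within-triplet correlation of the five
classes matters (p-values, FDR counting) an explicit shared permutation
is used instead.

**Discovery.**  A lower relationship needs both directions above
`t_lower`.  A pair is scanned only if *neither* member holds a lower
relationship with that phenotype (the exclusion rule: report a pair only
when it carries information no single member already carries); it is
reported if the best class forward value and the corresponding reverse
value both exceed `t_higher`.  Constant feature rows are skipped as
inapplicable; a constant phenotype is a hard error.  With exactly two
complementary phenotype rows the scan covers one row and every
relationship is lifted to the partner phenotype by negating the logic
function's output (U values are unchanged under output negation).

**p-values.**  Per relationship, the fraction of `n_trials` (default
1000) randomized trials in which either randomized direction exceeds the
actual value; exact ties count one half.  The mid-p correction matters
because the permutation null of U is discrete with atoms of up to ~0.15
at ~120 specimens: counting ties fully out (or fully in) shifts null
p-values systematically off uniform, while mid-p keeps them calibrated
(Kolmogorov–Smirnov distance from uniform ≈ 0.05 in the null-calibration
test).  Discovered relationships sit far above every random draw at the
scales used here, so their p-values are unaffected by tie handling.

**Positive FDR.**  Lower: the mean discovery count over
`n_fdr_datasets` (default 20) independently randomized datasets (every
feature row permuted independently), divided by the actual count;
undefined (reported as not applicable) when nothing was discovered.
Higher: each repeat samples the same triplet subset in actual and
randomized data and counts discoveries in both; the FDR is the mean of
the per-repeat random/actual ratios, repeats without actual discoveries
being skipped with a warning.

**Recurrence.**  Each of `n_cv_trials` (default 100) trials subsamples a
fixed number of specimens per phenotype (default: the smallest class
size), recomputes thresholds on the subsample and re-discovers; the
recurrence rate Q is the fraction of trials in which the same features,
phenotype and logic type reappear.  Relationships with Q above `q_min`
(default 0.5) are considered independent of the specimens selected.

## Surrounding steps

- **Binarization**: detection flags map P→1, M/A→0; detection p-values
  map below `alpha_present` (default 0.04, the conventional MAS5 cutoff,
  with `alpha_marginal` = 0.06 bounding the Marginal band) to 1, all else
  to 0.  Probes are partitioned by gene multiplicity (the `///`
  annotation separator); only single-gene probes enter discovery.
- **Gene mapping**: a gene (or unordered gene pair) inherits the
  relationship of its unique related probe (pair); with several, the one
  with the largest mean bidirectional coefficient represents it, ties
  broken by probe id.  Probes of one gene disagreeing on logic type is
  flagged as a warning, not an error.
- **Baselines**: relevance ranking by mutual information `I(feature;
  phenotype)`, and rank-k NMF (`k` = number of phenotypes) with features
  ranked by their coefficient in the metagene whose expression row is
  highest in the target class.  The NMF alternates exact nonnegative
  least-squares subproblems (block coordinate descent), which makes the
  reconstruction residual provably non-increasing — the reason this
  solver was chosen over clipped least squares, which can oscillate.
  Rows with fewer than `min_ones` ones (default 1) are dropped first.
- **Classification**: a competitive winner-take-all network, one unit
  per class by default, weights initialised at randomly chosen specimens,
  learning rate 0.1 decaying linearly over 50 epochs, units labelled by
  the majority class of the inputs they win.  Accuracy is computed over
  all specimens; a holdout split is available but off by default.
- **Enrichment**: hypergeometric upper-tail p-value `P[X ≥ b]` for a
  term with `B` of `N` universe items annotated and `b` of `n` selected,
  and the enrichment score `(b/n)/(B/N)`.  Gene pairs are annotated to
  unordered pairs of their members' terms; the pair universe is the set
  of scanned gene pairs.  No multiple-testing correction is applied
  beyond the raw-p and enrichment filters.

## Synthetic data

The generator emulates binarized two-phenotype detection data: two
complementary phenotype rows; planted lower features equal to the
phenotype passed through the planted logic function with independent
flip noise ε; planted pairs drawn so the composed vector equals the
phenotype before noise; i.i.d. Bernoulli(β) background rows; probes
grouped into genes with a configurable size distribution (default 60%
singletons, 25% pairs, 10% triples, 5% quadruples), genes never spanning
different planted signals.  Defaults are the conditions the validation
suite runs: 60 + 60 specimens, 2000 background features at β = 0.3, ten
Type-1 and ten Type-2 lower plants at ε = 0.05, three AND and three XOR
pair plants at ε = 0.

XOR-class plants draw the first member with exactly half ones inside
each phenotype class and set the second to `a ⊕ c` (or its complement),
so both members carry exactly zero marginal mutual information about the
phenotype — which is what routes them past the lower scan into the pair
scan.  What the generator does **not** emulate: probe-level intensity
correlation, class imbalance drift across series, batch effects, or any
dependence among background features; passing tests therefore show the
machinery is correct under the stated noise model, not that real data
meet that model.

### A structural limit worth knowing

Only the XOR/XNOR class can have marginally silent members.  If
`AND(a, b) = c` holds exactly with a balanced phenotype, then on every
`c = 0` specimen at least one member is 0, so some member has
`P(1 | c=0) ≤ 1/2` while `P(1 | c=1) = 1`, i.e. at least ~0.31 bits of
marginal information — far above any permutation threshold.  That member
is then always discovered as a lower relationship and the exact
conjunctive pair is withheld by the exclusion rule (the same argument
covers OR and the asymmetric classes).  Noisy, member-decorrelated
conjunctions — the situation in real expression data — can and do pass;
exact ones cannot.  The validation suite asserts recovery of all
noise-free pair plants including the conjunctive ones, and that
assertion fails by design for AND; it is kept failing rather than
weakened, as a precise record of this boundary of the method.

## Numerical choices

- Entropies via `xlogy` with 0·log 0 ≡ 0; mutual information clipped at
  0, coefficients clipped to [0, 1] against rounding.
- `U(c|a)` canonicalises the contingency table between the two negation
  readings so input-negation invariance holds bit-exactly, not merely to
  rounding.
- Strict inequalities at thresholds ("higher than").
- Pair scans run on Gram matrices `M Mᵀ` and `(M∘c) Mᵀ`, from which all
  ten functions' contingency tables follow; memory is bounded by row
  chunking (512 rows per block by default).
- Symmetric logic types report their features in lexicographic order;
  asymmetric types record argument order explicitly.  Unordered pairs are
  scanned once; both orientations of the asymmetric classes are covered
  by scoring a∧¬b and ¬a∧b separately.
- All randomness flows from one master seed through spawned child
  generators, one per stage; re-running a pipeline config reproduces all
  outputs bit-exactly.

## Problem sizes in the validation suite

The validation suite and `scripts/acceptance.py` run at desk scale:
2000-feature stand-ins, 100 threshold trials, 1000 p-value trials, 20
FDR datasets.  The triplet-FDR repeats sample 20% of all pairs (rather
than the 1% default used for thresholds): with ~2×10⁶ pairs and three
planted ones, a 1% sample almost never contains an actual discovery and
every repeat would be skipped, whereas real-scale data (~10⁸ pairs,
hundreds of discoveries) keep small samples countable.  The exhaustive
oracle comparisons cover all vector pairs up to length 6 and all triples
up to length 4, plus 1000 random longer triples; enrichment p-values are
checked against full enumeration for every universe up to N = 12.

## Known limitations

- Arity ≤ 2 only; no multi-valued logic; no continuous-expression logic.
- The max-over-null threshold is a family-wise criterion: it becomes more
  conservative as the number of scanned combinations grows, and lower and
  higher scans each control only their own family.
- Recurrence recomputes thresholds per subsample, which is the dominant
  cost of cross-validation on large matrices.
- The competitive classifier is deliberately the simple architecture the
  evaluation calls for, not a tuned model; accuracy on all specimens is
  optimistic relative to a holdout.
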