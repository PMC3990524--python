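# logicmine

Mining Boolean logic relationships between binary features and binary
phenotypes — associations that are simultaneously **sufficient and
necessary** conditions, not merely correlations.

The motivating setting is binarized microarray detection data for disease
subtypes: each probe is either detected (1) or not (0) in each specimen,
and each specimen belongs to exactly one phenotype (e.g. the two major
subtypes of non-small cell lung cancer, adenocarcinoma AC and squamous
cell carcinoma SCC).  A gene like *NKX2-1* that is expressed iff the
specimen is AC, or a gene pair whose AND or XOR tracks a subtype, is a
candidate biomarker and a candidate therapeutic target.  `logicmine`
finds such single-feature ("lower") and feature-pair ("higher")
relationships and quantifies their significance.  It is written for
computational biologists working with presence/absence calls, but
nothing in it is specific to microarrays — any binary feature matrix
with one-hot phenotype labels works.

## The statistic

For binary vectors, with H the Shannon entropy and I the mutual
information, the uncertainty coefficient

&nbsp;&nbsp;&nbsp;&nbsp;U(c | x) = [H(x) + H(c) − H(x, c)] / H(c) = I(x; c) / H(c)

measures the fraction of the phenotype c's entropy explained by a
predictor x (0 = independent, 1 = c fully determined).  A single feature
a is scored directly; a pair (a, b) is scored through the ten two-input
Boolean functions, which collapse into five output-complement classes
{AND, OR, a∧¬b, ¬a∧b, XOR}, the pair's score being the best class value
U(c | f(a, b)).  The method's defining move is **bidirectionality**: a
relationship also needs the reverse coefficient U(x | c) = I(x; c)/H(x)
to be high — the feature state must be necessary for the phenotype, not
just sufficient.  Both directions must strictly exceed the maximum
coefficient observed anywhere in histogram-preserving permutations of
the data (100 trials by default).  Within the winning complement pair
(e.g. AND vs NAND) the reported logic type is the one with the greater
rule confidence P(c = 1 | f = 1).  Discoveries are then backed by
permutation p-values, a positive false discovery rate from fully
randomized datasets, and a recurrence rate Q under specimen subsampling;
probe-level results are lifted to gene level through an annotation
table, and mutual-information ranking, NMF metagene ranking, a
winner-take-all classifier and hypergeometric term enrichment round out
the comparison and interpretation steps.

See `docs/methods.md` for the full model, parameter defaults and
numerical choices.

## Worked example

```python
from logicmine import (NullConfig, SyntheticConfig, compute_thresholds,
                       generate, p_values, scan_higher, scan_lower)
from logicmine.discovery import relationships_to_frame

cfg = SyntheticConfig(
    n_per_phenotype=(30, 30), n_background=500,
    lower_plants={1: 2, 2: 2}, lower_noise=0.05,
    higher_plants={"XOR": 1}, higher_noise=0.0, seed=42,
)
m, p, annotation, truth = generate(cfg)

null = NullConfig(n_threshold_trials=100, n_trials=1000)
t = compute_thresholds(m, p, null, rng=0, phenotypes=["AC"])
lower = scan_lower(m, p, t, phenotypes=["AC"])
higher = scan_higher(m, p, t, lower, phenotypes=["AC"])
p_values(lower + higher, m, p, null, rng=1)

print(f"thresholds: t_lower={t.t_lower:.3f}  t_higher={t.t_higher:.3f}")
print(relationships_to_frame(lower + higher).drop(columns=["arity", "q"]).to_string(index=False))
```

prints

```
thresholds: t_lower=0.277  t_higher=0.345
             features phenotype  type_index type_name  u_forward  u_reverse  coefficient  confidence  p_value
           P000001_at        AC           1  IDENTITY   0.789158   0.789158     0.789158    0.966667      0.0
           P000002_at        AC           1  IDENTITY   0.820112   0.822752     0.821432    1.000000      0.0
           P000003_at        AC           2       NOT   0.588021   0.588493     0.588257    0.931034      0.0
           P000004_at        AC           2       NOT   0.717098   0.717673     0.717385    0.935484      0.0
P000005_at;P000006_at        AC           8       XOR   1.000000   1.000000     1.000000    1.000000      0.0
```

All five planted relationships — and none of the 500 background
features — clear the permutation thresholds.  The two Type-1 plants read
"probe detected iff AC"; the Type-2 plants are the negated reading (so,
by complementarity, "detected iff SCC"); the XOR pair predicts AC
perfectly in both directions while each member alone carries no
information (that is why it survives the pair scan at all).  Every
p-value is 0: no random trial out of 1000 reached the actual
coefficients.  The 5% flip noise on the lower plants is what pulls their
coefficients down from 1.0.

The same workflow is scriptable from the shell:

```sh
logicmine simulate --out-dir syn --seed 42
logicmine run-all syn/matrix.tsv --phenotypes syn/phenotypes.tsv \
    --annotation syn/annotation.tsv --out-dir results --seed 7
```

which writes `relationships.tsv`, `gene_relationships.tsv` and
`run_metadata.json` (thresholds, seeds, trial counts, stage timings).
Re-running with the same seed reproduces all outputs bit-exactly.

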