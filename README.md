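# lncentropy

Classify transcripts as long non-coding RNA (lncRNA) or protein-coding
transcript (PCT) from features computed directly on the nucleotide
sequence — no alignments, no external databases. The package is aimed at
people building or studying alignment-free coding-potential predictors:
it bundles the feature extractors, a reproducible preprocessing pipeline,
three tuned classifiers with proper nested cross-validation, and a
seeded synthetic-transcript generator so the whole pipeline can be
exercised and tested end to end.

## The features

The integrated feature vector has 35 entries per transcript: sequence
length; four ORF features (first-ORF length and relative length,
longest-ORF length *ll* and relative length *lp*); and a 30-value
information-theory block, all in log₄ units — 4 block Shannon entropies
(word lengths L = 1..4), 3 topological entropies, 3 generalized
topological entropies, 17 gapped mutual-information values (gaps
g = 1..17) and 3 Kullback–Leibler divergences.

Topological entropy measures subword richness. For a sequence ω with
supported scale n_ω (the largest n with 4ⁿ + n − 1 ≤ |ω|),

&nbsp;&nbsp;&nbsp;&nbsp;H_top(ω, n) = log₄(p) / n,

where p counts distinct n-words in the prefix window of length
4ⁿ + n − 1, so H ∈ [0, 1]. The generalized form of order k averages the
per-length terms over the k largest supported word lengths:

&nbsp;&nbsp;&nbsp;&nbsp;H⁽ᵏ⁾(ω) = (1/k) Σᵢ log₄(p(i)) / i,  i = n_ω − k + 1 .. n_ω.

Both come in a *modified* variant that drops rare subwords below a
frequency threshold before counting, emphasizing repetition. Coding
sequences — long ORFs, periodic codon structure, repeated subwords —
score differently from background on these measures, which is the signal
the classifier exploits alongside ORF length. An 84-feature k-mer
baseline (mono-/di-/trinucleotide frequencies) is included for
comparison; the integrated set uses 49 fewer features.

## Worked example

```python
from lncentropy import (SyntheticSpec, generate_dataset, build_feature_table,
                        cross_validated_scores, feature_importance_report,
                        topological_entropy, EntropyConfig)

# a periodic sequence uses 4 of the 64 possible trinucleotides: log4(4)/3
print(topological_entropy("ACGT" * 50, 3, EntropyConfig(modified=False)))

ds = generate_dataset(SyntheticSpec(n_per_class=100, seed=7))
table = build_feature_table(ds, "integrated35")     # 200 rows x 35 features
result, clf = cross_validated_scores(table, "gbt", seed=7)
print(f"AUC  = {result.auc:.4f}")
print(f"AUPR = {result.aupr:.4f}")
print("top features:", [n for n, _ in feature_importance_report(clf)[:4]])
```

prints

```
0.3333333333333333
AUC  = 0.9784
AUPR = 0.9848
top features: ['orf_longest_rel', 'gte_3', 'orf_first_len', 'mi_9']
```

The AUC/AUPR are pooled out-of-fold values from a stratified 5-fold
cross-validation in which hyperparameters are re-selected inside each
training fold, so they estimate generalization, not training fit. The
importance ranking shows the longest-ORF relative length and a
generalized-topological-entropy feature carrying most of the class
signal on this data.

The same pipeline is available from the shell:

```
lncentropy synth      --out-dir run/synth --n-per-class 500 --seed 1
lncentropy prep       --fasta run/synth/transcripts.fasta \
                      --labels run/synth/labels.tsv --out-dir run/prep --seed 1
lncentropy features   --fasta run/prep/processed.fasta \
                      --labels run/prep/labels.tsv \
                      --feature-set integrated35 --out-csv run/feat35.csv
lncentropy train-eval --csv run/feat35.csv --algo all --seed 1 --out-dir run/eval
```

`prep` applies the standard preprocessing: drop sequences shorter than
200 nt, greedy redundancy removal (alignment-free, canonical-8-mer
identity, default threshold 0.9), and seeded down-sampling of the
majority class. Every subcommand writes a `config.json`; re-running with
the same config and inputs reproduces all outputs byte for byte.

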