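# rbfrce

Ensemble feature selection for high-dimensional small-sample data —
expression matrices with thousands of genes (features) and tens of
specimens (samples), where classical selectors are both inaccurate and
unstable. The package implements:

- **OOB permutation importance** inside a bootstrap tree ensemble (a
  simplified *random-bits forest*): for each tree *i* and feature *f*, the
  feature's values are permuted within the tree's out-of-bag samples and
  the accuracy drop E<sub>i</sub><sup>f</sup> = C<sub>i</sub> −
  C<sub>i</sub><sup>f</sup> is recorded; the importance is the standardized
  mean drop **fip = E<sup>f</sup> / S**, with E<sup>f</sup> the mean over
  trees and S² the sample variance (m−1 denominator).
- **Recursive cluster elimination (RCE)**: features are grouped into
  *feature classes* by K-means under the correlation distance
  D<sub>ij</sub> = 1 − r<sub>ij</sub>; each class is scored by its best
  member, Score(S<sub>i</sub>) = max<sub>j∈S<sub>i</sub></sub>
  fip<sup>j</sup>, and the lowest-scoring fraction of classes is deleted
  per round. Once few classes remain, deletion moves to individual
  features, down to a target subset size.
- **Selection-stability metrics**: Fagin's intersection metric on top-k
  rankings, IM(f<sub>i</sub>, f<sub>j</sub>) = (1/k) Σ<sub>t=1..k</sub>
  δ<sub>t</sub> with δ<sub>t</sub> the normalized symmetric difference of
  the top-t prefix sets, its similarity sim<sub>IM</sub> = 1 − IM, and the
  combinatorial priors (1/C(m,k), 1 − C(m−k,k)/C(m,k)) that explain why
  stability grows with k.
- A **repeated 2/3–1/3 holdout harness** that compares selection methods by
  held-out accuracy and stability-versus-k curves, and a **synthetic-data
  generator** that plants informative features inside correlated feature
  blocks so everything can be validated against known ground truth.

## Worked example

```python
from rbfrce import RCEConfig, SyntheticSpec, make_dataset, run_rbf_rce

spec = SyntheticSpec(n_samples=60, n_features=2000, n_informative=20,
                     n_blocks=50, effect_size=2.0, seed=0)
data, truth = make_dataset(spec)
records, state = run_rbf_rce(data, RCEConfig(target_features=50, seed=0))
```

Running `python examples/select_features.py` (the same computation) prints:

```
elimination rounds: 35
planted informative genes recovered in top 50: 15/20
top 10 features (rank, id, fip at final fit):
    1  g00018*  +0.845
    2  g00000*  +0.756
    3  g00002*  +0.465
    ...
```

60 samples by 2000 genes is far too small to estimate 2000 importances at
once reliably; the cluster-elimination loop still recovers 15 of the 20
planted genes in its final 50 because whole blocks of irrelevant,
correlated genes are discarded early while any class with one strong
member survives. The `fip` column is the standardized mean OOB-accuracy
drop under permutation — larger means the ensemble leans on that gene.

The other scripts in `examples/` each exercise one capability:
`importance_basics.py` (importance statistics E^f, S², fip),
`stability_analysis.py` (intersection metric and the stability-vs-k
trend), `holdout_evaluation.py` (the repeated-holdout comparison).

## Command line

```
rce-select simulate --n-samples 60 --n-features 2000 --n-informative 20 \
    --blocks 50 --effect 2.0 --seed 0 --out synth.csv --truth truth.json
rce-select select --input synth.csv --target-features 50 --seed 0 \
    --out ranking.tsv --report report.json
rce-select stability --rankings r1.tsv --rankings r2.tsv --k 50 \
    --k-grid 5,10,20,50 --out stability.json
```

Input is a delimited samples × features matrix with a label column
(`--orientation features_as_rows` for gene-major files); output is a
ranking TSV (`rank, feature_id, score`) and a JSON run report with the
full elimination log.

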