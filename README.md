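# mimgo

Matrix-assisted identification of differentially expressed GO terms in
multi-condition expression datasets.

Given a genes × conditions matrix of positive expression ratios (a
time-course or tissue microarray dataset, or any multi-condition bulk
profile) and a collection of gene sets (GO terms), `mimgo` answers two
questions at once:

1. **Which gene sets are concordantly up- or down-regulated somewhere in
   the dataset?** (differentially expressed GO terms)
2. **In which specific conditions?** — without pre-specifying a phenotype
   of interest, which is what distinguishes this approach from enrichment
   against a fixed two-class or continuous label.

## Method

For each gene set, a K × K **comparison matrix** is built over the K
conditions. For every ordered pair (i, j), i ≠ j, genes are ranked by
log₂(xᵢ/xⱼ) and a weighted Kolmogorov–Smirnov running-sum enrichment
score is computed for the set, with significance from a gene-set
permutation null (NES and FDR q-values per the standard signed-side GSEA
convention). Cell (i, j) is marked 1 when the positive-direction q falls
below a threshold (default 0.05).

Each row and column of the matrix is then tested for enrichment of marks
with the upper-tail hypergeometric probability

    p = Σ_{j=x}^{min(n,M)}  C(n,j) · C(N−n, M−j) / C(N,M)

with N = K(K−1) off-diagonal cells, M total marks, n = K−1 cells per
line and x marks in the line, corrected across lines by the percentage
false discovery rate

    FDR% = 100 · MC · p / PN

with MC = K lines per direction and PN the number of lines at p < 0.05.
Rows with FDR < 5% name the conditions of concerted **up**-regulation,
columns those of **down**-regulation. A guard skips matrices with fewer
than K total marks, where the line test is meaningless.

The package also ships the paper-trail around the method: a
mean-plus-standard-deviation indicator that independently checks the
identified up-regulation conditions (via the Pearson correlation of the
two bit vectors), a Pearson-metric comparator (enrichment against an
idealized expression pattern), and a synthetic time-course generator
with planted gene sets that grounds every claim in known truth.

## Worked example

```sh
cat > spec.yaml <<'EOF'
n_genes: 500
noise_sigma: 0.3
n_decoy_sets: 3
decoy_size: 10
planted_sets:
  - {size: 10, peaks: [2, 11], fold: 4.0}
  - {size: 10, peaks: [5, 14], fold: 4.0}
EOF
mimgo simulate --spec spec.yaml --seed 42 --out demo_data
mimgo run --expression demo_data/expression.tsv \
          --gmt demo_data/genesets.gmt \
          --n-perm 200 --seed 42 --out demo_run
```

prints

```
wrote 500 genes x 18 conditions, 5 gene sets -> demo_data
2 differentially expressed term(s) of 5 -> demo_run
```

and `demo_run/decisions.tsv` contains

```
term_id    differentially_expressed  min_marks_ok  up_rows      down_columns  total_marks
DECOY000   0                         0             -            -             3
DECOY001   0                         0             -            -             3
DECOY002   0                         0             -            -             0
PLANT000   1                         1             14min,77min  -             36
PLANT001   1                         1             35min,98min  -             32
```

Both planted sets are recovered with exactly their planted peak
time points (condition indices 2, 11 and 5, 14 of the 18-point 7-minute
grid) as up-regulation rows; the three decoy sets fall below the
minimum-marks guard. `demo_run/validation_summary.json` reports an
average correlation of 1.0 between the recovered up-rows and the
independent mean-plus-SD indicator over the two flagged terms.

Gene sets can equally be built from real annotations:

```python
from mimgo import read_gaf_obo, merge_and_filter, ExpressionMatrix

expr = ExpressionMatrix.read_tsv("expression.tsv")
coll = read_gaf_obo("gene_association.sgd", "gene_ontology.obo")
coll = merge_and_filter(coll, expr.universe, min_size=3)
```

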