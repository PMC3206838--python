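# irstab — where does phenotype information live in expression data?

Biomarker gene lists derived from transcriptome studies are notoriously
unstable: the top differentially expressed genes for the *same* clinical
question often barely overlap between two cohorts.  `irstab` implements a
diagnostic for this problem.  It splits every gene's (log2) expression
vector into a component inside the leading PCA subspace of the gene–gene
correlation matrix and an orthogonal residual,

    x_i = x_p,i + x_r,i ,

tests differential expression between the two phenotype classes in both
components, and condenses the result into the **Information Ratio**

    IR = Σ_i w_i |log p_r,i| / (|log p_r,i| + |log p_p,i|) / Σ_i w_i ,

with exponential weights w_i = exp(λ|log10 p_i|) fitted to the genome-wide
p-value distribution.  IR ≈ 0 means the phenotype is carried by the main
variance axes of the data (tumor vs control behaves like this); IR ≈ 1
means the information hides in the residual space (relapse-type outcomes
behave like this).  Low-IR contrasts (≤ 0.25) yield stable, transferable
gene lists and better classifiers; high-IR contrasts do not, and more
samples barely help them.

The package is aimed at computational biologists triaging clinical
expression cohorts: compute the IR for a phenotype *before* investing in a
biomarker signature for it.

It ships with, per module:

| module      | what it does |
|-------------|--------------|
| `io_prep`   | TSV loaders, probe-set collapse, sample dedup (R² ≥ 0.99), 5σ outlier removal, gene intersection, declarative phenotype binarization |
| `subspace`  | correlation-matrix PCA via SVD, metagene profiles, least-squares projected/residual split |
| `diffexpr`  | gene-wise Welch / Wilcoxon tests in original, projected and residual space |
| `infratio`  | λ weight fit, the IR, the subspace-dimension scan, low/high typing |
| `stability` | top-5% gene lists and percentage of overlapping genes (POG) between studies |
| `predict`   | nested 10×10 cross-validated RBF-SVM accuracy, cross-study transfer loss |
| `simdata`   | latent-factor study generator with controlled signal placement (the test bed) |
| `cli`       | `irstab` command wiring it all together over TSV/JSON files |

## A worked example

```python
from irstab import SimConfig, simulate_study, ir_for_contrast

study, contrast, truth = simulate_study(SimConfig(signal_mode="subspace", seed=1))
result = ir_for_contrast(study, contrast, n=4)
print(result.ir, result.type_label)

study, contrast, _ = simulate_study(SimConfig(signal_mode="residual", seed=1))
print(ir_for_contrast(study, contrast, n=4).ir)
```

prints

```
0.06419737654984306 type1_low
0.6581915568961703
```

The first study's phenotype shifts the leading latent factor, so nearly all
differential-expression significance survives projection onto the
4-dimensional subspace: IR ≈ 0.06, the biomarker-friendly regime.  The
second study carries its signal orthogonally to the factors; the
projected-space p-values are blank and the IR lands at 0.66.

The same analysis runs from the shell over TSV files:

```bash
irstab simulate --n-genes 2000 --n-samples 100 --seed 1 \
    --out-expr study.tsv --out-pheno study_pheno.tsv
irstab compute --expr study.tsv --pheno study_pheno.tsv \
    --contrast group1_vs_2 --n 4 --out ir.json
```

`examples/` contains five short scripts — one per capability (IR,
dimension scan, gene-list stability, predictor accuracy, file workflow) —
each printing the numbers it computes and a line on what they mean.

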