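# lofpipe

Classify tumors by transcription-factor loss-of-function (LoF) phenotype
from expression data, and integrate the phenotype with mutation status,
TF/chromatin binding, motif content and immunohistochemistry.

Some tumors silence a transcription factor's program without mutating the
factor itself: pancreatic ductal adenocarcinomas of non-classical subtype,
for instance, can show coordinated downregulation of HNF1A-dependent genes
— an *HNF1A LoF phenotype* — that correlates with loss-of-function
mutations in the chromatin regulator *KDM6A*. `lofpipe` is the analysis
toolkit for that kind of study: it calls the phenotype per sample, tests
its association with mutations, and links TF binding sites to the
transcriptional changes they drive.

## What it computes

For each sample *s* of a cohort matrix *x*, genes are ranked by
log2((x[g,s] + c) / (median_t x[g,t] + c)) and a LoF marker gene set is
scored by preranked GSEA (weighted running-sum ES, random-gene-set
permutation null, NES = ES / mean same-sign null |ES|, add-one permutation
p). The sample is labeled

| label | rule |
|---|---|
| LoF | NES < 0 and p < α |
| Control1 | NES < 0 and p ≥ α |
| Control2 | NES ≥ 0 |

Around the classifier: Fisher exact association of phenotype with
putative-LoF mutations; extreme-decile contrasts (⌈n/10⌉ per group);
promoter/enhancer partition (active peak within 1 kb of a TSS) and
closest-gene assignment; Fisher enrichment of TF binding among
downregulated genes over an expressed-gene background (log2 basemean >
2.5); binned coverage aggregation around peak centers; PWM scanning with
one-tailed binomial motif enrichment; and the Remmele–Stegner
immunoreactive score (IRS = intensity 0–3 × proportion score 0–4) with
chi-square grade association. A synthetic-data module generates every
input with known ground truth. See `docs/methods.md` for the full model
descriptions and numerical conventions.

## Worked example

```python
from lofpipe import simulate, classify, GeneSet

cfg = simulate.CohortSimConfig(n_samples=120, lof_fraction=0.2, set_size=100,
                               effect_log2=1.0, noise_sd=0.5, seed=11)
matrix, truth, mutations = simulate.gen_cohort(cfg)

lof_set = GeneSet("lof_orthologs", tuple(sorted(truth.set_gene_ids)))
classes = classify.classify_cohort(matrix, lof_set, n_perm=1000, seed=11)
print(classes["label"].value_counts().to_dict())

table, oratio, p = classify.mutation_association(classes, mutations)
print("2x2 table:", table.tolist())
print("odds ratio: %.2f  Fisher p: %.4g" % (oratio, p))
```

Output:

```
{'Control2': 96, 'LoF': 24}
2x2 table: [[5, 19], [1, 95]]
odds ratio: 25.00  Fisher p: 0.001154
```

The simulated cohort plants a 1-log2 downshift of a 100-gene set in 20% of
120 samples; the classifier recovers all 24 planted LoF samples (here with
no false calls, so no Control1 tumors remain). Of the LoF-class tumors 5
carry a putative loss-of-function mutation versus 1 of the 96 others,
giving the 2×2 table, its odds ratio, and a two-sided Fisher exact p.

The same workflows are available from the shell:

```sh
lofpipe simulate cohort --seed 11 --out cohort/
lofpipe classify --matrix cohort/matrix.tsv --gmt cohort/lof_set.gmt \
        --nperm 1000 --seed 11 --mutations cohort/mutations.tsv --out out/
```

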