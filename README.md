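# wregdiv

Classification of cis- vs trans-regulatory divergence and inheritance mode of
W-linked (maternally inherited, allele-less) genes from reciprocal-cross
RNA-seq expression data.

In birds, females are the heterogametic sex (ZW) and genes in the
non-recombining region of the W chromosome have no second allele, so
allele-specific expression cannot separate cis from trans regulation.
Reciprocal crosses can: since the W is always maternal, an F1 female whose
expression matches her maternal parent points to cis regulation, while a
departure from the maternal level points to trans factors. Trans genes are
further subdivided by inheritance mode — dominant (tracking the paternal
parent), additive (between the parents), over-dominant (above both) and
under-dominant (below both).

The package implements the full pipeline on gene-level TPM matrices:

| module | role |
| --- | --- |
| `wregdiv.expression_io` | TSV I/O for expression matrices, sample sheets and gene annotations; low-expression filter; chromosome subsetting |
| `wregdiv.diffexpr` | per-gene two-population contrast: fold change on mean TPM, exact binomial and Fisher tests on integerized pseudo-counts, q-value FDR (Storey / BH) |
| `wregdiv.regclass` | decision tree combining the parental, F1-vs-maternal and F1-vs-paternal contrasts into a regulatory category per gene and cross group |
| `wregdiv.summarize` | category tabulation, cis/trans fractions, dominance and breed-skew report, fold-change spectrum, cross-group consistency |
| `wregdiv.ordination` | PCA of expression profiles and PERMANOVA with permutation p-values |
| `wregdiv.synthetic_data` | reciprocal-cross simulator with per-gene ground truth (regulatory class, effect size, lognormal replicate noise, unbalanced design) |
| `wregdiv.cli` | `wregdiv` command with `simulate` / `classify` / `summarize` / `pca` / `report` subcommands |

A reference table of published per-tissue category counts for a Cornish (Cor)
x White Leghorn (WL) chicken reciprocal cross ships with the package
(`wregdiv/data/reference_category_counts.tsv`) and backs the worked-example
tests and the acceptance report.

## Command-line usage

Simulate a dataset with known truth, classify it, and report:

```sh
wregdiv simulate --seed 1 --genes-per-class 50 --out-dir sim/
wregdiv classify --matrix sim/matrix.tsv --samples sim/samples.tsv \
    --annotation sim/annotation.tsv --out-dir calls/
wregdiv report --calls calls/calls.tsv --out report.json
```

`classify` writes per-gene calls (`calls.tsv`), the per-tissue/per-group
category table (`summary.tsv`), derived fractions (`fractions.json`) and a
provenance record. Thresholds mirror the published procedure: fold change
> 1.25 or < 0.8 on mean TPM, and q < 0.05 for both exact tests (FDR applied
per contrast within tissue); all are configurable flags.

Summaries of the packaged reference counts:

```sh
wregdiv report --reference --out reference_report.json
```

PCA and PERMANOVA of sample profiles:

```sh
wregdiv pca --matrix sim/matrix.tsv --samples sim/samples.tsv \
    --tissue brain --seed 1 --out-dir pca/
```

## File formats

All inputs and outputs are plain TSV (UTF-8):

* expression matrix — first column `gene_id`, remaining columns sample ids,
  non-negative TPM values, no missing cells;
* sample sheet — columns `sample_id population sex tissue replicate`,
  populations in {Cor, WL, CL, LC} (CL = Cor dam x WL sire, LC = WL dam x
  Cor sire);
* gene annotation — BED (names map to gene ids) or two-column
  `gene_id<TAB>chromosome`.

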