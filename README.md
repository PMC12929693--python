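# ibspred

How well do genome-based inbreeding and relationship estimators, computed
from the SNPs you *observe* on an array, predict identity-by-state (IBS)
at the loci you *don't*? That is the quantity that matters when breeders
manage homozygosity of unknown deleterious recessives or preserve
variability at loci relevant to future breeding goals. `ibspred` answers
it by forward-in-time simulation of cattle populations: a historical
bottleneck population (Ne = 20 or 100) builds realistic linkage
disequilibrium, a recent population with overlapping generations and
random or BLUP-EBV selection is bred on top of it, the simulated SNPs are
split into an observed panel and an unobserved reference set, and every
estimator computed from the observed panel is correlated against the IBS
reference.

## The estimators

Reference (unobserved SNPs): the similarity-score GRM
`G_t = 2K`, `k_xy,j = (I11 + I12 + I21 + I22)/4`, with
`F_IBS = diag(G_t) - 1` and `f_IBS` the off-diagonals, plus expected
heterozygosity `E[Het] = mean 2p(1-p)`.

Predicted (observed SNPs, MAF >= 0.01 unless noted):

| family | inbreeding | relationship |
|---|---|---|
| VanRaden GRM `ZZ'/(2 sum p q)` (cohort p / p = 0.5) | F_GRMV1, F_GRMV2 | f_GRMV1, f_GRMV2 |
| Yang GRM `WW'/m` | F_GRMY | f_GRMY |
| excess homozygosity `(O-E)/(m-E)` | F_HOM | — |
| haploblock pseudo-SNP GRM (r² >= 0.25 blocks) | F_GHAP | f_GHAP |
| ROH (PLINK windows; 4/16 Mbp; MAF-filtered / all SNPs) | F_ROH4, F_ROH16, F_ROH4all, F_ROH16all | f_GROH |
| HBD hidden Markov model (10 classes, `e^{-R_k d}`) | F_HBD | — |
| shared IBS segments (>= 50 SNPs, >= 4/16 Mbp) | — | f_SEG4, f_SEG16 |
| pedigree tabular method (full / 4-generation) | F_APED, F_PED | f_APED, f_PED |

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from ibspred import desk_config, desk_eval_config, run_replicate

cfg = desk_config(ne=20, selection="ebv")      # scaled-down study profile
ecfg = desk_eval_config()
ecfg.measures = ("F_GRMV2", "F_GRMY", "f_GRMV2", "f_SEG4")
table = run_replicate(cfg, ecfg, seed=11)
print(table[["generation", "measure", "pearson_r", "mean_value"]]
      .round(3).to_string(index=False))
```

prints (one desk replicate, EBV selection, Ne = 20):

```
 generation measure  pearson_r  mean_value
          5   F_IBS      1.000       0.600
          5 F_GRMV2      0.941       0.210
          5  F_GRMY      0.598      -0.000
          5 f_GRMV2      0.935       0.415
          5  f_SEG4      0.921       0.164
         10   F_IBS      1.000       0.636
         10 F_GRMV2      0.952       0.267
         10  F_GRMY      0.239      -0.008
         10 f_GRMV2      0.945       0.549
         10  f_SEG4      0.941       0.242
```

Read it as: at generations 5 and 10 of the selected line, the
founder-frequency VanRaden coefficients (F_GRMV2/f_GRMV2) and the
shared-segment kinship (f_SEG4) predict IBS at held-out loci with r > 0.9,
while the Yang coefficient — whose per-SNP standardisation keys it to the
*current* cohort frequencies — degrades under selection; its cohort mean
stays pinned near zero by construction. The `F_IBS` rows carry the
reference's own population mean (rising as the line gets more inbred) and
`pearson_r = 1` by definition.

The same machinery scales up: `--scale full` (or
`ibspred.full_config()`) runs the full study conditions — 29
chromosomes, 24.71 Morgans, 60k SNPs, 1,030 historical generations, 100
recent generations, 100 replicates — as a long (overnight-class)
replication job.

## Command line

```sh
ibspred simulate  --scale desk --scenario Ne=20_random --seed 1 --out-prefix run1
ibspred measure   --vcf run1.vcf --measures F_GRMV2,F_HOM,f_GRMV2 --out-prefix run1
ibspred evaluate  --scale desk --scenario Ne=20_ebv --replicates 3 --seed 1 --out eval.tsv
ibspred summarize --table eval.tsv --out summary.tsv --plot trends.png
```

`simulate` writes phased VCF, PLINK PED/MAP, a pedigree CSV and the
observed/unobserved split TSV; `measure` computes genome-based measures
for any phased VCF cohort and writes per-measure TSVs; `evaluate` writes
the long-format correlation table; `summarize` aggregates replicate
means/SDs.

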