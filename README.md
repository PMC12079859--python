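# partmr

Pathway- and tissue-partitioned Mendelian randomization (MR) toolkit.

Complex-trait genetic instruments are heterogeneous: different variants act
through different biological mechanisms. `partmr` partitions
exposure-associated variants into named subsets — by enrichment of
Mendelian-disease ontology terms in LD intervals around each instrument
("pathway" partitions), or by Bayesian colocalization with per-tissue
cis-eQTLs ("tissue" partitions) — estimates partition-specific causal
effects in one-sample and two-sample MR (univariable and multivariable),
and tests whether between-partition effect differences exceed what random
instrument assortment produces.

## Components

| Module | What it does |
| --- | --- |
| `partmr.datatypes` | Domain types: summary-stat records, LD reference, gene annotations, cohort data |
| `partmr.io` | Delimited-text readers/writers (GWAS stats, BED4 genes + term map, long-format LD, eQTL panels) |
| `partmr.instruments` | Greedy p-ordered LD clumping (p < 5e-8, r² < 0.001 in 10 Mbp), proxy lookup (r² > 0.8), effect-allele harmonization |
| `partmr.pathway` | LD intervals (r² ≥ 0.8 within 1 Mbp), gene overlap with 1 kb flanks, interval-relocation term enrichment, category assignment |
| `partmr.coloc` | Wakefield log-ABFs and five-hypothesis colocalization posteriors; tissue assignment at PP_H4 > 0.9 over ±100 kbp windows |
| `partmr.onesample` | Weighted GRS, rank-based inverse-normal transform, two-stage IV regression (linear/logistic), two-score multivariable MR |
| `partmr.twosample` | Wald ratio, IVW, MR-Egger, weighted median/mode, Cochran's Q / I² / Q_het = Q/(Q_df − 1), Steiger directionality, PP_H4-weighted multivariable MR |
| `partmr.resampling` | Empirical null for between-partition differences: random subset draws or pooled PP_H4 permutation; two-tailed p with floor 1/R |
| `partmr.simulate` | Seeded synthetic studies with known ground truth: block-LD genotypes, pathway-structured phenotypes, planted eQTL colocalization, category-labelled genes |

## Command-line usage

All stages operate on delimited text files. A complete worked example using
only synthetic data:

```sh
# write a synthetic study (summary stats, LD, genes, terms, eQTLs, truth)
partmr simulate --out study/ --seed 1 --n-individuals 20000

# select independent genome-wide-significant instruments
partmr clump --stats study/exposure.tsv --ld study/ld.tsv \
    --out instruments.tsv

# harmonize outcome effects to the exposure effect alleles
partmr harmonize --exposure study/exposure.tsv \
    --outcome study/outcome_cont.tsv --out pairs.tsv

# pathway partition: LD intervals -> gene overlap -> term enrichment
printf 'cat1\tTERM:pathway1\ncat2\tTERM:pathway2\n' > categories.tsv
printf '1\t40000000\n' > lengths.tsv
partmr pathway-assign --instruments instruments.tsv --ld study/ld.tsv \
    --genes study/genes.bed --terms study/terms.tsv \
    --categories categories.tsv --genome-lengths lengths.tsv \
    --n-perm 1000 --seed 1 --out pathway.tsv

# tissue partition: colocalization with per-tissue eQTLs
partmr tissue-assign --instruments instruments.tsv \
    --exposure study/exposure.tsv --eqtl study/eqtl.tsv --out tissues.tsv

# summary-level MR with diagnostics
partmr twosample --pairs pairs.tsv --out mr.tsv \
    --methods ivw,egger,wmedian,wmode --steiger --n-exp 20000 --n-out 20000

# empirical null for a between-subset difference
partmr resample --pairs pairs.tsv --subset1 s1.txt --subset2 s2.txt \
    --replicates 1000 --seed 1 --out resample.tsv
```

One-sample analyses (GRS construction, two-stage IV regression, two-score
MVMR) are exposed through the Python API (`partmr.onesample`), since they
require individual-level cohort data held in memory.

## Notes

- Coordinates are 1-based closed internally; BED input is converted on read.
- All randomness is driven by explicit seeds; simulated studies are
  reproducible bit-for-bit from their parameters.
- Non-goals: GWAS-VCF parsing, binary genotype formats, SuSiE/multi-causal
  colocalization, LD-aware MR estimators, real-resource curation.
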