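# lncbind

`lncbind` identifies and annotates interactions between RNA-binding
proteins (RBPs) and long non-coding RNAs (lncRNAs) from CLIP-seq binding
clusters, and connects them to expression and disease-variant evidence.
It is aimed at regulatory-genomics analysts who have per-RBP binding-site
BED files, a GENCODE/Ensembl-style GTF, expression matrices and GWAS SNP
catalogs, and want a tested, reproducible pipeline rather than a pile of
one-off intersection scripts.

The package covers five stages, each usable on its own from Python:

1. **Genomic-context classification.** Every binding site is assigned to
   exactly one category by a fixed priority order,
   `CDS > 3'UTR > 5'UTR > lncRNA > pseudogene > sncRNA > intron > intergenic`;
   among the features a site overlaps (≥ 1 bp, strand-aware), the
   highest-priority category wins.
2. **Interaction calling.** An RBP interacts with a lncRNA gene iff at
   least one of its clusters overlaps an *exon* of the gene (intronic-only
   overlap never counts). lncRNAs overlapping protein-coding genes are
   filtered out first. Per-lncRNA RBP multiplicity and multi-RBP co-bound
   ("identical") sites are derived from the interaction map, and IUPAC
   motifs (e.g. the PUM2 motif `UGURUAUA`) can be scanned over sequences.
3. **Co-expression screening.** For each called pair and each cohort,
   Pearson's
   $r = \frac{\sum_i (x_i-\bar x)(y_i-\bar y)}{\sqrt{\sum_i (x_i-\bar x)^2 \sum_i (y_i-\bar y)^2}}$
   on log2(x+1) expression, with the two-sided p-value from
   $t = r\sqrt{(n-2)/(1-r^2)}$ on $n-2$ degrees of freedom and
   Benjamini–Hochberg q-values within each cohort.
4. **LD-expanded disease-SNP mapping.** rsIDs are resolved through
   merge/history tables, catalogs deduplicated, and each seed SNP expanded
   with proxies at $r^2 = D^2 / (p_A p_a p_B p_b) > 0.5$ (strict) in at
   least one population panel, where the haplotype frequency $f(AB)$ behind
   $D = f(AB) - p_A p_B$ is estimated from unphased diploid genotypes by
   two-locus EM under Hardy–Weinberg. SNPs are then mapped onto lncRNA
   exons, splice sites (the 2 intronic nt flanking each junction) and RBP
   binding sites.
5. **Synthetic data with planted truth.** Every input format the pipeline
   consumes can be generated with known ground truth (planted contexts,
   interactions, correlations, pairwise r², SNP placements, rsID merge
   chains), so each stage is testable without external downloads.

## Worked example

```python
from lncbind import (ScenarioConfig, generate_scenario, filter_lncrnas,
                     call_interactions, coexpression_screen)

scen = generate_scenario(ScenarioConfig(seed=1))      # all inputs + truth
ann = filter_lncrnas(scen.annotation)                 # drop coding-overlap lncRNAs
inter = call_interactions(scen.sites_by_rbp, ann)
print(len(inter))                                     # -> 14
```

The scenario plants 14 (RBP, lncRNA) pairs and the caller recovers exactly
those 14 — no false positives. Screening the planted expression pairs
(`examples/03_coexpression_screen.py`) prints, for seed 1:

```
rbp    lncrna    cohort      n       r         p         q sig
RBP1   LNC0001   cohortA   200   0.789  8.71e-44  2.61e-43 True
RBP3   LNC0005   cohortA   200  -0.502  3.42e-14  5.14e-14 True
RBP2   LNC0002   cohortB   200   0.383  2.16e-08  6.47e-08 True
```

i.e. the pairs planted at ρ = 0.8, −0.6 and 0.5 are recovered with r
estimates within sampling error and flagged significant in their planted
cohort only. `examples/04_ld_expansion_and_snps.py` shows the GWAS side:
the seed catalog of 14 unique SNPs expands to 16 with exactly the two
planted high-LD proxies (targets r² = 0.8 and 0.9) included and the
low-LD ones (0.2, 0.3) excluded, and the mapping summary

```
{'n_snps': 16, 'n_exonic': 5, 'n_splice_site': 2, 'n_in_binding_site': 2, ...}
```

matches the planted placement classes. Each script in `examples/` is a
short narrative of one capability; all run in seconds.

A thin CLI wraps the same stage functions:

```bash
lncbind simulate --out run --seed 1
lncbind all --out run --seed 1
```

writing per-stage TSVs and JSON manifests (config hash, input/output
checksums, filter funnel counts) under `run/`.

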