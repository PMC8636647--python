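# rnapir

Analysis of RNA-mediated promoter interactions in human embryonic stem
cells: do promoter-interacting regions (PIRs) that co-localise with
RNA–chromatin contacts carry more architectural-protein binding sites, and
what does that mean for the expression of the genes they contact?

The package is written for regulatory-genomics analysts who have three
kinds of evidence on the same cells — a promoter-capture Hi-C interaction
table (bait promoter ↔ PIR fragment), RNA–DNA contact pairs (MARGI-style),
and replicate transcription-factor binding-site tracks (e.g. ENCODE CTCF
and YY1 peak sets) — plus expression (TPM) tables and qPCR / 3C-qPCR Ct
tables for follow-up at a single locus.

## What it computes

1. **Classification.** Unique intrachromosomal PIR fragments are
   classified as RNA-PIRs or nonRNA-PIRs by ≥ 1 bp overlap with
   RNA-interacting DNA regions (contacts on unlocalized/unplaced scaffolds
   are filtered out first).
2. **Consensus TFBS enrichment.** Replicate binding-site tracks are
   reduced to per-base consensus intervals (bases covered by *every*
   track). Enrichment of consensus sites in RNA-PIRs is estimated by
   binary logistic regression

   logit P(TFBS) = β₀ + β₁·RNA + β₂·log₁₀(fragment length),

   where exp(β₁) is the size-adjusted odds ratio. Fragment length must be
   in the model: longer fragments are more likely to overlap *anything*,
   and RNA contacts themselves attach preferentially to long fragments,
   so the crude 2×2 odds ratio is confounded upward. Significance is
   additionally referenced against a permutation null built by shuffling
   the consensus intervals uniformly across the genome (lengths preserved)
   and re-running the identical regression; with r permuted p-values below
   the observed one out of n shuffles, the permutation p is (r+1)/(n+1),
   reported as "< 1/(n+1)" when r = 0.
3. **Expression by category.** Transcript TPM replicates are averaged per
   transcript and summed per gene; mean TPM of the genes contacted by each
   PIR category (RNA+sites, RNA-only, sites-only, neither) is compared
   with two-sided Mann–Whitney U tests (exact for small untied samples).
4. **qPCR / 3C quantification.** Livak 2^−ΔΔCt fold changes with a
   housekeeping reference (IPO8) for expression and a constitutive
   ligation junction (ERCC3) for 3C interaction frequency; Welch t-tests
   on ΔCt with Bonferroni correction.

A synthetic-data generator emits every input format with planted effect
sizes (conditional odds ratios, expression category effects, ΔCt fold
changes) so the full pipeline is verifiable end to end without any
external download. Its defaults reproduce the statistical structure of the
real datasets: log-normal HindIII-like fragment lengths, 39% RNA-PIRs,
consensus-site rates of ~20%/10% (CTCF) and ~8.5%/4% (YY1) in RNA-/nonRNA-
PIRs at planted conditional ORs of 1.78 and 1.67.

## Worked example

Simulate a dataset with known ground truth, then run the three analyses:

```sh
rnapir simulate --seed 7 --out .
rnapir enrich --config config.yaml
rnapir expression --config config.yaml
rnapir qpcr --config config.yaml
```

with `config.yaml` pointing at the simulated files (see
`tests/test_cli.py::_worked_config` for a complete example). The enrich
step prints, for seed 7 at the default 20,000 fragments with 200 shuffles:

```
ctcf: 19.8% of RNA-PIRs vs 9.8% of nonRNA-PIRs carry consensus sites; OR 1.71 (95% CI 1.57-1.87), Wald p 4.54e-34, permutation p < 5.0e-03
yy1: 8.9% of RNA-PIRs vs 4.1% of nonRNA-PIRs carry consensus sites; OR 1.76 (95% CI 1.55-1.99), Wald p 2.34e-18, permutation p < 5.0e-03
```

Both size-adjusted odds ratios land on the planted conditional effects
(1.78 and 1.67) within sampling error, while the percentage gap shows the
raw (confounded) contrast; no permuted site set beat the observed fit.
The expression step reports the planted category effect:

```
ctcf: mean TPM rna_and_tfbs 8.69 vs tfbs_only 5.19 (Mann-Whitney p 1.22e-45)
```

— genes contacting RNA-PIRs with consensus CTCF sites are about twice as
expressed as genes contacting CTCF-only PIRs (planted 2.0×). The qPCR step
recovers the planted locus perturbations, e.g. lncRNA knock-down halving
the target gene while doubling its promoter–PIR 3C signal:

```
stx18_del vs control [MSX1]: fold 0.516 (SE band 0.462-0.578), p_adj 0.101
stx18_del vs control [MSX1_PIR]: fold 2.223 (SE band 1.843-2.681), p_adj 0.231
```

Every report (JSON + TSV) embeds the config hash, seed and package
version; identical configs and seeds reproduce byte-identical outputs.

## Library use

All CLI stages are thin wrappers over importable functions:

```python
from rnapir import (
    load_pchic, load_margi, classify_pirs, annotate_tfbs,
    consensus_intervals, enrichment_from_records, permutation_enrichment,
    gene_tpm, category_expression, mann_whitney, delta_delta_ct,
)
```

Formats: BED3+ tracks, two-column chromosome-sizes files, tab-separated
interaction/contact/TPM tables (column names configurable), CSV Ct tables.
All interval arithmetic is 0-based half-open and strandless.
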