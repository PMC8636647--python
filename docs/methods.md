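# Methods

## Interval model

All coordinates are 0-based half-open (BED convention). Overlap means
sharing at least one base: abutting intervals (`[100,200)` vs `[200,300)`)
do not overlap. Features are strandless throughout — the analysis uses
positional overlap only. Overlap queries merge the subject track to
disjoint runs and binary-search each query against them, which is
equivalent to (and tested against) the all-pairs definition.

**Consensus.** Replicate binding-site tracks are combined by
intersection-of-coverage: a base belongs to the consensus iff every track
covers it; maximal runs of such bases form the consensus intervals. The
statement "all datasets agreed" admits a second reading — each dataset has
*some* overlap with a region, possibly at different bases — which is
implemented as `track_overlap_union` and selectable, but per-base
consensus is the default everywhere: it is the only reading under which
"consensus genomic intervals" are themselves well-defined intervals.
Within-track merging of overlapping intervals precedes the intersection,
since coverage semantics require disjoint inputs.

**Shuffling.** The permutation null re-places each consensus interval
uniformly at random over all genome-wide placements of its length:
chromosome drawn with probability proportional to
(chromosome length − interval length + 1), start uniform among valid
positions. Shuffled intervals may overlap one another and chromosomes may
be reassigned; no regions are excluded. This mirrors the default behaviour
of the standard genome-shuffling utilities. Sub-seed *i* of master seed
*s* is the splitmix64 finalizer of `(s << 64/2) + i`, truncated to 31
bits — documented so permutation runs are reproducible across platforms.

## Filters and classification

Interchromosomal promoter interactions are dropped. RNA–DNA contact rows
whose either end maps to an unlocalized or unplaced scaffold are removed;
the concrete rule is: chromosome name not in {chr1..chr22, chrX, chrY,
chrM} (which also excludes every name containing an underscore, i.e.
`chrUn_*` and `*_random`). Contact pairs and DNA regions are deduplicated
exactly. PIR identity is the exact coordinate triple — PIRs are HindIII
restriction fragments, so no fuzzy merging is appropriate — and a unique
PIR keeps the union of bait gene symbols over all its interactions. Gene
symbols are used verbatim; identifier mapping is out of scope.

## Enrichment regression

Outcome = consensus-TFBS presence, exposure = RNA-PIR status, covariate =
log10 fragment length (default). The direction is a modelling choice:
with a covariate present the two directions give slightly different
adjusted ORs, so the reverse (`rna-on-tfbs`) is available via config.
log10 rather than raw length is the default because fragment lengths span
roughly two orders of magnitude and the logistic index is more plausibly
linear in log-length; raw bp and no covariate are selectable.

The fit is maximum likelihood via iteratively reweighted least squares:
Newton steps on the observed information, convergence when the largest
absolute coefficient update falls below 1e-8, cap of 100 iterations.
Diverging coefficients (|β| > 30) raise an explicit separation error —
with a binary exposure and a bounded covariate, |β| of that size only
occurs under complete or quasi-complete separation. Without a covariate
the exposure coefficient equals the log of the sample 2×2 odds ratio
exactly (saturated model), which the tests exploit as an analytic oracle;
with a covariate the fit is checked against direct numerical maximisation
of the likelihood and against an independent library implementation.

Confidence intervals and p-values are Wald (exp(β ± 1.959964·se), normal
two-sided p) — the standard output of a binary logistic regression;
profile-likelihood intervals are out of scope.

**Permutation null.** The consensus is built once per factor (so the
order of the replicate tracks cannot matter), shuffled n_perm times, and
each shuffle re-annotated and re-fit with the identical model. r counts
permuted Wald p-values strictly below the observed one; the add-one
estimator p = (r+1)/(n+1) never returns 0 and makes "0 of 1000" print as
"< 1.0e-03". Permuted fits that fail (separation on degenerate shuffles,
possible at small n) are excluded with a warning and n reduced; whether
one consensus set is shuffled (implemented) or each replicate track is
shuffled before re-consensus (not) is an open reading of the procedure —
the former matches building consensus intervals first and shuffling
"these".

## Expression comparison

Gene TPM = replicate-mean per transcript, then sum of transcript TPMs
within the gene (a per-transcript mean is available; summing is the
default because TPM is additive over transcripts of a gene). Category
gene lists are non-exclusive — a gene contacting PIRs of two categories
appears in both — and deduplicated within a list. Genes without a TPM
entry are dropped with a count; zero-TPM genes are retained. The
Mann–Whitney test runs on the per-gene TPM vectors, not on the means.

**Mann–Whitney p-values.** U uses midranks. For untied samples with both
n ≤ 8 the two-sided p is exact: the null distribution of U is enumerated
by the standard recurrence and the lower tail doubled (the null is
symmetric). Otherwise a normal approximation is used with tie-corrected
variance and continuity correction, plus — on untied data — an Edgeworth
kurtosis term with the exact excess kurtosis of U,

γ₂ = −(6/5)·(n² + m² + nm + n + m) / (nm(N+1)),

subtracting φ(z)·(γ₂/24)(z³ − 3z) from the normal tail. The plain
continuity-corrected normal deviates from the exact p by up to 0.011 at
n = m = 8 (worst case over all U, by exhaustive scan); the kurtosis term
brings the worst case to ~5×10⁻⁴, so the approximation is uniformly
within 0.01 of exact at the point where the implementation switches from
enumeration. With ties the term is dropped (no closed-form kurtosis); at
the sample sizes where ties matter here (thousands of genes) it is
negligible anyway.

## qPCR / 3C quantification

Per biological sample, ΔCt = Ct(target) − Ct(reference); technical
replicates of the same sample and assay are averaged first. ΔΔCt is the
difference of group mean ΔCt (test − control), fold = 2^−ΔΔCt. The
reference is a housekeeping assay (IPO8) for expression and a
constitutive ligation junction (the ERCC3 interaction) for 3C, making
"fold" a relative interaction frequency in the latter case. SE(ΔΔCt) =
√(SE²_test + SE²_control) with per-group standard errors of the mean ΔCt;
the reported fold band 2^−(ΔΔCt ± SE) is asymmetric by construction — no
delta-method symmetrisation. Group tests are two-sided Welch t-tests on
ΔCt (the approximately normal scale), Bonferroni-corrected by the number
of comparisons in the report; primer-efficiency correction (Pfaffl),
standard curves and melt-curve QC are out of scope. A plate-wide constant
Ct offset cancels exactly, and swapping test and control inverts the fold
— both are tested invariants.

## Synthetic-data generator

The generator is the package's study-conditions definition, not a test
fixture: every analysis input is emitted from one seed through named
substreams (pirs, rna, tfbs_*, assembly, contacts, pchic, expr, qpcr), so
stages can be regenerated independently and identical configs are
byte-identical.

* **Fragment lengths**: log10(len) ~ N(3.6, 0.40) truncated to
  [2.7, 4.8] — median ≈ 4 kb, HindIII-fragment-like, minimum ≈ 500 bp so
  every fragment can host a jitter-protected binding site.
* **RNA attachment**: logit P(rna) = −7.70 + 2.0·log10(len).
* **TFBS presence**: logit P(tfbs) = b₀ + b_rna·rna + 1.0·log10(len)
  with b_rna = ln 1.78 (CTCF, b₀ = −5.77) and ln 1.67 (YY1, b₀ = −6.71).

The intercepts and slopes were calibrated once, before any estimator was
run, to reproduce the observed marginal rates (39.2% RNA-PIRs; consensus
sites in 20.6%/9.8% of RNA-/nonRNA-PIRs for CTCF and 8.5%/4.1% for YY1)
at the planted conditional ORs. Because both models load positively on
length, the crude 2×2 OR is biased upward (≈ 2.36 for CTCF against the
planted 1.78, close to the crude contrast implied by the observed
percentages) — the generator deliberately reproduces the confounding that
makes the size covariate necessary, and the tests verify that the
adjusted estimator removes it while the crude one does not.

**Placement.** Fragments tile the synthetic chromosomes round-robin with
uniform 1–5 kb gaps; chromosome lengths follow from the tiling. True
binding sites (300 bp) are placed inside TFBS-flagged fragments with a
margin of jitter+1 bp; replicate tracks are independently edge-jittered
copies (± 20 bp), so every copy stays inside the host fragment and the
all-tracks consensus recovers the planted flag exactly — mirroring
ENCODE replicate-track concordance, which is what the all-tracks-agree
rule exploits. Background sites and background RNA contacts are confined
to gaps with the same margins, so re-deriving flags from the emitted
files recovers the planted flags with no error; decoy rows
(interchromosomal interactions, chrUn contacts, exact duplicates) are
added to exercise the loaders' filters. Expression is log-normal
(ln TPM ~ N(1, 1)) with a multiplicative category effect (default 2.0×
for RNA+sites, 1.3× RNA-only) applied by each gene's strongest category;
transcripts per gene are 1+Poisson(0.7) with a Dirichlet TPM split and
2 replicates at 10% log-normal noise. Ct tables carry planted fold
changes as −log2(fold) shifts on the target Ct with N(0, 0.15) replicate
noise, three biological samples per group.

What the generator does **not** emulate: Hi-C contact-frequency decay and
CHiCAGO-style interaction calling (interaction significance is upstream
of this analysis), sequence content, read-level noise, partial overlaps
of features with fragment boundaries, and correlated ENCODE track errors.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the planted model, not robustness to
those real-data artefacts.

## Problem sizes used in the checks

Unit and property tests run at small n (12–5,000 records). The
statistical acceptance checks use the sizes at which their guarantees are
stated: Type-I-error calibration of the permutation p over 100 null
datasets × 200 shuffles of 5,000 PIRs; planted-OR recovery over 100
replicates of 20,000 PIRs; CI coverage over 200 replicates. The
acceptance script regenerates the full 53,563-fragment scale with 1000
permutations per factor, the scale at which the headline numbers are
defined.

## Known limitations

* The permutation null shuffles the single consensus set; shuffling each
  replicate track before re-consensus would give a slightly different
  null.
* Wald intervals undercover mildly in near-separated designs; no Firth
  correction is provided.
* Bait-side analysis (which RNA contacts which PIR, promoter-side
  features) is out of scope: RNA identity is carried but unused beyond
  overlap.
* Gene lists are symbol-based; duplicated symbols across loci collapse.
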