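# Methods

This note documents the models, rules and numerical choices behind
`sibcnv`, and what the synthetic cohort does and does not establish.

## Coordinates and interval matching

All intervals are stored 0-based half-open. Array-style CNV call TSVs are
parsed as 1-based inclusive (the convention of microarray CNV software) and
converted on read; BED tracks are 0-based half-open and used as-is. The
choice shifts lengths by at most one base relative to pipelines that treat
breakpoints differently; it is a convention, not a result. Chromosome
labels are normalized by stripping a `chr` prefix so mixed-source tracks
interoperate; recognized labels are 1–22, X and Y.

Reciprocal overlap (RO) — `min(overlap/len(a), overlap/len(b))` — is the
single matching criterion used everywhere a CNV is compared to another
interval set: consensus clustering, control-frequency lookup, parental
matching, genomic-disorder matching and population-frequency lookup. Using
one matcher keeps the pipeline's behaviour predictable; the disorder-region
rule can alternatively be switched to critical-region containment
(`match_rule="containment"`), since the field uses both conventions and
neither is canonical.

## Consensus calling

Published multi-algorithm CNV studies state *that* calls must be supported
by ≥ 2 algorithms but rarely state *how* calls are matched across
algorithms. We cluster same-sample, same-chromosome, same-copy-state calls
by single-linkage at RO ≥ 0.50 — the same threshold the rarity rule uses —
and emit a cluster when it contains ≥ 2 distinct algorithms, at least one
of which is a required caller (ChAS or iPattern in the four-caller
configuration; iPattern alone in the three-caller `ssc_mode()`). The
emitted interval is the union span of the supporting calls (deterministic
and conservative for downstream gene-overlap tests) and the probe count is
the maximum over supporters, i.e. the probe filter applies per cluster
rather than per call. X-chromosome calls are considered only from the
designated X callers and require agreement of both; Y calls are dropped
unconditionally.

## Rarity

A CNV is rare iff its carrier frequency in the platform-matched control
cohort is strictly below 0.1%, where carriers are distinct control
*individuals* (not CNV events) with a same-copy-state match at RO ≥ 0.50.
With the default 873-individual cohort, 0.1% is less than one person, so
the rule is operationally "absent from controls"; a single control carrier
(1/873 ≈ 0.115%) already renders a variant common.

## Classification tiers

Rule order, first match wins, applied only to rare filter-survivors:

1. match to a genomic-disorder region with a compatible copy state →
   **pathogenic**;
2. ≥ 1 bp overlap of a coding exon of a high-confidence ASD-susceptibility
   gene, or of a listed noncoding exception element (lncRNA exons or
   noncoding critical-region exons) — de novo → **pathogenic**, inherited
   → **likely pathogenic**, unknown inheritance → **likely pathogenic**
   (de novo status cannot be claimed without both parents);
3. exonic overlap of a candidate ASD / neuropsychiatric gene with
   population frequency ≤ 0.1% in the DGV-like table (absent = 0) →
   **VUS**;
4. otherwise **not relevant**. Non-rare CNVs never rank above
   not-relevant.

Severity precedence (a CNV matching both a disorder region and a gene tier
takes the highest tier) mirrors clinical reporting. The classifier takes no
phenotype argument, so classification is blind to outcome by construction.

Inheritance calls require the same-copy-state parental consensus CNV at
RO ≥ 0.50; "de novo" requires both parents genotyped with no match, any
missing parent yields "unknown", and a match in both parents is reported
explicitly as "biparental" rather than forced into one lineage.

## Outcome labels

BSRC-style labeling models the clinician-best-estimate design: the
clinician ASD flag determines ASD (ADOS CSS ≥ 4 is the supporting
threshold); otherwise a child is *atypically developing* if any
subthreshold criterion holds — CSS ≥ 3 with ADI-R or clinical support,
MSEL composite < 85, an MSEL language subscale < 85, VABS composite or
subscale < 85, or a clinician-noted atypical pattern — else *typical*. The
precedence between clinician judgement and score thresholds is genuinely
clinical; the flag-based model is an approximation, and the specific
criteria met are recorded in `criteria_met` while only the three-way label
feeds the statistics. SSC-style labeling applies the three-instrument
screen to non-ASD siblings (SRS T > 60, CBCL T > 60, VABS ABC < 85;
strict inequalities; ≥ 1 instrument must be present).

## Diagnostic statistics

Sensitivity, specificity, PPV and NPV are simple binomial proportions on
their own numerator/denominator; a zero denominator yields an *undefined*
measure, never 0. Confidence intervals are exact Clopper–Pearson bounds via
beta quantiles, the conservative standard for the small carrier counts
involved (the suite cross-checks them against `statsmodels`' beta-method
intervals and verifies ≥ 95% empirical coverage by simulation). Reported
values are rounded half-up to 2 decimals; full precision is kept
internally.

## pTDT and power under the liability threshold model

For each complete trio the transmission deviation is
`(PRS_child − midparent) / SD(midparent)`, standardized within the
analyzed subgroup's trios (the alternative — whole-cohort standardization
— only rescales; subgroup standardization keeps each test self-contained).
A two-sided one-sample t-test of mean deviation = 0 is reported; test
sidedness is a choice, and two-sided is the conservative default.

The power simulation uses the simplest liability-threshold construction
consistent with the stated parameters: standardized parental PRS are
independent N(0, 1); the child PRS is midparent + N(0, ½) (Mendelian
segregation variance); liability is `√r² · PRS_child + N(0, 1 − r²)`; a
child is affected when liability exceeds the (1 − K) standard-normal
quantile. SNP heritability h²g enters only through the residual
decomposition and is exposed as a parameter; it does not affect power
beyond requiring r² ≤ h²g. Defaults: K = 1.5%, h²g = 60%, r² = 2.45%,
α = 0.05.

Power is the fraction of simulated ascertained-affected cohorts in which
the pTDT rejects. Rejection sampling is vectorized in capped batches
(≤ 5 × 10⁶ children per batch) so memory stays bounded; 2,000 replicates
at n = 189 take a few seconds. At the default parameters the estimate is
≈ 0.97 (e.g. 0.975 ± 0.004 at 2,000 replicates), consistent with an
independent noncentral-t computation (≈ 0.972) in which the noncentrality
is `√n · E[d]/SD(d)` with the ascertained-deviation moments estimated from
a single large draw; the analytic mean deviation before standardization is
`(√r²/2) · φ(z_K)/K ≈ 0.198`. The empirical type-I error on unascertained
cohorts is within [0.04, 0.06] at 5,000 replicates. Every stochastic
function requires an explicit seed; `None` is refused.

## Synthetic cohort

The generator's defaults encode the study design: 253 families (223 with
one infant sibling, 25 with two, 5 with three → 288 siblings), phenotype
margins 103 ASD / 54 atypical / 131 typical, 13 sibling CNV carriers
(pathogenic-or-likely-pathogenic: 3 ASD, 2 atypical, 1 typical; VUS-only:
3 ASD, 3 atypical, 1 typical), 13 of 253 probands with ASD-relevant CNVs,
an 873-individual control cohort, and trio-PRS groups of 189 probands, 93
affected, 44 atypical and 112 unaffected siblings.

Margins and carrier-by-phenotype cells are satisfied **by construction**
(deterministic assignment followed by a seeded shuffle), not by rejection
sampling: reproducing the contingency table exactly must not depend on
sampling luck. Psychometric scores are drawn uniformly on the correct side
of each instrument threshold for the assigned label — the labels, not the
score distributions, are what the downstream statistics consume.

The miniature genome has 24 chromosomes of 10 Mb; the copy-number-stable
track covers the first 7 Mb of each autosome and X, and a segmental
duplication occupies 8.0–8.3 Mb of each autosome. The knowledge base
places two disorder regions (610 kb and 400 kb, emulating recurrent
16p11.2/16p13.11-style loci), five high-confidence and five candidate
genes (three 2-kb exons over 52 kb each), and two noncoding exception
elements, one of them on X so the X-caller rule is exercised end to end.
Planted carrier CNVs span their target's exons (72 kb) or the disorder
region; inherited variants are also planted in the transmitting parent.
Caller support per true variant is 2–4 algorithms including a required
one, with uniform breakpoint jitter of ± 500 bp — bounded so that mutual
RO stays ≥ (L − 2j)/(L + 2j) > 0.5, which the configuration validator
enforces. Negative controls are planted alongside: single-caller
artifacts, Nexus+Partek-only calls, sub-15-kb calls, a segdup-embedded
call, a Y-chromosome call, and common variants shared with the control
cohort at 1–5% frequency.

What the synthetic cohort does **not** emulate: array intensity noise,
realistic CNV length/frequency spectra, LD structure or genotype-level
PRS construction, and any correlation between CNV carriage and the
polygenic background. Passing the end-to-end tests therefore demonstrates
that the pipeline's logic — consensus, filtering, rarity, inheritance,
tiering, labeling and statistics — is correct and deterministic, not that
the generator's data are biologically realistic.

## Problem sizes and tolerances

The default test and acceptance runs use the full 253-family cohort (it is
small), 2,000 Monte-Carlo replicates for power (MC SE ≈ 0.004), 5,000 for
the null rejection rate and 2,000 for interval coverage. Floating-point
comparisons in tests use exact equality only where the computation is
exact (counts, labels); proportions are compared at the 2-decimal
reporting precision and stochastic quantities within 3–4 Monte-Carlo
standard errors.

## Known limitations

- The rarity rule's strict "<" at 0.1% makes results sensitive to the
  control cohort size near the boundary (1/1000 is common; 0/873 is rare).
- QC exceptions (retaining a failing parent to establish segregation) are
  supported via an explicit per-sample override list, not encoded
  judgement.
- The pTDT implementation tests one group at a time; no multiple-testing
  correction across groups is applied.
- Power at small n for the *affected sibling* group depends strongly on
  the ascertainment model; the simple construction here predicts higher
  power than some published figures for comparable designs, and no attempt
  is made to reverse-engineer alternative power methods.
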