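# Methods

## The locus as a symbolic site map

All reasoning is done over an ordered list of informative landmarks rather
than genomic coordinates: the promoter (`UTR5`), exons `E1`–`E10`, the
intron-2 splice-mutation site (`I2G_SITE`, between `E2` and `E3`), the
exon-3 8 bp-deletion site (`DEL8BP_SITE`, inside exon 3 after the splice
site), and the probed *TNXB* exons. Published junction descriptions, probe
panels and severity tables are all expressed in these terms, so coordinates
would add no testable content. The default model ships as a YAML document
(`cyp21kit/data/locus_model.yaml`) and every documented invariant is checked
at load time; a user file can override any part (e.g. add a probe) and is
validated the same way.

A haplotype is abstracted as a **marker vector**: one origin call per site —
`GENE`, `PSEUDO`, `ABSENT`, `UNKNOWN`, or `PARTIAL` (both origins within one
site, i.e. the junction falls inside it) — plus a set of *TNXB* signature
tokens observed on the same haplotype. This stands in for one phased long
read spanning the gene; no read-level alignment or variant calling is done
here, and raw sequencing data are deliberately out of scope.

## Junction calling and chimera typing

Under the single-junction model a chimeric *CYP21A1P*/*CYP21A2* gene has
exactly one 5′-pseudogene → 3′-gene transition. The caller returns the
tightest interval (last pseudogene/absent-origin site, first gene-origin
site) consistent with the calls; a gene-origin call preceding a
pseudogene-origin call raises a distinct error naming both sites rather than
producing a best-effort call, since such a haplotype falls outside the model
(the test-suite checks the caller against an exhaustive cut-point oracle on
1,000 random vectors). The catalogue then matches the interval against each
chimera's converted span `[UTR5, span_end)`:

| type | junction | carries I2G | carries 8 bp del |
|---|---|---|---|
| CH1 | between E3 and E4 | yes | yes |
| CH2 | between E5 and E6 | yes | yes |
| CH3 | inside E8 (`PARTIAL`) | yes | yes |
| CH4 | between E1 and E2 | no | no |
| CH6 | between I2G and the 8 bp-del site | yes | no |
| CH8 | between E8 and E9 | yes | yes |

Junctions inside the E1–E3 landmark run are disambiguated by I2G / 8 bp-del
carriage. CH5, CH7 and CH9 have no published junction interval; they are
catalogued as unobserved placeholders and the classifier never emits them
under the default configuration (an unmatched junction returns an
`UnclassifiedChimera` result, not an exception). Whole-gene-absent
haplotypes resolve by *TNXB* signature: none → solo deletion; the exon-35
120 bp deletion → CAH-X CH1; p.C4058W → CH2; the exon-41/43 cluster → CH3.

Allele taxonomy: structural evidence dominates; otherwise an allele whose
every token is transferable from the pseudogene is a **microconversion**,
and any other token makes it a **novel variant** (taxonomy and severity are
independent axes — p.R484Pfs*58 is a novel variant of known Null class). The
*CYP21A2*/*CYP21A1P* exon 7-8 integration arrangement is recorded as a
**duplication** allele whose copies are listed explicitly; the variant an
allele string cannot express — an accompanying intact extra copy — lives in
the cohort schema's `extra_copy` column.

## Severity grouping

Alleles are tiered by in-vitro residual enzyme activity (Table rules):
Null ⊇ {deletion, p.G111Vfs*21, E6 cluster, p.Q319X, p.R357W, p.R484Pfs*58,
p.L308Ffs*6}; A = {I2G}; B = {p.I173N}; C = {p.P31L, p.P454S, p.V282L};
anything unscored is D. Structural rules derived from the cohort evidence:

* every I2G-carrying chimera (CH1/2/3/5/6/7/8) scores **Null**, not A — an
  I2G/CH1 genotype groups A while a p.R357W/CH1 genotype groups Null, which
  is only consistent if the chimera itself is Null;
* CH4/CH9 (promoter conversion + p.P31L) score **C**;
* a duplication allele **with an intact extra copy scores C**: the intact
  copy rescues complete loss of function, and the cohort's two such carriers
  group C even when the partner allele is Null. A chimeric
  *CYP21A2*/*CYP21A1P* copy without an intact partner copy scores by its
  tokens (Null for the observed p.L308Ffs*6 + p.Q319X alleles). Both rules
  reproduce all 67 recorded groups;
* a multi-token allele takes its **most severe** token's class; an unscored
  token makes the allele D unless a known Null-class token is present
  (nothing can be more severe than Null).

The diploid group is the **milder** allele's class — in a recessive disease
one working-enough allele sets the phenotype — with D dominating every
pairing (including a hypothetical C/D pair: no expectation exists once an
allele is unscored; users should be aware this is a convention). Groups map
to expected phenotypes Null/A → SW, B → SV, C → NC, D → unknown. Symmetry
and monotonicity of the rule are property-tested over the full 5×5 grid.

## The conventional-assay model

MLPA dosage is modelled per probed landmark: six *CYP21A2* probes (exons
1/3/4/6/7 and the intron-2 splice site; the panel's eight physical probes
over these six landmarks are collapsed because multiplicity never changes a
call) and six *TNXB* probes (exon 35 ×2, exons 19/20/29/31). Each haplotype
contributes its gene-origin presence at each probed site; converted or
deleted spans contribute 0, a duplication contributes one per copy, and
point alleles lose only mutation-specific probe targets (the I2G probe).
Since nothing probes *TNXB* exons 40–44, the three CAH-X types are
indistinguishable except for the exon-35 probe — an asserted invariant.

Reported deletion strings follow the span rule — first through last missing
probed exon, extended to exon 10 when no *CYP21A2* probe remains downstream
— validated against the canonical per-structure mapping (CH1 → `Exon 1-3
Del`, CH2 → `Exon 1-4 Del`, CH3 → `Exon 1-7 Del`, CH8 and all complete
losses → `Exon 1-10 Del`). CH3 and CH8 produce *identical* dropout, so their
differing recorded reports cannot both follow from the rule; the canonical
mapping is authoritative for catalogued structures and the rule serves
uncatalogued dropout patterns (a per-probe listing style, e.g.
`Exon 1, 3, 4, 6, 7 Del`, is also available). Long-PCR masking: CH4 is
reported only as `p.P31L`, CH6 only as `I2G`, exon 7-8 integrations lose
p.V282L, and promoter conversions are never echoed.

**Comparison semantics.** Assay calls are reduced to canonical forms before
comparison; spelling synonyms (legacy residue numbering, frameshift-length
suffixes, bare vs `p.`-prefixed tokens) unify, and promoter tokens are
dropped from point-call lists. A call *phrased as a deletion* is compared on
the exon span it removes (`del (CYP21A2)` ≡ `Exon 1-10 Del`; a
deletion-phrased chimera call ≡ its span), while a call naming structure
beyond a bare span — a CAH-X type, a chimera recombination call, an exon 7-8
integration — is a distinct form, because the structural typing is exactly
the information the conventional assay loses. Under these semantics the
reference cohort shows 30 discordant allele-level results; the probe model
alone predicts 28, and the remaining two are recorded dataset facts
(injectable via `recorded_overrides`): a sporadically missed paternal
p.R357W, and a donor-sperm pregnancy whose paternal allele origin an
unphased assay cannot resolve.

## Cohort statistics

Rates use the allele denominator (2 × patients = 134 for the reference
cohort); a duplicated allele counts once even though the cohort's total
*copy* number is two higher. Frequency-table keys are structural subtypes
for deletions/duplications and joined token lists otherwise, giving 28
observed allele classes. Of the four taxonomy shares, note that the novel
share is 17/134 = 12.7% — the only value consistent with the shares summing
to 100%.

Group-D patients (11/67) are excluded from the cross-tabulation,
concordance, positive predictive rates and the rank correlation. The
Spearman statistic is computed from the definition — mid-ranks per margin,
then the product-moment correlation of the rank vectors — with ordinal
codings Null=1…C=4 and SW=1…NC=3 (any strictly increasing recoding gives
the same value, a property the tests check). On the 56 classified patients
it evaluates to 0.6786; the reference analysis printed 0.682, a ≤0.01 gap
attributable to that analysis' software rounding, documented rather than
reconciled. Degenerate inputs (fewer than two pairs, a constant margin,
empty tables or rows) raise a dedicated `UndefinedStatisticError` instead of
returning a number.

## Synthetic cohorts

The generator's defaults are the reference cohort's empirical distributions:
allele draw probabilities = the 28-class spectrum (counts/134), phenotype
given group = the cross-tabulation rows (Null: 10/12, 2/12, 0; A: 17/19,
2/19, 0; B: 3/17, 14/17, 0; C: 1/8, 2/8, 5/8), sex ratio 44:23, ages
resampled from the recorded ages. Alleles are paired independently
(Hardy–Weinberg-like): no mating or ascertainment structure is known, so
this is the simplest defensible null; exact genotype lists can be replayed
through the cohort reader instead when pairing matters. Group-D genotypes
get a uniform phenotype and a flag, mirroring their exclusion downstream.
Artifact rates default to 0. All draws flow through one
`numpy.random.default_rng(seed)` stream; a fixed seed reproduces the cohort
exactly.

What the generator does *not* emulate: read-level noise, allele frequencies
varying across populations, de-novo structures outside the catalogue,
relatedness, and genotype-phenotype modifiers (androgen-receptor CAG length,
P450 oxidoreductase polymorphism). Passing tests therefore demonstrate
internal consistency of the pipeline under the reference cohort's
conditions, not robustness to every real-world cohort.

## Problem sizes and numerical choices

The test-suite and the acceptance script run entirely at desk scale: the
67-patient fixture, 1,000 random junction vectors, 134,000 spectrum draws
for the sampling-error check, and synthetic cohorts of 5,000 patients —
sizes chosen so Monte-Carlo checks at ±3 standard errors are sharp while the
whole suite stays in seconds. Probability validations tolerate 1e-9; rank
statistics are asserted against oracles at 1e-12; percentage comparisons use
the printed precision of the values they reproduce. Ties in the frequency
table are broken by descending count then key insertion order; all
dataclasses are frozen and classification is deterministic.

## Known limitations

* Junction resolution is landmark-level; nucleotide-resolution breakpoints
  (and hence CH5/CH7/CH9 typing) are out of scope by design.
* The MLPA model predicts calls, not electropherogram peak ratios; probe
  chemistry and hybridization kinetics are not modelled.
* The CH3 vs CH8 report split and the CH4/CH6 point-call behaviour are
  recorded assay conventions, not consequences of the dropout rule.
* Severity classes come from a fixed in-vitro table; no quantitative enzyme
  activity model, and no VCF emission (pseudogene-relative coordinates make
  naive VCF output misleading).
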