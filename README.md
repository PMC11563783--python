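# cyp21kit

Genotyping analysis toolkit for **21-hydroxylase deficiency (21-OHD)**, the
commonest form of congenital adrenal hyperplasia, caused by mutations in
*CYP21A2*. The gene sits in the tandem-repeat RCCX module on 6p21.3 next to
its 98%-identical pseudogene *CYP21A1P*, so most pathogenic alleles arise
from meiotic misalignment: microconversions (I2G, p.I173N, p.Q319X, ...),
whole-gene deletions extending into *TNXB* (the CAH-X chimeras), partial
*CYP21A1P*/*CYP21A2* chimeric genes typed by their junction (CH1–CH9), and
*CYP21A2*/*CYP21A1P* duplication arrangements. This structure defeats
short-read assays; phased long reads resolve it directly.

cyp21kit is aimed at molecular geneticists and method developers who want a
tested, scriptable model of this locus. It provides:

* a **symbolic locus model** — ordered informative landmarks (promoter,
  exons 1–10, the intron-2 splice site, the exon-3 8 bp deletion, probed
  *TNXB* exons), a chimera junction catalogue, a severity table and the
  commercial CAH-MLPA probe panel;
* an **allele classifier**: single-junction calling on per-site
  gene/pseudogene origin vectors (the abstraction of one phased long read),
  chimera typing, and the four-way taxonomy
  microconversion / novel variant / deletion / duplication;
* **severity grouping** by the milder-allele rule. Alleles are tiered by
  in-vitro residual enzyme activity (Null ≈ 0%, A < 1%, B 1–2%, C 20–60%,
  D unknown); the diploid group is `max`(allele classes) in that order, with
  D dominating, and groups map to expected phenotypes
  Null/A → SW (salt wasting), B → SV (simple virilizing), C → NC (non-classic);
* an **in-silico MLPA + Long-PCR simulator** that predicts, per true allele,
  what the conventional work-up reports — including its blind spots (all
  three CAH-X types collapse to `Exon 1-10 Del`; CH4 and CH6 surface only as
  `p.P31L` / `I2G` point calls) — and counts discordances against the
  long-read truth;
* **cohort statistics**: allele frequency spectrum, genotype-group ×
  phenotype cross-tabulation, concordance, per-group positive predictive
  rates, and a tie-corrected Spearman rank correlation
  (mid-ranks, then the product-moment correlation of the rank vectors —
  implemented from the definition and cross-checked against independent
  oracles in the tests);
* a **synthetic cohort generator** reproducing the reference cohort's
  statistical structure, with configurable reporting artifacts;
* a digitized **67-patient reference cohort** (two structurally resolved
  alleles per patient, both assays' calls verbatim) shipped as a TSV fixture.

## Worked example

```python
from cyp21kit import (load_locus_model, load_reference_cohort,
                      compute_cohort_stats, cohort_discordances)

model = load_locus_model()
cohort = load_reference_cohort()
st = compute_cohort_stats(model, cohort)
print(st.crosstab.counts)
print(f"concordance {100*st.concordance:.1f}%  rho {st.rho:.4f}")
print("discordances:", cohort_discordances(model, cohort, use_recorded=True))
```

prints

```
      SW  SV  NC
Null  10   2   0
A     17   2   0
B      3  14   0
C      1   2   5
concordance 82.1%  rho 0.6786
discordances: 30
```

Reading: of the 56 patients with a classifiable genotype group (11 group-D
patients carry variants of unknown effect and are excluded), 46 show exactly
the phenotype their group predicts (82.1%); genotype severity and phenotype
severity rank-correlate at ρ ≈ 0.68; and across all 134 alleles the
conventional MLPA + Long-PCR work-up disagrees with the long-read calls for
30 allele-level results — 28 of which the probe-panel simulator predicts
from structure alone, the other two being recorded dataset facts (a missed
paternal point call; a donor-sperm pregnancy the unphased assay cannot
resolve).

The `examples/` directory holds one short narrative script per capability
(`classify_alleles.py`, `genotype_grouping.py`, `conventional_report.py`,
`cohort_statistics.py`, `synthetic_cohort.py`); each prints what it computes
and what the numbers mean. A thin CLI mirrors the library:

```bash
cyp21kit stats            # full JSON document for the packaged cohort
cyp21kit compare          # per-allele assay discordances (total: 30)
cyp21kit simulate-cohort --n 1000 --seed 7
```

## Documentation

`docs/methods.md` describes the locus model, the classification and grouping
rules, the probe-dropout and masking model, the comparison semantics, the
statistics, the synthetic generator, and the package's numerical and design
choices, including known limitations.
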