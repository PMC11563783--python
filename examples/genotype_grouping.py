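"""Severity grouping by the milder-allele rule.

Scores a few diploid genotypes: the group is set by the allele with more
residual 21-hydroxylase activity (Null < A < B < C), and any unknown-effect
variant (class D) makes the genotype unclassifiable.
"""

from cyp21kit import (
    assign_group,
    expected_phenotype,
    load_locus_model,
    parse_allele,
    severity_of_allele,
)

model = load_locus_model()

genotypes = [
    ("micro:I2G", "cahx:CH2"),        # A / Null -> A, expect salt wasting
    ("micro:p.I173N", "chimera:CH6"),  # B / Null -> B, expect simple virilizing
    ("micro:p.P31L", "del:solo"),      # C / Null -> C, expect non-classic
    ("micro:p.I173N", "novel:c.292+1G>A"),  # B / D -> D, unclassifiable
    ("micro:p.Q319X", "micro:p.R357W"),     # Null / Null -> Null
]

for a1, a2 in genotypes:
    s1 = severity_of_allele(model, parse_allele(a1))
    s2 = severity_of_allele(model, parse_allele(a2))
    g = assign_group(s1, s2)
    print(f"  {a1:24s} ({s1.value:4s}) / {a2:22s} ({s2.value:4s})"
          f" -> group {g.value:4s} expected phenotype {expected_phenotype(g).value}")

print(
    "\nIn a recessive disease one working-enough allele sets the phenotype,"
    "\nso the milder class rules; class D (unknown effect) dominates because"
    "\nno phenotype expectation exists for it."
)
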