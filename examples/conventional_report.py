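"""What MLPA + Long-PCR would report for structurally distinct true alleles.

Shows the probe-panel blind spots: all three CAH-X TNXA/TNXB chimeras print
the same ``Exon 1-10 Del``, a CH2 chimera's exon-5 loss goes unseen (no
probe), and the CH4/CH6 chimeras surface only as point calls.
"""

from cyp21kit import (
    AlleleSpec,
    load_locus_model,
    parse_allele,
    render_deletion_call,
    render_longpcr_call,
    simulate_probe_dropout,
)
from cyp21kit.alleles import Category
from cyp21kit.grouping import GenotypeRecord, Phenotype

model = load_locus_model()
WT = AlleleSpec(category=Category.MICROCONVERSION, variants=())

print("True structure            -> conventional report")
for s in ("cahx:CH1", "cahx:CH2", "cahx:CH3", "del:solo",
          "chimera:CH1", "chimera:CH2", "chimera:CH3", "chimera:CH8",
          "chimera:CH4", "chimera:CH6",
          "dup:E7E8[p.V282L,p.L308Ffs*6,p.Q319X]"):
    a = parse_allele(s)
    call = render_deletion_call(model, a)
    if call is None:
        call = ", ".join(render_longpcr_call(model, a)) or "negative"
    print(f"  {s:38s} -> {call}")

rec = GenotypeRecord(
    patient_id="demo", sex="F", age_years=0.1, phenotype=Phenotype.SW,
    allele1=parse_allele("cahx:CH1"), allele2=WT,
)
d = simulate_probe_dropout(model, rec)
print("\nDiploid probe dosage, CAH-X-CH1 over a structurally normal allele:")
print(" ", dict(d.calls))
print(
    "\nThe CYP21A2 probes at exons 1/3/4/6/7 drop to dosage 1; TNXB exon 35"
    "\ndrops too (the 120 bp deletion), but no probe covers TNXB exons 40-44,"
    "\nso CAH-X-CH2 and CH3 would look identical apart from that one probe."
)
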