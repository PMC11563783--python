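# Default symbolic model of the RCCX locus (CYP21A2 + flanking TNXB landmarks).
#
# Sites are an ordered 5'->3' list of informative landmarks, not genomic
# coordinates; chimera junction intervals are expressed over this order.
# DEL8BP_SITE marks the pseudogene-derived 8 bp deletion inside exon 3 and is
# ordered between the intron-2 splice site (I2G_SITE) and the exon-3 landmark
# so that junctions falling between I2G and the 8 bp deletion are expressible.
sites:
  - {id: UTR5, region: promoter}
  - {id: E1, region: exon}
  - {id: E2, region: exon}
  - {id: I2G_SITE, region: intron_site}
  - {id: DEL8BP_SITE, region: exon}
  - {id: E3, region: exon}
  - {id: E4, region: exon}
  - {id: E5, region: exon}
  - {id: E6, region: exon}
  - {id: E7, region: exon}
  - {id: E8, region: exon}
  - {id: E9, region: exon}
  - {id: E10, region: exon}
  - {id: TNXB_E19, region: tnxb}
  - {id: TNXB_E20, region: tnxb}
  - {id: TNXB_E29, region: tnxb}
  - {id: TNXB_E31, region: tnxb}
  - {id: TNXB_E35, region: tnxb}
  - {id: TNXB_E40, region: tnxb}
  - {id: TNXB_E41, region: tnxb}
  - {id: TNXB_E43, region: tnxb}

# Chimera catalogue.  span_end is the first gene-origin site after the
# pseudogene-converted 5' segment (the converted span is the half-open
# interval [UTR5, span_end)).  partial_end means the junction lies inside the
# last converted site rather than between two sites.  CH5/CH7/CH9 have no
# published junction interval and are kept as unobserved placeholders: the
# classifier never emits them under this default configuration.
chimeras:
  CH1:  {span_end: E4,  carries_i2g: true,  carries_8bp_del: true}
  CH2:  {span_end: E6,  carries_i2g: true,  carries_8bp_del: true}
  CH3:  {span_end: E8,  partial_end: true, carries_i2g: true,  carries_8bp_del: true}
  CH4:  {span_end: E2,  carries_i2g: false, carries_8bp_del: false}
  CH5:  {span_end: null, observed: false,   carries_i2g: true,  carries_8bp_del: null}
  CH6:  {span_end: DEL8BP_SITE, carries_i2g: true, carries_8bp_del: false}
  CH7:  {span_end: null, observed: false,   carries_i2g: true,  carries_8bp_del: null}
  CH8:  {span_end: E9,  carries_i2g: true,  carries_8bp_del: true}
  CH9:  {span_end: null, observed: false,   carries_i2g: false, carries_8bp_del: false}
  CAHX_CH1: {whole_gene_absent: true, tnxb_signature: [TNXB_E35_120bp_del]}
  CAHX_CH2: {whole_gene_absent: true, tnxb_signature: [TNXB_E40_C4058W]}
  CAHX_CH3: {whole_gene_absent: true, tnxb_signature: [TNXB_E41_R4073H, TNXB_E43_D4172N, TNXB_E43_S4175N]}
  DEL_SOLO: {whole_gene_absent: true, tnxb_signature: []}
  DUP_E7E8: {duplication: true}

# Severity classes from in-vitro residual 21-hydroxylase activity
# (Null ~0%, A <1%, B 1-2%, C 20-60%).  Tokens absent from this table are
# class D (unknown effect).
severity:
  "NULL": [DELETION, p.G111Vfs*21, E6_CLUSTER, p.Q319X, p.R357W, p.R484Pfs*58, p.L308Ffs*6]
  A: [I2G]
  B: [p.I173N]
  C: [p.P31L, p.P454S, p.V282L]

# Spelling synonyms (legacy vs current residue numbering, frameshift-length
# suffixes) resolving to one canonical token each.
synonyms:
  p.V281L: p.V282L
  p.P453S: p.P454S
  p.G110fs: p.G111Vfs*21
  p.G111Vfs: p.G111Vfs*21
  p.Leu308fs: p.L308Ffs*6
  p.L308Ffs: p.L308Ffs*6
  p.R484Pfs: p.R484Pfs*58
  p.R484P: p.R484Pfs*58
  Cluster6E: E6_CLUSTER
  E6cluster: E6_CLUSTER
  E6_cluster: E6_CLUSTER

# Variant tokens transferable from CYP21A1P by microconversion.
pseudogene_derived:
  - I2G
  - p.G111Vfs*21
  - p.L308Ffs*6
  - p.Q319X
  - p.P31L
  - p.I173N
  - p.R357W
  - E6_CLUSTER
  - p.V282L
  - UTR5

# Landmark site housing each known variant token.
variant_sites:
  UTR5: UTR5
  p.P31L: E1
  I2G: I2G_SITE
  c.292+1G>A: I2G_SITE
  p.G111Vfs*21: DEL8BP_SITE
  p.S126X: E3
  p.I173N: E4
  E6_CLUSTER: E6
  p.E247Gfs*11: E7
  p.V282L: E7
  p.V306F: E7
  p.L308Ffs*6: E7
  p.Q319X: E8
  p.R355H: E8
  p.R357W: E8
  p.G423_C424delinsVCL: E10
  p.P454S: E10
  p.R484Pfs*58: E10
  p.R484Q: E10

# Commercial CAH-MLPA probe panel, by probed landmark.  Area 2 targets
# CYP21A2 (dosage multiplicity of the eight physical probes over these six
# landmarks is ignored: multiplicity never changes a reported call).  The six
# TNXB probes interrogate exons 35 (twice), 19, 20, 29 and 31 only, so no
# probe distinguishes signatures in TNXB exons 40-44.
probe_panel:
  a2_probe_sites: [E1, E3, E4, E6, E7, I2G_SITE]
  a1p_probe_count: 4
  tnxb_probe_sites: [TNXB_E35, TNXB_E35, TNXB_E19, TNXB_E20, TNXB_E29, TNXB_E31]
  reference_area: true
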