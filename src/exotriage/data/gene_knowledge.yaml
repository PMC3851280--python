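# Default gene-knowledge table for speech-disorder exome triage.
#
# Tier semantics:
#   TIER_CAS     - causally associated with the target phenotype (or the same
#                  phenotype reported under another diagnosis)
#   TIER_OVERLAP - associated with an overlapping phenotype (e.g. dyslexia,
#                  specific language impairment, AOA2)
#   TIER_GUS     - gene of uncertain significance for the target phenotype
#
# Tiering is curated and configurable; replace this file to change rescue and
# reporting behaviour. prior_variants lists variant descriptions with prior
# phenotype association, which rescue frequency-deprioritized variants.
- gene: FOXP2
  tier: TIER_CAS
  phenotype_note: "CAS"
- gene: FOXP1
  tier: TIER_CAS
  phenotype_note: "Developmental delay, expressive language deficits, ASD"
- gene: CNTNAP2
  tier: TIER_CAS
  phenotype_note: "Intellectual delay, ASD, CAS"
- gene: ATP13A4
  tier: TIER_CAS
  phenotype_note: "ASD, CAS"
  prior_variants: ["p.Glu646Asp"]
- gene: KIAA0319
  tier: TIER_OVERLAP
  phenotype_note: "Developmental dyslexia, SLI"
  prior_variants: ["p.Ala311Thr"]
- gene: SETX
  tier: TIER_GUS
  phenotype_note: "AOA2"
  prior_variants: ["p.Lys992Arg"]
- gene: CNTNAP1
  tier: TIER_GUS
  phenotype_note: "No human phenotype"
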