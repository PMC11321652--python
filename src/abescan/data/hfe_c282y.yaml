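# Hereditary-hemochromatosis correction locus: editable adenines at
# protospacer +1/+5/+8, therapeutic target +5; +1 and +8 bystanders are
# missense. Matches abescan.simulate.make_locus_fixture("hfe_c282y").
name: hfe_c282y
target_position: 5
positions:
  - {position: 1, consequence: missense, ref_codon: ACG, edited_codon: GCG}
  - {position: 5, consequence: corrective, ref_codon: TAC, edited_codon: TGC}
  - {position: 8, consequence: missense, ref_codon: CAG, edited_codon: CGG}
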