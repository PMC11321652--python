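# Sickle-HBB style locus: target adenine +7; bystander adenines +9 and +12
# sit at codon third positions, so their A>G edits are synonymous.
name: hbb_s
target_position: 7
positions:
  - {position: 7, consequence: corrective, ref_codon: ACA, edited_codon: GCA}
  - {position: 9, consequence: synonymous, ref_codon: ACA, edited_codon: ACG}
  - {position: 12, consequence: synonymous, ref_codon: CCA, edited_codon: CCG}
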