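# Splice-donor disruption locus: therapeutic adenine at +6 (noncoding
# context, labelled corrective as the designated target); bystander adenine
# immediately 5' of the protospacer at -1.
name: pcsk9_intron1
target_position: 6
positions:
  - {position: -1, consequence: noncoding}
  - {position: 6, consequence: corrective}
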