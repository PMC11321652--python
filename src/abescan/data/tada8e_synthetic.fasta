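>TadA-8e_synthetic_standin modern deaminase parent (synthetic scaffold)
MSEVEFSHEYWMRHALTLAKRARDEREVPVGAVLVLNNRVIGEGWNRAIGLHDPTAHAEI
MALRQGGLVMQNYRLIDATLYVTFEPCVMCAGAMIHSRIGRVVFGVRNSKRGAAGSLMNV
LNYPGMNHRVEITEGILADECAALLCDFYRMPRQVFNAQKKAQSSTD
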