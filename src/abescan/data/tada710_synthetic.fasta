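>TadA-7.10_synthetic_standin ancestral comparison (synthetic scaffold)
MSEVEFSHEYWMRHALTLAKRARDEREVPVGAVLVLNNRVIGEGWNRAIGLHDPTAHAEI
MALRQGGLVMQNYRLIDATLYVTFEPCVMCAGAMIHSRIGRVVFGVRNAKTGAAGSLMDV
LHYPGMNHRVEITEGILADECAALLCYFFRMPRQVFNAQKKAQSSTD
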