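# Charged side-chain atoms used for salt-bridge detection.
# Format: <sign +|-> <residue> <atom name>
- ASP OD1
- ASP OD2
- GLU OE1
- GLU OE2
+ LYS NZ
+ ARG NE
+ ARG NH1
+ ARG NH2
+ HIS ND1
+ HIS NE2
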