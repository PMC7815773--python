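# Atomic solvation parameters (kcal/mol/A^2), Eisenberg-McLachlan style.
# Atom classes: C (apolar carbon), N (neutral nitrogen), O (neutral oxygen),
# S (sulfur), O- (carboxylate/terminal oxygen), N+ (charged nitrogen).
# Positive sigma: burial of the atom stabilises the interface.
C 0.016
N -0.006
O -0.006
S 0.021
O- -0.024
N+ -0.050
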