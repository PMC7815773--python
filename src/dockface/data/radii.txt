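# Van der Waals radii (Angstrom) for protein heavy atoms, Chothia-style.
# Specific (residue, atom) entries override element defaults; "*" matches
# any residue. Blank lines and '#' comments are ignored.
#
# element defaults
element C 1.87
element N 1.65
element O 1.40
element S 1.85
element P 1.90
default 1.80
#
# trigonal / carbonyl / aromatic carbons are slightly smaller
atom * C 1.76
atom ASN CG 1.76
atom ASP CG 1.76
atom GLN CD 1.76
atom GLU CD 1.76
atom ARG CZ 1.76
atom HIS CG 1.76
atom HIS CD2 1.76
atom HIS CE1 1.76
atom PHE CG 1.76
atom PHE CD1 1.76
atom PHE CD2 1.76
atom PHE CE1 1.76
atom PHE CE2 1.76
atom PHE CZ 1.76
atom TYR CG 1.76
atom TYR CD1 1.76
atom TYR CD2 1.76
atom TYR CE1 1.76
atom TYR CE2 1.76
atom TYR CZ 1.76
atom TRP CG 1.76
atom TRP CD1 1.76
atom TRP CD2 1.76
atom TRP CE2 1.76
atom TRP CE3 1.76
atom TRP CZ2 1.76
atom TRP CZ3 1.76
atom TRP CH2 1.76
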