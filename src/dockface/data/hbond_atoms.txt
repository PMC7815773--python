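# Hydrogen-bond donor and acceptor heavy atoms (distance-only criterion;
# donor hydrogens are absent from the filtered structures).
# Format: donor|acceptor <residue or *> <atom name>
donor * N
donor ARG NE
donor ARG NH1
donor ARG NH2
donor LYS NZ
donor HIS ND1
donor HIS NE2
donor TRP NE1
donor ASN ND2
donor GLN NE2
donor SER OG
donor THR OG1
donor TYR OH
acceptor * O
acceptor * OXT
acceptor ASP OD1
acceptor ASP OD2
acceptor GLU OE1
acceptor GLU OE2
acceptor ASN OD1
acceptor GLN OE1
acceptor SER OG
acceptor THR OG1
acceptor TYR OH
acceptor HIS ND1
acceptor HIS NE2
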