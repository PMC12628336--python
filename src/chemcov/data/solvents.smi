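# Solvent fragments stripped by get_parent before salt stripping.
O
CO
CCO
CC(C)O
CC(=O)C
CC#N
CS(=O)C
C1CCOC1
CCOCC
ClCCl
ClC(Cl)Cl
c1ccccc1C
CCCCCC
CCCCCCC
CC(=O)OCC
CC(=O)N(C)C
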