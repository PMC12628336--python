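# Counterion / salt fragments stripped by get_parent.
# One SMILES per line; '#' comments allowed. Charged and neutral forms are
# both listed because inputs arrive in either protonation state.
[Cl-]
Cl
[Br-]
Br
[I-]
I
[F-]
F
[Na+]
[K+]
[Li+]
[Ca+2]
[Mg+2]
[Zn+2]
[NH4+]
N
O=S(=O)(O)O
[O-]S(=O)(=O)[O-]
[O-]S(=O)(=O)O
O=S(O)O
O=[N+]([O-])O
[O-][N+](=O)[O-]
OP(=O)(O)O
[O-]P(=O)([O-])[O-]
OC(=O)C(=O)O
[O-]C(=O)C(=O)[O-]
CC(=O)O
CC(=O)[O-]
OC(=O)C(F)(F)F
[O-]C(=O)C(F)(F)F
OC(=O)/C=C/C(=O)O
[O-]C(=O)/C=C/C(=O)[O-]
OC(=O)/C=C\C(=O)O
OC(=O)CC(O)(CC(=O)O)C(=O)O
OC(=O)[C@H](O)[C@@H](O)C(=O)O
OC(=O)c1ccccc1
CS(=O)(=O)O
CS(=O)(=O)[O-]
Cc1ccc(cc1)S(=O)(=O)O
OS(=O)(=O)c1ccccc1
C(=O)O
[O-]C=O
OC(=O)CCC(=O)O
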