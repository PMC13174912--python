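# Small-substituent library: 1-3 heavy-atom SMILES over C, N, O, F
C
N
O
F
CC
CN
CO
CF
C=C
C=O
CCC
CCN
CCO
CCF
CNC
COC
CC=C
CC=O
NC=N
NC=O
OC=O
NN=C
ON=C
C1CC1
C1CN1
C1CO1
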