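# Curated structural-key set A: broad functional groups.
# One SMARTS per line; "#" starts a comment.
[CX4]                     # sp3 carbon
[CX3]=[CX3]               # alkene
[CX2]#[CX2]               # alkyne
c                         # aromatic carbon
a1aaaaa1                  # six-membered aromatic ring
[OX2H]                    # hydroxyl
[OX2]([#6])[#6]           # ether
[CX3]=[OX1]               # carbonyl
[CX3](=O)[OX2H1]          # carboxylic acid
[CX3](=O)[OX2][#6]        # ester
[CX3](=O)[NX3]            # amide
[NX3;H2,H1;!$(NC=O)]      # primary/secondary amine
[NX3]([#6])([#6])[#6]     # tertiary amine
[NX1]#[CX2]               # nitrile
[NX3](=O)=O               # nitro (charge-separated drawn form varies)
[SX2H]                    # thiol
[SX2]([#6])[#6]           # thioether
[#16X4](=[OX1])(=[OX1])   # sulfonyl
[F,Cl,Br,I]               # halogen
[OX2H][CX4][OX2H]         # vicinal diol fragment
[NX3][CX4][CX3](=O)       # alpha-amino carbonyl
[cX3][OX2H]               # phenol
n                         # aromatic nitrogen
o                         # aromatic oxygen
[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]  # trihalomethyl
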