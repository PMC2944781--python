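# Curated structural-key set B: ring systems, chain shapes and
# heteroatom environments complementary to set A.
[R]                       # any ring atom
[R2]                      # fused-ring atom
C1CCCCC1                  # cyclohexane
C1CCCC1                   # cyclopentane
c1ccccc1                  # benzene
c1ccncc1                  # pyridine
c1cc[nH]c1                # pyrrole
c1ccoc1                   # furan
c1ccsc1                   # thiophene
[#6]~[#6]~[#6]~[#6]~[#6]~[#6]~[#6]  # seven-atom carbon chain
[CH3]                     # methyl
[CH2]([CH3])[CH3]         # isopropyl core
[CX4]([#6])([#6])([#6])[#6]  # quaternary carbon
[OX2r]                    # ring oxygen
[NX3r]                    # ring nitrogen
[Sr]                      # ring sulfur
[NX3][CX3](=O)[#6]        # N-acyl
[OX2][CX3](=O)            # acyloxy
[NX3][NX3]                # hydrazine fragment
[#7]~[#7]~[#7]            # azide-like triple nitrogen
[OX2][OX2]                # peroxide
[#6]=[#7]                 # imine
[#6]~[#8]~[#6]~[#8]       # acetal-like O-C-O
[#7;R][#6;R]=O            # cyclic amide (lactam)
[#8;R][#6;R]=O            # cyclic ester (lactone)
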