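# Cyanobacterial glutathione S-transferase (GST) class definitions, version 1.
#
# One section per class. Motifs use degenerate bracket notation: residues in
# (...) or [...] are alternatives at one position; "B" is the Asx ambiguity
# code and is read as [ND].
#
#   architecture          class-wide degenerate motif (union over orders)
#   variant.<Order>       order-specific motif form; a class is considered
#                         present in an order iff a variant line exists
#   catalytic_type        Y (tyrosine), S (serine) or C (cysteine)
#   catalytic_positions   1-based sequence positions at which the catalytic
#                         residue is accepted (Y in beta-strand 1; S/C near
#                         the start of helix 1)
#   signature_n/_c        N-/C-terminal signature motifs; only needed where
#                         two classes share an architecture (Chi vs cyGSTX1)

[Chi]
architecture = SGAIL
catalytic_type = Y
catalytic_positions = 5 7
signature_n = GG[PA][KR]SRAS
signature_c = NPFGK[VL]P[VA]L
variant.Chroococcales = SGAIL
variant.Oscillatoriales = SGAIL
variant.Nostocales = SGAIL
variant.Stigonematales = SGAIL

[cyGSTX1]
architecture = SGAIL
catalytic_type = Y
catalytic_positions = 5 7
signature_n = ISPN[SGN]RIP
signature_c = BADIA[TC]YP
variant.Chroococcales = SGAIL
variant.Oscillatoriales = SGAIL
variant.Nostocales = SGAIL
variant.Stigonematales = SGAIL

[cyGSTX2]
architecture = S(FL)AI(LM)
catalytic_type = Y
catalytic_positions = 5 7
variant.Chroococcales = SLAIL
variant.Oscillatoriales = S(FL)AIL
variant.Nostocales = SLAI(LM)
variant.Stigonematales = SLAIL

[cyGSTX3]
architecture = SNA(IVM)(LM)
catalytic_type = Y
catalytic_positions = 5 7
variant.Chroococcales = SNA(IV)L
variant.Oscillatoriales = SNA(IM)(LM)
variant.Nostocales = SNAIL
variant.Stigonematales = SNAIL

[cyGSTX4]
architecture = ST(EDA)IA
catalytic_type = Y
catalytic_positions = 5 7
variant.Pleurocapsales = STEIA
variant.Chroococcales = ST(EDA)IA
variant.Oscillatoriales = ST(AE)IA
variant.Nostocales = ST(EA)IA
variant.Stigonematales = STEIA

[cyGSTX5]
architecture = SD(DRV)I(IL)
catalytic_type = S
catalytic_positions = 8 66
variant.Pleurocapsales = SDDI(IL)
variant.Chroococcales = SD(DRV)II
variant.Nostocales = SDDII

[cyGSTX6]
architecture = SA(DE)II
catalytic_type = C
catalytic_positions = 12 26 74
variant.Pleurocapsales = SAEII
variant.Chroococcales = SAEII
variant.Oscillatoriales = SA(DE)II

[cyGSTX7]
architecture = S(ST)AI(AC)
catalytic_type = S
catalytic_positions = 8 66
variant.Chroococcales = S(ST)AI(AC)
variant.Oscillatoriales = SSAIA

[cyGSTX8]
architecture = SAI(IV)N
catalytic_type = Y
catalytic_positions = 5 7
variant.Nostocales = SAI(IV)N

[cyGSTX9]
architecture = SL(ED)I(IM)
catalytic_type = C
catalytic_positions = 12 26 74
variant.Pleurocapsales = SL(ED)I(IM)

[cyGSTX10]
architecture = SA(IV)IN
catalytic_type = Y
catalytic_positions = 5 7
variant.Nostocales = SA(IV)IN

[cyGSTX11]
architecture = SKDIL
catalytic_type = S
catalytic_positions = 8 66
variant.Nostocales = SKDIL
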