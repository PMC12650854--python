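# Mammalian cell-cycle Boolean network (10 genes, synchronous update).
# Transcribed from the published logical model of the mammalian cell cycle
# (Faure, Naldi, Chaouiya & Thieffry, 2006, Bioinformatics 22:e124-e131).
# CycD is the extracellular growth-factor input and sustains itself, so the
# state space splits into a CycD=0 half (flowing to the quiescent fixed
# point with Rb, p27 and Cdh1 active) and a CycD=1 half (flowing to the
# 7-state oscillatory cycle through the CycE -> CycA -> CycB sequence).
CycD = CycD
Rb = (NOT CycD AND NOT CycE AND NOT CycA AND NOT CycB) OR (p27 AND NOT CycD AND NOT CycB)
E2F = (NOT Rb AND NOT CycA AND NOT CycB) OR (p27 AND NOT Rb AND NOT CycB)
CycE = E2F AND NOT Rb
CycA = (E2F AND NOT Rb AND NOT Cdc20 AND NOT (Cdh1 AND UbcH10)) OR (CycA AND NOT Rb AND NOT Cdc20 AND NOT (Cdh1 AND UbcH10))
p27 = (NOT CycD AND NOT CycE AND NOT CycA AND NOT CycB) OR (p27 AND NOT (CycE AND CycA) AND NOT CycB AND NOT CycD)
Cdc20 = CycB
Cdh1 = (NOT CycA AND NOT CycB) OR Cdc20 OR (p27 AND NOT CycB)
UbcH10 = NOT Cdh1 OR (Cdh1 AND UbcH10 AND (Cdc20 OR CycA OR CycB))
CycB = NOT Cdc20 AND NOT Cdh1
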