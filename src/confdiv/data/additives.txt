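# Crystallization additives that are neither cognate ligands nor organic
# solvents: ions, buffers and cryoprotectants. HET codes on this list never
# count as bound ligands. One code per line; '#' starts a comment.
SO4   # sulfate
PO4   # phosphate
NO3   # nitrate
BCT   # bicarbonate
CL    # chloride
BR    # bromide
IOD   # iodide
F     # fluoride
NA    # sodium
K     # potassium
LI    # lithium
CS    # caesium
MG    # magnesium
CA    # calcium
SR    # strontium
BA    # barium
ZN    # zinc
MN    # manganese
FE    # iron(III)
FE2   # iron(II)
NI    # nickel
CU    # copper(II)
CU1   # copper(I)
CO    # cobalt
CD    # cadmium
NH4   # ammonium
AZI   # azide
SCN   # thiocyanate
GOL   # glycerol (cryoprotectant by default; move to solvents.txt to reclassify)
EDO   # 1,2-ethanediol (cryoprotectant usage)
PEG   # di(hydroxyethyl)ether
PG4   # tetraethylene glycol
PGE   # triethylene glycol
P6G   # hexaethylene glycol
1PE   # pentaethylene glycol
2PE   # nonaethylene glycol
15P   # polyethylene glycol
TRS   # tris buffer
EPE   # HEPES
MES   # MES buffer
CAC   # cacodylate
IMD   # imidazole
CIT   # citric acid
FLC   # citrate
FMT   # formate
TLA   # L-tartrate
MLI   # malonate
BME   # beta-mercaptoethanol
DTT   # dithiothreitol
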