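# Organic solvents and non-aqueous crystallization media, as PDB HET codes.
# One code per line; '#' starts a comment. Edit freely: the aqueous (A) vs
# non-aqueous (O) verdict is exactly "structure contains a code on this list".
# Placement of borderline cryoprotectants (GOL, EDO, PEGs) is a policy choice:
# they live on the additive list by default and can be moved here.
EOH   # ethanol
MOH   # methanol
IPA   # isopropanol / 2-propanol
POL   # n-propanol
1BO   # 1-butanol
CCN   # acetonitrile
ACN   # acetone
ACT   # acetate / acetic acid media
DMF   # N,N-dimethylformamide
DMS   # dimethyl sulfoxide
TFE   # 2,2,2-trifluoroethanol
ETF   # trifluoroethanol (alternate code)
MPD   # 2-methyl-2,4-pentanediol
DIO   # 1,4-dioxane
DOX   # dioxane (alternate code)
EGL   # ethylene glycol (solvent usage)
HEX   # hexane
HEZ   # 1,6-hexanediol
BNZ   # benzene
TOL   # toluene
MB3   # chloroform-like halogenated medium
CLF   # chloroform
DCE   # 1,2-dichloroethane
EEE   # ethyl acetate
PYD   # pyridine
PHN   # phenol
FRM   # formamide
NMF   # N-methylformamide
URE   # urea (denaturant medium)
GAI   # guanidine
BUD   # 2,3-butanediol
PDO   # 1,3-propanediol
BU1   # 1,4-butanediol
PGO   # S-1,2-propanediol
PGR   # R-1,2-propanediol
DTD   # dithiane-diol medium
MXE   # 2-methoxyethanol
EHN   # ethane
HP6   # heptane
OCT   # n-octane
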