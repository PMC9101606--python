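criterion,element,limit_mg_per_70kg_week
BMDL01,Pb,0.245
BMDL01,As,0.3381
NOAEL,Hg,112.7
BMDL10,Cr,53.9
BMDL05,Cr,98
LOAEL,Co,490
DNEL,Cd,0.49
DNEL,Ni,5.39
DNEL,Se,2.107
DNEL,Fe,347.9
DNEL,Cu,20.09
DNEL,Zn,406.7
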