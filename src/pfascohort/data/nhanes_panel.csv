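abbreviation,full_name,lod_ng_ml
2-(N-ethyl-PFOSA) acetate,2-(N-Ethyl-perfluorooctane sulfonamido) acetic acid,0.2
PFDA,Perfluorodecanoic acid,0.2
PFOA,Perfluorooctanoic acid,0.1
PFOS,Perfluorooctane sulfonic acid,0.2
PFHxS,Perfluorohexane sulfonic acid,0.1
N-MeFOSAA,2-(N-Methyl-perfluorooctane sulfonamido) acetic acid,0.2
PFBS,Perfluorobutane sulfonic acid,0.1
PFHPA,Perfluoroheptanoic acid,0.4
PFNA,Perfluorononanoic acid,
PFOSA,Perfluorooctane sulfonamide,
PFUnDA,Perfluoroundecanoic acid,
PFDoDA,Perfluorododecanoic acid,
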