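analyte,k,n
2-(N-ethyl-PFOSA) acetate,2,101
PFDA,67,101
PFOA,101,101
PFOS,101,101
PFHxS,101,101
N-MeFOSAA,62,101
PFBS,0,101
PFHPA,8,101
PFNA,89,101
PFOSA,1,101
PFUnDA,31,101
PFDoDA,1,101
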