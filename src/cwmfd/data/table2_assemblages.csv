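assemblage_id,corner,n_Pm,n_Ps,n_Oa,n_Av,biomass_g
Pm,monoculture,10,0,0,0,0.102
Ps,monoculture,0,10,0,0,0.436
Oa,monoculture,0,0,10,0,0.647
Av,monoculture,0,0,0,10,0.676
LL1,LL,0,0,2,6,0.572
LL2,LL,0,6,2,3,0.615
LL3,LL,5,0,2,6,0.609
LL4,LL,4,2,2,5,0.569
HL1,HL,0,0,7,2,0.499
HL2,HL,2,0,7,2,0.508
HL3,HL,8,0,7,0,0.479
HL4,HL,2,4,7,0,0.562
LH1,LH,7,0,3,5,0.570
LH2,LH,5,7,3,0,0.581
LH3,LH,6,3,3,3,0.648
LH4,LH,4,7,3,0,0.525
HH1,HH,3,0,6,3,0.540
HH2,HH,5,4,6,0,0.619
HH3,HH,3,2,6,2,0.648
HH4,HH,5,0,6,2,0.543
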