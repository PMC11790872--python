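abbreviation,nc_ng_L,mpc_ng_L
Naph,1.2,1200
Acthy,0.7,700
Ace,0.7,70
Fl,0.7,70
Phe,3,300
Ant,0.7,70
Flu,3,300
Pyr,0.7,70
BaA,0.1,10
Chry,3.4,340
BbF,0.1,10
BkF,0.4,40
BaP,0.5,50
DBA,0.5,50
BghiP,0.3,30
InP,0.4,40
TOTAL,27.2,2720
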