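sample_id,site_name,TOC
1,Suez,2.31
2,Ain Sukhna,1.64
3,Zaafarana N.,1.52
4,Zaafarana S.,1.52
5,Ras Gharib,1.57
6,Ras Shokier,1.54
7,Gabal El Zeit,1.63
8,Qusier,1.63
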