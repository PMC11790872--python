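sample_id,site_name,Naph,Acthy,Ace,Fl,Phe,Ant,Flu,Pyr,BaA,Chry,BbF,BkF,BaP,DBA,BghiP,InP
1,Suez,ND,ND,1.22,ND,5.18,ND,ND,443,ND,ND,2.12,8.04,19.46,ND,ND,ND
2,Ain Sukhna,0.084,ND,ND,0.303,1.24,0.229,0.519,0.87,ND,0.22,1.79,1.72,3.79,1.28,4.28,3.34
3,Zaafarana N.,1.77,0.120,0.045,0.463,1.349,ND,0.217,1.16,0.54,ND,2.56,12.37,1.86,1.23,0.277,2.76
4,Zaafarana S.,0.855,ND,ND,0.265,1.17,ND,0.803,1.55,ND,0.532,1.41,0.635,3.06,0.684,0.626,3.49
5,Ras Gharib,0.041,ND,ND,0.337,1.00,ND,0.412,0.675,ND,ND,0.396,1.09,0.294,1.01,2.39,3.48
6,Ras Shokier,0.102,ND,ND,0.388,1.06,ND,0.205,0.599,1.84,ND,2.36,4.85,3.76,0.943,1.11,3.23
7,Gabal El Zeit,0.088,ND,ND,0.291,1.40,ND,0.297,0.739,ND,0.150,0.179,4.28,2.65,0.592,1.12,2.98
8,Qusier,1.50,ND,ND,0.373,1.39,0.505,0.190,1.42,0.173,0.346,1.13,3.86,5.14,2.77,0.272,3.46
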