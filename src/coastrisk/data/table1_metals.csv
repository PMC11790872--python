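sample_id,site_name,Cd,Cr,Cu,Fe,Mn,Ni,Pb,Zn
1,GOS-01,0.002,0.001,0.012,0.010,0.002,0.001,0.006,0.143
2,GOS-02,0.003,0.002,0.241,0.020,0.002,0.001,0.999,0.013
3,GOS-03,0.001,0.003,0.034,0.021,0.021,0.021,0.006,0.070
4,GOS-04,0.006,0.001,0.006,0.022,0.002,0.001,0.484,0.009
5,GOS-05,0.004,0.005,0.006,0.021,0.005,0.001,0.005,0.018
6,GOS-06,0.003,0.010,0.073,0.028,0.002,0.012,0.408,0.089
7,GOS-07,0.008,0.001,0.108,0.010,0.005,0.033,0.004,0.037
8,GOS-08,0.009,0.009,0.118,0.020,0.013,0.011,0.003,0.068
9,GOS-09,0.004,0.010,0.009,0.011,0.024,0.002,0.009,0.008
10,GOS-10,0.007,0.139,0.006,0.013,0.002,0.001,0.144,0.019
11,GOS-11,0.011,0.180,0.006,0.513,0.034,0.032,0.019,0.039
12,GOS-12,0.008,0.095,0.007,0.042,0.012,0.012,0.008,0.019
13,GOS-13,0.033,0.095,0.006,0.014,0.022,0.002,0.018,0.011
14,GOS-14,0.003,0.072,0.006,0.013,0.032,0.005,0.002,0.012
15,GOS-15,0.023,0.119,0.006,0.015,0.002,0.002,0.017,0.015
16,GOS-16,0.029,0.169,0.006,0.012,0.021,0.003,0.009,0.012
17,GOS-17,0.013,0.048,0.007,0.012,0.003,0.003,0.008,0.009
18,GOS-18,0.016,0.079,0.115,0.010,0.003,0.003,0.017,0.017
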