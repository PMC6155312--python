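id,actual,pred_steric_acceptor,resid_steric_acceptor,pred_donor_acceptor,resid_donor_acceptor,pred_2d,resid_2d,role
1,8.260,7.890,0.37,7.607,0.65,8.229,0.03,test
2,6.650,6.637,0.01,6.664,0.01,6.453,0.20,train
3,7.670,7.229,0.44,7.686,-0.02,7.798,-0.13,test
4,9.051,9.061,-0.01,9.041,-0.01,9.232,-0.18,train
5,9.252,9.241,0.01,9.254,0.00,9.141,0.11,train
6,9.108,9.107,0.00,9.117,0.01,9.068,0.04,train
7,8.879,8.887,-0.01,8.885,0.01,9.114,-0.23,train
8,8.759,8.757,0.00,8.773,0.01,8.567,0.19,train
9,9.678,9.668,0.00,9.673,0.00,9.385,0.29,train
10,9.222,9.225,-0.01,9.207,-0.01,8.951,0.27,train
11,9.553,9.519,0.03,9.286,0.26,9.535,0.01,test
12,9.292,9.296,-0.01,9.296,0.01,9.064,0.23,train
13,9.060,9.058,0.00,9.065,0.01,8.973,0.09,train
14,9.585,9.568,0.01,9.593,0.01,9.499,0.08,train
15,9.187,9.198,-0.01,9.101,0.09,9.023,0.17,test
16,8.921,8.917,0.00,8.913,-0.01,9.077,-0.16,train
17,9.319,9.080,0.24,9.013,0.31,9.613,-0.29,test
18,9.260,8.830,0.43,9.101,0.16,9.527,-0.27,test
19,6.790,6.790,0.00,6.790,0.00,7.173,-0.38,train
20,8.921,8.899,0.02,8.931,0.01,8.842,0.08,train
21,7.440,7.900,-0.46,7.603,-0.16,7.740,-0.30,train
22,8.000,8.019,-0.02,7.975,-0.03,7.455,0.54,train
23,8.530,8.532,0.00,8.532,0.00,8.295,0.23,train
24,8.350,8.356,-0.01,8.341,-0.01,8.666,-0.32,train
25,9.000,9.010,-0.01,8.989,-0.01,9.026,-0.03,train
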