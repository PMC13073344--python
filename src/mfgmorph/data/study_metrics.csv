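sample_id,particle_class,d10,pn10,pn50,pn90,intensity_sd_median,hs_circularity_median,convexity_median,elongation_median,solidity_median
1,total,4.67,2.91,4.25,6.81,27,0.981,0.996,0.040,0.996
1,individual,4.28,2.85,4.00,5.90,33,0.984,0.997,0.032,0.997
1,agglomerate,6.93,4.61,6.55,9.47,36,0.632,0.918,0.386,0.891
2,total,4.00,2.33,3.54,6.04,27,0.987,0.996,0.023,0.996
2,individual,3.76,2.30,3.42,5.50,27,0.988,0.997,0.021,0.997
2,agglomerate,6.55,3.71,5.88,9.75,31,0.655,0.927,0.384,0.899
3,total,4.05,2.24,3.34,6.30,27,0.983,0.995,0.037,0.995
3,individual,3.48,2.20,3.15,5.01,27,0.986,0.997,0.031,0.997
3,agglomerate,7.61,3.58,6.41,12.91,35,0.691,0.938,0.352,0.916
4,total,5.55,3.13,5.05,8.50,28,0.955,0.991,0.052,0.993
4,individual,4.96,3.00,4.71,7.13,28,0.961,0.994,0.050,0.995
4,agglomerate,8.48,5.23,7.91,12.19,31,0.664,0.937,0.385,0.897
5,total,4.49,2.46,3.72,7.17,30,0.978,0.996,0.050,0.997
5,individual,4.18,2.42,3.58,6.48,30,0.980,0.997,0.046,0.997
5,agglomerate,7.72,3.70,6.36,12.49,35,0.653,0.920,0.336,0.900
6,total,5.91,3.25,4.14,8.97,33,0.962,0.993,0.055,0.994
6,individual,5.16,3.16,4.72,7.51,33,0.967,0.995,0.046,0.996
6,agglomerate,8.92,5.69,8.20,12.76,43,0.802,0.972,0.507,0.952
7,total,4.64,2.60,4.00,7.11,32,0.983,0.996,0.040,0.996
7,individual,4.20,2.54,3.77,6.23,31,0.985,0.997,0.035,0.997
7,agglomerate,7.58,4.20,6.50,11.72,36,0.644,0.917,0.343,0.897
8,total,4.55,2.53,3.95,6.75,27,0.983,0.997,0.043,0.997
8,individual,4.28,2.51,3.85,6.25,27,0.984,0.997,0.041,0.997
8,agglomerate,8.95,4.84,7.23,15.46,32,0.623,0.899,0.320,0.900
9,total,4.73,2.48,4.25,7.42,29,0.991,0.966,0.016,0.995
9,individual,4.21,2.42,3.95,6.24,28,0.993,0.998,0.013,0.998
9,agglomerate,7.79,5.04,7.49,10.66,35,0.592,0.895,0.397,0.879
10,total,5.97,3.07,5.44,9.33,38,0.993,0.996,0.011,0.998
10,individual,5.31,2.98,5.01,7.84,37,0.994,0.998,0.008,0.998
10,agglomerate,9.75,6.42,9.40,13.04,43,0.600,0.897,0.396,0.882
11,total,5.28,3.12,4.39,8.34,35,0.977,0.995,0.031,0.996
11,individual,4.37,3.05,3.97,5.96,34,0.982,0.997,0.023,0.997
11,agglomerate,8.36,5.03,7.21,13.20,39,0.614,0.921,0.517,0.878
12,total,5.16,3.14,4.54,7.95,35,0.972,0.992,0.042,0.994
12,individual,4.10,3.02,3.90,5.34,34,0.981,0.997,0.025,0.997
12,agglomerate,7.39,5.20,6.96,9.86,37,0.558,0.903,0.429,0.851
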