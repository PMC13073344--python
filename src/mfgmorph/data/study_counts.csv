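sample_id,n_total,n_individual,pct_individual,n_agglomerate,pct_agglomerate
1,70557,60031,85.08,10526,14.92
2,107557,98324,91.42,9233,8.58
3,74498,63371,85.06,10127,13.59
4,70582,58645,83.09,11937,16.91
5,79868,72801,91.15,7067,8.85
6,73469,60702,82.62,12767,17.38
7,88238,76803,87.04,11435,12.96
8,80960,76247,94.18,4713,5.82
9,169546,145063,85.56,24483,14.44
10,122333,104204,85.18,18129,14.82
11,132820,102742,77.35,30078,22.65
12,128048,86977,67.93,41071,32.07
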