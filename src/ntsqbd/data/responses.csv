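run_id,SP1_pct,SP2_pct,SP3_pct,SP4_pct,SP5_pct,TSP_pct,DMY_mgg,TSY_mgg
1,8.65,33.33,5.23,30.19,6.60,83.99,144,121
2,9.16,39.41,5.37,30.07,3.64,87.65,76.3,66.9
3,9.45,35.33,5.19,30.40,4.75,85.12,142,121
4,8.62,33.27,3.38,32.51,7.68,85.46,90.2,77.1
5,10.00,35.67,5.32,29.96,5.56,86.51,140,121
6,8.85,35.77,4.44,30.77,7.28,87.10,153,133
7,10.59,42.97,5.20,28.91,3.34,91.01,79.4,72.3
8,7.60,29.95,4.51,29.48,6.32,77.85,166,130
9,7.11,34.97,4.81,30.12,5.70,82.70,125,103
10,8.75,38.88,4.79,30.38,4.06,86.85,94.8,82.3
11,8.20,33.85,4.99,29.43,6.50,82.96,126,104
12,9.74,43.44,5.28,29.85,3.15,91.47,80.7,73.8
13,8.29,37.19,5.38,32.94,4.74,88.53,82.1,72.6
14,8.52,32.22,4.84,29.92,6.70,82.20,143,118
15,8.23,33.54,5.30,30.39,7.11,84.57,117,99.0
16,7.38,33.32,4.88,30.87,4.82,81.26,148,121
17,8.88,33.91,4.08,30.93,7.43,85.23,82.5,70.3
18,8.54,32.32,4.40,28.94,6.79,80.99,170,137
19,8.52,31.38,4.60,29.94,6.57,81.01,138,111
20,8.15,33.32,5.49,29.14,5.28,81.38,153,125
21,9.22,35.01,4.81,30.52,7.02,86.57,162,140
22,7.23,34.68,4.92,32.14,5.18,84.16,97.1,81.7
23,8.75,33.11,4.18,29.52,7.71,83.27,166,138
24,9.70,33.40,4.43,29.54,6.57,83.64,152,127
25,9.61,32.78,4.13,31.22,8.58,86.31,137,119
26,9.08,38.66,5.61,30.37,3.90,87.61,91.0,79.8
27,8.23,33.98,5.64,30.30,6.21,84.37,137,116
28,9.35,31.69,4.06,30.55,7.26,82.92,146,121
29,8.86,33.54,5.24,30.49,6.65,84.79,153,130
30,9.57,40.20,5.20,32.82,5.23,93.02,86.8,80.7
31,8.26,30.95,4.79,29.16,5.91,79.07,168,133
32,8.85,33.01,4.45,29.75,7.47,83.53,175,146
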