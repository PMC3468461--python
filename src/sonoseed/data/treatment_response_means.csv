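treatment,gp_mean,gp_sd,pl_mean,pl_sd,rl_mean,rl_sd
1,66.92,15.44,36.77,9.24,11.39,4.21
2,75.31,11.10,37.47,9.89,13.34,5.03
3,77.62,19.60,38.53,8.93,14.98,6.74
4,81.08,14.38,38.64,9.20,14.14,6.63
5,83.08,16.44,37.56,9.48,14.13,5.89
6,88.77,12.59,41.33,9.57,18.40,7.57
7,83.00,17.58,39.55,9.42,16.28,6.71
8,83.69,15.39,38.56,9.25,13.34,6.10
9,81.00,19.50,35.60,9.02,12.35,5.02
10,84.69,13.08,39.69,8.68,15.47,5.92
11,90.12,11.44,41.05,9.32,18.32,7.59
12,79.69,15.04,38.36,9.31,14.09,7.16
13,76.07,17.05,38.02,8.55,13.38,5.83
14,77.38,11.80,37.59,9.82,13.15,7.04
15,81.85,19.09,36.84,10.02,13.72,6.29
16,77.23,24.97,34.91,8.52,11.87,4.57
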