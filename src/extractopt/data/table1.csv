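run_id,ethanol_pct,time_min,temperature_C,frequency_kHz,tpc,tpc_sd,tpc_rsm,tpc_ann,tfc,tfc_sd,tfc_rsm,tfc_ann,dpph,dpph_sd,dpph_rsm,dpph_ann,abts,abts_sd,abts_rsm,abts_ann
1,50,50,20,35,47.78,3.25,49.27,49.55,35.77,1.52,38.84,35.39,19.24,1.62,20.10,19.26,33.07,1.19,32.65,33.09
2,50,35,60,26,55.85,3.54,54.93,58.95,20.08,3.14,24.99,20.06,23.58,1.78,22.85,22.63,35.01,1.74,30.84,35.54
3,50,20,40,40,57.62,2.87,60.47,60.48,23.49,2.87,24.88,23.61,26.59,2.17,25.46,26.74,32.11,1.76,34.76,32.92
4,50,50,60,35,71.80,1.98,71.23,71.96,36.54,2.36,34.91,38.89,30.36,1.15,29.09,29.69,32.01,1.66,34.34,32.16
5,30,50,40,35,65.33,4.25,67.46,67.04,22.04,3.14,23.66,27.68,25.65,2.17,25.54,25.69,49.29,1.39,45.89,49.31
6,50,50,40,40,66.40,2.64,61.25,64.13,32.71,2.77,33.02,32.96,26.04,1.94,23.66,24.69,32.16,1.58,33.16,32.43
7,50,50,40,26,65.33,3.14,64.58,64.30,28.57,3.35,23.77,28.84,25.65,1.81,26.75,25.69,38.04,1.95,38.24,37.65
8,50,35,60,40,65.95,1.64,66.07,64.15,35.81,2.31,33.71,35.46,26.33,0.37,26.31,25.37,33.79,2.75,31.37,33.11
9,70,50,40,35,53.03,2.88,55.90,55.18,57.45,2.87,58.90,59.83,17.46,1.75,19.28,15.56,20.03,3.88,20.35,18.57
10,30,35,40,40,63.56,4.35,63.72,63.08,22.04,2.70,19.80,24.23,23.58,1.44,24.24,23.82,43.83,3.65,42.28,42.29
11,50,35,40,35,66.25,1.61,67.37,67.87,25.55,1.93,26.78,30.05,28.19,1.52,29.34,28.38,44.22,2.44,44.87,43.17
12,30,20,40,35,67.65,3.47,65.86,65.63,22.67,3.40,23.95,22.34,26.01,1.85,25.18,25.24,38.21,3.36,35.48,39.26
13,30,35,60,35,64.40,2.95,66.65,65.95,24.76,1.88,27.94,24.88,21.68,1.17,24.44,21.63,34.40,2.38,37.80,34.26
14,30,35,40,26,69.76,1.98,68.74,70.00,22.87,2.67,20.52,25.6,31.06,1.99,29.73,31.05,32.27,2.35,34.60,31.39
15,50,20,60,35,58.12,3.16,55.24,58.67,35.92,3.79,33.78,34.02,20.91,2.33,19.38,20.16,29.95,2.01,30.32,29.34
16,50,20,40,26,50.57,2.75,54.26,52.15,28.22,3.02,24.01,28.7,15.95,1.34,17.74,15.03,27.22,1.58,28.33,25.49
17,70,20,40,35,50.17,2.97,49.13,49.92,47.20,2.75,48.33,48.85,14.40,2.20,15.52,14.6,24.73,2.98,25.73,25.71
18,70,35,40,26,47.69,3.11,46.29,47.69,41.30,1.79,42.90,41.44,13.06,1.12,11.74,12.79,24.24,3.45,25.97,22.54
19,30,35,20,35,61.70,3.77,60.00,62.25,27.95,2.78,26.50,26.29,28.75,2.30,27.62,28.86,36.34,2.15,38.31,35.5
20,50,35,40,35,68.01,2.58,67.37,67.87,26.78,2.35,26.78,30.05,31.41,1.60,29.34,28.38,45.85,2.64,44.87,43.17
21,50,20,20,35,57.71,3.79,56.89,58.75,27.12,1.97,29.68,27.4,25.08,1.89,25.69,23.98,34.02,2.78,31.64,31.77
22,50,35,20,26,56.82,4.20,57.25,57.09,24.74,2.78,29.61,26.32,22.46,2.64,22.99,23.22,31.65,2.25,30.47,33.00
23,70,35,40,40,54.69,3.13,54.19,53.26,48.86,1.95,53.73,48.9,21.18,1.52,21.85,20.19,22.24,2.46,19.62,22.75
24,70,35,60,35,53.98,2.65,56.01,54.85,58.59,2.60,56.39,55.7,20.18,1.39,21.00,20.03,20.33,2.62,20.85,18.74
25,70,35,20,35,44.28,2.95,42.35,46.88,64.49,3.10,57.66,62.51,18.22,2.29,15.14,17.55,20.88,2.35,19.97,19.10
26,50,35,20,40,46.44,3.57,48.98,48.97,33.21,3.16,31.01,30.82,21.93,1.67,24.15,21.26,28.34,3.69,31.29,31.17
27,50,35,40,35,67.85,4.10,67.37,67.87,28.02,1.30,26.78,30.05,28.41,1.71,29.34,28.38,44.55,2.45,44.87,43.17
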