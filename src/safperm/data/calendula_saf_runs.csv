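run_id,run_order,pressure_bar,co2_flow_g_min,y_pv_pct,y_dv_pct,y_saf_pct,e_cha_pv,e_caf_pv,e_fa_pv,e_all_pv
1,9,80,35,47.0,1.3,48.3,0.86,1.19,0.69,0.79
2,4,92,17,41.0,21.5,62.5,1.04,1.25,1.10,1.09
3,10,92,53,16.1,15.0,31.1,1.08,1.33,1.16,1.21
4,13,120,10,26.0,32.2,58.2,1.51,1.48,1.67,1.64
5,2,120,35,26.1,20.3,46.4,1.53,1.36,1.55,1.52
6,3,120,35,22.0,25.8,47.8,1.52,1.37,1.54,1.52
7,6,120,35,18.5,30.0,48.5,1.40,1.44,1.56,1.66
8,7,120,35,15.1,30.5,45.6,1.59,1.40,1.73,1.66
9,11,120,35,13.6,29.6,43.2,1.72,1.39,1.70,1.67
10,12,120,60,12.3,30.4,42.7,1.14,1.30,1.25,1.27
11,8,148,17,23.4,31.3,54.7,1.18,1.40,1.32,1.32
12,5,148,53,30.9,42.8,73.7,1.33,1.41,1.52,1.46
13,1,160,35,31.1,34.3,65.4,1.28,1.37,1.55,1.46
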