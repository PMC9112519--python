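sex,age_group,n,cold_prevalence_pct,mortality_per_100k,yld_prop,sbp_mean,sbp_sd,ihd_ir_per_100k,ihd_cfr,ihd_dr_per_100k,isch_stroke_ir_per_100k,isch_stroke_cfr,isch_stroke_dr_per_100k,hem_stroke_ir_per_100k,hem_stroke_cfr,hem_stroke_dr_per_100k
male,0-4,514007,8.98,18,0.032,,,0,0.000,0,5,0.000,23,2,0.001,0
male,5-9,500318,8.98,9,0.039,,,0,0.000,0,5,0.001,52,2,0.002,0
male,10-14,462301,8.98,11,0.056,,,0,0.000,0,5,0.003,81,2,0.003,0
male,15-19,478494,8.98,42,0.082,119.5,23.7,1,0.002,0,5,0.004,110,2,0.005,0
male,20-24,552493,8.98,64,0.098,119.5,23.7,2,0.011,2,6,0.005,143,3,0.007,0
male,25-29,578722,8.98,75,0.107,120.3,16.9,5,0.017,3,8,0.005,191,5,0.009,0
male,30-34,571793,8.98,93,0.114,120.3,16.9,15,0.024,5,14,0.007,266,8,0.012,1
male,35-39,516034,7.49,118,0.121,121.3,16.0,38,0.028,10,24,0.008,383,13,0.015,2
male,40-44,512660,7.49,169,0.127,121.3,16.0,86,0.027,20,39,0.009,573,20,0.017,3
male,45-49,499837,7.49,237,0.134,126.5,15.6,177,0.024,38,60,0.009,885,28,0.019,5
male,50-54,486978,7.49,354,0.145,126.5,15.6,312,0.021,63,90,0.009,1323,37,0.022,8
male,55-59,465154,5.52,535,0.159,132.4,18.5,486,0.018,97,134,0.010,1949,48,0.027,12
male,60-64,411857,5.52,800,0.177,132.4,18.5,721,0.017,154,200,0.011,2775,62,0.037,19
male,65-69,377806,5.52,1227,0.201,134.9,16.3,1001,0.017,255,286,0.014,3874,81,0.060,30
male,70-74,331006,5.52,2018,0.230,134.9,16.3,1310,0.018,376,386,0.018,5774,105,0.107,50
male,75-79,205258,3.40,3462,0.260,136.5,16.0,1696,0.023,501,518,0.026,8841,145,0.224,95
male,80-84,137498,3.40,6308,0.297,136.5,16.0,2245,0.035,649,727,0.043,12677,217,0.429,178
male,85-89,84731,3.40,11646,0.342,140.2,15.7,3096,0.066,770,1119,0.076,16667,350,0.720,331
male,90-94,32443,3.40,18487,0.388,140.2,15.7,4561,0.151,817,1687,0.139,19947,536,1.085,533
male,95-99,6255,3.40,30624,0.429,140.2,15.7,5678,0.224,813,2077,0.187,22295,623,1.254,622
male,100-104,590,3.40,30624,0.429,140.2,15.7,5678,0.224,813,2077,0.187,22295,623,1.254,622
female,0-4,486858,8.98,15,0.028,,,0,0.000,0,6,0.000,37,3,0.002,0
female,5-9,475040,8.98,8,0.038,,,0,0.000,0,6,0.000,85,3,0.002,0
female,10-14,437256,8.98,9,0.058,,,0,0.002,0,5,0.002,129,3,0.002,0
female,15-19,455281,8.98,23,0.096,107.6,16.5,1,0.001,0,5,0.004,171,3,0.003,0
female,20-24,528234,8.98,23,0.117,107.6,16.5,1,0.004,1,7,0.004,219,4,0.003,0
female,25-29,579388,8.98,29,0.125,108.5,17.1,2,0.006,3,10,0.003,293,6,0.005,0
female,30-34,580157,8.98,39,0.130,108.5,17.1,4,0.008,5,17,0.004,387,11,0.007,1
female,35-39,518900,7.49,65,0.137,112.5,16.2,8,0.011,9,27,0.005,553,17,0.010,2
female,40-44,522574,7.49,91,0.145,112.5,16.2,17,0.012,17,41,0.006,789,26,0.011,3
female,45-49,521716,7.49,141,0.152,119.6,20.1,37,0.012,28,59,0.006,1146,35,0.012,5
female,50-54,502591,7.49,214,0.156,119.6,20.1,68,0.011,44,82,0.007,1653,46,0.012,7
female,55-59,485496,5.52,311,0.164,126.8,19.0,114,0.011,65,112,0.007,2375,57,0.013,9
female,60-64,433268,5.52,462,0.178,126.8,19.0,189,0.012,97,163,0.007,3300,70,0.016,13
female,65-69,392690,5.52,721,0.200,133.6,16.7,294,0.013,161,240,0.009,4412,87,0.023,21
female,70-74,300714,5.52,1233,0.224,133.6,16.7,427,0.016,250,337,0.012,6132,111,0.042,36
female,75-79,229357,3.40,2242,0.249,137.9,14.8,610,0.024,364,460,0.020,8737,153,0.103,75
female,80-84,173515,3.40,4361,0.289,137.9,14.8,889,0.040,514,664,0.038,12137,229,0.232,153
female,85-89,127250,3.40,8819,0.337,140.8,16.2,1396,0.081,695,1085,0.073,16308,368,0.446,312
female,90-94,64694,3.40,16373,0.386,140.8,16.2,2607,0.192,802,1728,0.148,20097,562,0.735,547
female,95-99,16786,3.40,30867,0.434,140.8,16.2,3630,0.289,833,2178,0.208,22859,652,0.869,652
female,100-104,2018,3.40,30867,0.434,140.8,16.2,3630,0.289,833,2178,0.208,22859,652,0.869,652
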