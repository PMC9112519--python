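# SYNTHETIC stand-in relative-risk table (not the published supplementary values).
# GBD-style log-linear-in-age declining relative risks of disease incidence per
# 10 mmHg systolic blood pressure, anchored at IHD 55-59 = 1.60 and attenuating
# toward ~1.1 at the oldest ages. Replace with the published supplementary table
# for exact reproduction. rr_lo/rr_hi are 95% CI bounds used for uncertainty.
disease,age_group,rr_per_10mmhg,rr_lo,rr_hi
ihd,25-29,2.05,1.75,2.40
ihd,30-34,1.97,1.68,2.30
ihd,35-39,1.89,1.62,2.21
ihd,40-44,1.81,1.55,2.12
ihd,45-49,1.74,1.49,2.04
ihd,50-54,1.67,1.43,1.95
ihd,55-59,1.60,1.37,1.87
ihd,60-64,1.54,1.32,1.80
ihd,65-69,1.47,1.26,1.72
ihd,70-74,1.41,1.21,1.65
ihd,75-79,1.36,1.16,1.59
ihd,80-84,1.30,1.11,1.52
ihd,85-89,1.25,1.07,1.46
ihd,90-94,1.20,1.03,1.40
ihd,95-99,1.15,0.98,1.35
ihd,100-104,1.10,0.94,1.29
isch_stroke,25-29,2.45,2.09,2.87
isch_stroke,30-34,2.31,1.98,2.70
isch_stroke,35-39,2.19,1.87,2.56
isch_stroke,40-44,2.07,1.77,2.42
isch_stroke,45-49,1.96,1.68,2.29
isch_stroke,50-54,1.85,1.58,2.16
isch_stroke,55-59,1.75,1.50,2.05
isch_stroke,60-64,1.66,1.42,1.94
isch_stroke,65-69,1.57,1.34,1.84
isch_stroke,70-74,1.48,1.27,1.73
isch_stroke,75-79,1.40,1.20,1.64
isch_stroke,80-84,1.32,1.13,1.54
isch_stroke,85-89,1.25,1.07,1.46
isch_stroke,90-94,1.18,1.01,1.38
isch_stroke,95-99,1.12,0.96,1.31
isch_stroke,100-104,1.06,0.91,1.24
hem_stroke,25-29,2.64,2.26,3.09
hem_stroke,30-34,2.49,2.13,2.91
hem_stroke,35-39,2.35,2.01,2.75
hem_stroke,40-44,2.21,1.89,2.59
hem_stroke,45-49,2.08,1.78,2.43
hem_stroke,50-54,1.96,1.68,2.29
hem_stroke,55-59,1.85,1.58,2.16
hem_stroke,60-64,1.74,1.49,2.04
hem_stroke,65-69,1.64,1.40,1.92
hem_stroke,70-74,1.55,1.33,1.81
hem_stroke,75-79,1.46,1.25,1.71
hem_stroke,80-84,1.37,1.17,1.60
hem_stroke,85-89,1.30,1.11,1.52
hem_stroke,90-94,1.22,1.04,1.43
hem_stroke,95-99,1.15,0.98,1.35
hem_stroke,100-104,1.08,0.92,1.26
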