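model,r2x_cum,r2,q2,permutation_pass,r2_minus_q2,valid,p_cv_anova,significant
PA vs HC,0.63,0.95,0.71,yes,0.24,yes,1.83e-3,yes
PA vs PB,0.60,0.88,0.51,yes,0.37,no,1.37e-1,no
PA vs PC,0.65,0.88,0.66,yes,0.22,yes,1.00e-2,yes
PA vs PD,0.67,0.89,0.43,yes,0.46,no,2.42e-1,no
PA vs PE,0.47,0.67,0.33,yes,0.34,no,1.56e-1,no
HC vs PB,0.68,0.99,0.91,yes,0.08,yes,2.03e-6,yes
HC vs PC,0.67,0.99,0.91,yes,0.08,yes,4.81e-7,yes
HC vs PD,0.72,0.99,0.86,yes,0.13,yes,6.69e-4,yes
HC vs PE,0.54,0.99,0.72,yes,0.27,yes,1.19e-2,yes
PB vs PC,0.68,0.97,0.08,yes,0.89,no,9.97e-1,no
PB vs PD,0.61,0.76,0.12,yes,0.64,no,7.16e-1,no
PB vs PE,0.63,0.99,0.93,yes,0.06,yes,3.31e-7,yes
PC vs PD,0.58,0.68,0.24,yes,0.44,no,2.98e-1,no
PC vs PE,0.60,0.98,0.89,yes,0.09,yes,1.90e-7,yes
PD vs PE,0.57,0.84,0.69,yes,0.15,yes,3.43e-4,yes
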