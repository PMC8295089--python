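solute,delta_h,t_delta_s,delta_g,logp_calc,sem,logp_exp,abs_dlogp
SM25,-1.99,0.45,-2.44,1.79,0.67,2.67,0.88
SM26,1.07,-0.10,1.18,-0.86,0.22,1.04,1.90
SM27,0.67,1.19,-0.52,0.38,0.81,1.56,1.18
SM28,2.16,-0.42,2.58,-1.90,0.56,1.18,3.08
SM29,0.37,0.70,-0.33,0.24,1.93,1.61,1.37
SM30,-1.01,0.72,-1.73,1.27,1.05,2.76,1.49
SM31,-1.09,0.68,-1.77,1.30,0.26,1.96,0.66
SM32,1.99,0.60,1.40,-1.02,0.92,2.44,3.46
SM33,-3.25,1.70,-4.94,3.63,0.30,2.96,0.67
SM34,-2.58,0.28,-2.86,2.10,1.64,2.83,0.73
SM35,0.73,-0.01,0.74,-0.55,1.22,0.88,1.43
SM36,-1.87,0.61,-2.48,1.82,1.25,0.76,1.06
SM37,-0.68,0.76,-1.44,1.05,1.61,1.45,0.40
SM38,-2.97,0.68,-3.66,2.68,1.44,1.03,1.65
SM39,-2.75,1.31,-4.06,2.98,1.97,1.89,1.09
SM40,-0.17,0.68,-0.86,0.63,0.95,1.83,1.20
SM41,-4.29,-0.98,-3.31,2.42,1.59,0.58,1.84
SM42,-7.36,-0.19,-7.17,5.26,1.04,1.76,3.50
SM43,-3.27,0.32,-3.59,2.63,1.06,0.85,1.78
SM44,-6.54,-0.72,-5.82,4.27,0.41,1.16,3.11
SM45,-6.76,-0.36,-6.41,4.70,0.38,2.55,2.15
SM46,-2.90,0.11,-3.01,2.21,0.92,1.72,0.49
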