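role,parent_id,compound_id,c_pred,fit_value,c_reduction_pct,b_pred,b_increase_pct,p_pred_ev,p_reduction_pct,ratio
parent,TCPP,TCPP,2.22,,,1.62,,7.29,,
derivative,TCPP,TCPP-OH,1.40,5.75,37.03,2.52,55.48,3.91,46.37,1.20
derivative,TCPP,TCPP-CH2OH,1.24,5.82,44.06,2.31,42.43,3.43,52.98,0.80
derivative,TCPP,TCPP-NH2,1.31,5.93,41.14,2.57,58.76,4.60,36.93,1.59
derivative,TCPP,TCPP-COOH,1.49,5.84,32.94,2.23,37.69,4.35,40.38,0.93
derivative,TCPP,TCPP-CONH2,1.38,5.81,37.90,2.46,51.89,4.49,38.37,1.35
derivative,TCPP,TCPP-CHO,1.52,5.88,31.45,2.17,34.12,4.03,44.75,0.76
derivative,TCPP,TCPP-PO3H2,1.39,5.85,37.38,2.17,33.88,4.02,44.88,0.75
derivative,TCPP,TCPP-COOCH3,1.37,5.84,38.42,2.58,58.82,4.59,37.02,1.59
derivative,TCPP,TCPP-SO3H,1.39,5.85,37.30,2.17,33.77,4.67,35.98,0.94
parent,TCEP,TCEP,1.08,,,2.09,,7.28,,
derivative,TCEP,TCEP-OH,1.01,5.84,6.36,2.89,38.07,4.50,38.25,1.00
derivative,TCEP,TCEP-CH2OH,0.90,5.87,16.70,3.06,46.38,3.57,50.99,0.91
derivative,TCEP,TCEP-NH2,0.71,5.89,26.55,2.72,29.90,3.51,51.76,0.58
derivative,TCEP,TCEP-COOH,0.86,5.92,20.35,2.97,42.15,4.09,43.85,0.96
derivative,TCEP,TCEP-CONH2,0.79,5.87,27.11,3.00,43.60,4.53,37.77,1.15
derivative,TCEP,TCEP-CHO,0.61,5.93,26.40,2.82,34.61,3.46,52.41,0.66
derivative,TCEP,TCEP-PO3H2,1.01,5.97,6.46,3.01,43.98,4.95,31.99,1.37
derivative,TCEP,TCEP-COOCH3,0.79,5.79,26.87,2.92,39.46,5.05,30.58,1.29
derivative,TCEP,TCEP-SO3H,0.85,5.91,21.08,3.11,48.68,3.78,48.03,1.01
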