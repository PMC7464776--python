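role,parent_id,compound_id,flame_retardancy_kcal_mol,flame_enhanced_rate_pct,energy_gap_ev,gap_change_rate_pct,energy_au,energy_change_rate_pct,min_frequency
parent,TCPP,TCPP,225.72,,5.38,,-1023.57,,6.07
derivative,TCPP,TCPP-OH,209.57,7.15,5.15,-4.28,-1536.08,-50.07,2.34
derivative,TCPP,TCPP-CH2OH,256.70,-13.73,5.56,3.35,-1626.53,-58.91,2.16
derivative,TCPP,TCPP-COOH,294.37,-30.42,5.42,0.74,-1695.34,-65.63,2.44
derivative,TCPP,TCPP-CONH2,205.82,8.81,5.31,-1.30,-1563.15,-52.72,2.70
derivative,TCPP,TCPP-CHO,215.94,4.33,5.68,5.58,-1532.77,-49.75,2.51
derivative,TCPP,TCPP-PO3H2,201.83,10.58,5.39,0.19,-1506.84,-47.21,3.08
derivative,TCPP,TCPP-SO3H,266.90,-18.24,5.18,-3.72,-1551.22,-51.55,2.49
parent,TCEP,TCEP,273.03,,6.64,,-1375.51,,7.31
derivative,TCEP,TCEP-OH,310.61,-13.76,8.29,24.85,-1475.55,-7.27,5.89
derivative,TCEP,TCEP-CH2OH,322.95,-18.28,8.9,34.04,-1395.67,-1.47,4.67
derivative,TCEP,TCEP-COOH,327.24,-19.85,8.14,22.59,-1402.43,-1.96,5.14
derivative,TCEP,TCEP-CONH2,291.65,-6.82,7.86,18.37,-1433.19,-4.19,5.28
derivative,TCEP,TCEP-PO3H2,238.74,12.56,8.03,20.93,-1452.28,-5.58,4.72
derivative,TCEP,TCEP-COOCH3,255.25,6.51,8.42,26.81,-1466.84,-6.64,5.49
derivative,TCEP,TCEP-SO3H,270.96,0.76,8.34,25.60,-1467.63,-6.70,5.64
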