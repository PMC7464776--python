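compound_id,set_tag,binding_free_energy_kj_mol,efficacy_biodegradation,transition_energy_ev,efficacy_photodegradation,comprehensive_value
TCEP,training,−123.731,1.168,7.2805,0.992,1.08
TCIPP,training,−144.537,1.000,7.2211,1.000,1.00
TCPP,training,−41.842,3.454,7.2874,0.991,2.22
TDCIPP,test,−144.5,1.000,7.1323,0.988,0.99
TDCPP,training,−203.57,1.408,7.1821,0.995,1.20
TPHP,training,−190.952,1.321,5.4695,0.757,1.04
EHDPP,training,−196.153,1.357,5.4015,0.748,1.05
TEP,training,−219.226,1.517,5.3858,0.746,1.13
TBOEP,test,−84.125,1.718,7.6896,0.939,1.33
TEHP,training,−268.708,1.859,8.2033,0.880,1.37
TPrP,training,−22.103,6.539,8.2739,0.873,3.71
BdPhP,training,−180.854,1.251,5.4003,0.748,1.00
TMP,training,−19.82,7.292,8.1823,0.883,4.09
TiBP,training,−148.43,1.027,8.1651,0.884,0.96
TPeP,training,−74.236,1.947,8.3083,0.869,1.41
TnPP,training,−9.191,15.726,8.1795,0.883,8.30
TmTP,test,−219.036,1.515,5.2731,0.730,1.12
TpTP,test,−259.422,1.795,5.2399,0.726,1.26
TBPP,training,−88.759,1.628,4.3292,0.600,1.11
TiPP,test,−112.943,1.280,8.1537,0.886,1.08
CDPP,training,−208.576,1.443,5.3779,0.745,1.09
IDPP,training,−255.722,1.769,5.3928,0.747,1.26
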