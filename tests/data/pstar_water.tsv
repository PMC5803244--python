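# NIST PSTAR (ICRU 49) liquid water: proton collision stopping power and
# CSDA range at selected energies.  Independent oracle for the Bethe
# stopping-power and range implementation.
# columns: energy [MeV], stopping [MeV cm^2/g], csda_range [g/cm^2] (nan = not tabulated here)
energy	stopping	csda_range
5	79.11	nan
10	45.67	0.1230
20	26.07	0.4260
30	18.76	0.8853
40	14.89	1.489
50	12.45	2.227
60	10.80	3.093
70	9.559	4.080
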