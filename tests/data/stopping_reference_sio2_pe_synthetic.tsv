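# SYNTHETIC stand-in reference (no authoritative PSTAR rows packaged for
# these compounds): each value is the genuine PSTAR water entry scaled by the
# closed-form Bethe ratio (Z/A)_mat/(Z/A)_water x L(I_mat)/L(I_water) with
# L(I) = ln(2 m_e c^2 beta^2 gamma^2 / I) - beta^2, frozen at generation
# time.  SiO2: Z/A = 0.4993, I = 139.2 eV; polyethylene: Z/A = 0.5703,
# I = 57.4 eV.  These rows pin the compound-material handling relative to
# water; the water file is the independent absolute check.
# columns: material, energy [MeV], stopping [MeV cm^2/g]
material	energy	stopping
sio2	5	62.304
sio2	10	36.587
sio2	20	21.160
sio2	30	15.322
sio2	40	12.210
sio2	50	10.238
sio2	60	8.900
sio2	70	7.891
pe	5	85.649
pe	10	49.139
pe	20	27.915
pe	30	20.040
pe	40	15.882
pe	50	13.265
pe	60	11.498
pe	70	10.170
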