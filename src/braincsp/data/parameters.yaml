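# Reference parameter values of the brain energy metabolism model (v1).
# Any subset may be copied into a user config and passed via --config
# or braincsp.load_parameters() to override the defaults.
Ve: 0.2
Vcap: 0.0055
Vg: 0.25
Vn: 0.45
xi: 0.07
SmVn: 25000.0
SmVg: 25000.0
RT_F: 26.73
Faraday: 96485.3
psi_n: -73.59
psi_g: -70.0
Na_e: 150.0
gNa_n: 0.0136
gNa_g: 0.0061
gKpas: 0.2035
kpump_n: 2.2e-06
kpump_g: 4.5e-07
Jpump0_g: 0.0687
Km_pump: 0.5
Tmax_GLC_en: 0.041
Tmax_GLC_ce: 0.239
Tmax_GLC_eg: 0.147
Tmax_GLC_cg: 0.0016
Kt_GLC_en: 8.0
Kt_GLC_eg: 8.0
Kt_GLC_cg: 8.0
Kt_GLC_ge: 8.0
Kt_GLC_ce: 8.0
kHKPFK_n: 0.0504
kHKPFK_g: 0.185
KI_ATP: 1.0
nH: 4.0
Kg: 0.05
kPGK_n: 3.97
kPGK_g: 135.2
kPK_n: 36.7
kPK_g: 401.7
kLDHp_n: 72.3
kLDHp_g: 1.59
kLDHm_n: 0.72
kLDHm_g: 0.071
Tmax_LAC_gc: 0.00243
Tmax_LAC_ne: 24.3
Tmax_LAC_ge: 106.1
Tmax_LAC_ec: 0.25
Kt_LAC_en: 0.74
Kt_LAC_ge: 3.5
Kt_LAC_gc: 1.0
Kt_LAC_ec: 1.0
Vmax_in_n: 0.1303
Vmax_in_g: 5.7
Km_mito: 0.04
Km_NAD_n: 0.409
Km_NAD_g: 40.3
Km_ADP_n: 0.00341
Km_ADP_g: 0.000483
Km_NADH_n: 0.0444
Km_NADH_g: 0.0269
KO2_mito: 0.001
Vmax_out_n: 0.164
Vmax_out_g: 0.064
M_cyto_n: 4.9e-08
M_cyto_g: 0.00025
M_mito_n: 393000.0
M_mito_g: 10600.0
T_NADH_n: 10330.0
T_NADH_g: 150.0
C_tot: 10.0
kCKp_n: 0.0433
kCKp_g: 0.00135
kCKm_n: 0.00028
kCKm_g: 1.0e-05
KO2: 0.0361
HbOP: 8.6
nh_O2: 2.73
PScapVn: 1.66
PScapVg: 0.87
O2_a: 8.35
GLC_a: 4.75
LAC_a: 0.506
tau_v: 35.0
alpha_v: 0.5
Vv0: 0.02
dHb0: 0.058
N_tot: 0.212
A_tot: 2.212
qAK: 0.92
JATPases_n: 0.1695
JATPases_g: 0.1404
F0: 0.012
k1: 2.22
k2: 0.46
k3: 0.43
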