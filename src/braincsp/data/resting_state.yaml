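# Published resting-state values (mM; Vv dimensionless), v1.
# The package's canonical baseline is the Newton-refined fixed point
# seeded from these values; see braincsp.steady_state().
Na_n: 8.0
Na_g: 15.0
GLC_n: 1.2
GLC_g: 1.19
GAP_n: 0.0046
GAP_g: 0.0046
PEP_n: 0.015
PEP_g: 0.015
PYR_n: 0.17
PYR_g: 0.17
LAC_n: 0.6
LAC_g: 0.6
NADHcyto_n: 0.006
NADHcyto_g: 0.1
NADHmito_n: 0.12
NADHmito_g: 0.12
ATP_n: 2.2
ATP_g: 2.2
PCr_n: 4.9
PCr_g: 4.9
O2_n: 0.028
O2_g: 0.028
O2_c: 7.0
GLC_c: 4.5
LAC_c: 0.55
Vv: 0.02
dHb: 0.058
GLC_e: 2.48
LAC_e: 0.6
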