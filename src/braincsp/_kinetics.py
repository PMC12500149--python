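"""Generated by scripts/generate_kinetics.py -- do not edit.

Unidirectional rate laws and their analytic gradients with
respect to the state, in the canonical registry/state order.
"""

import math

import numpy as np

N_STATES = 29
N_REACTIONS = 67


def _unpack(y, p):
    (Na_n, Na_g, GLC_n, GLC_g, GAP_n, GAP_g, PEP_n, PEP_g, PYR_n, PYR_g, LAC_n, LAC_g, NADHcyto_n, NADHcyto_g, NADHmito_n, NADHmito_g, ATP_n, ATP_g, PCr_n, PCr_g, O2_n, O2_g, O2_c, GLC_c, LAC_c, Vv, dHb, GLC_e, LAC_e) = y
    A_tot = p.A_tot
    C_tot = p.C_tot
    F0 = p.F0
    Faraday = p.Faraday
    GLC_a = p.GLC_a
    HbOP = p.HbOP
    JATPases_g = p.JATPases_g
    JATPases_n = p.JATPases_n
    Jpump0_g = p.Jpump0_g
    KI_ATP = p.KI_ATP
    KO2 = p.KO2
    KO2_mito = p.KO2_mito
    Kg = p.Kg
    Km_ADP_g = p.Km_ADP_g
    Km_ADP_n = p.Km_ADP_n
    Km_NADH_g = p.Km_NADH_g
    Km_NADH_n = p.Km_NADH_n
    Km_NAD_g = p.Km_NAD_g
    Km_NAD_n = p.Km_NAD_n
    Km_mito = p.Km_mito
    Km_pump = p.Km_pump
    Kt_GLC_ce = p.Kt_GLC_ce
    Kt_GLC_cg = p.Kt_GLC_cg
    Kt_GLC_eg = p.Kt_GLC_eg
    Kt_GLC_en = p.Kt_GLC_en
    Kt_LAC_ec = p.Kt_LAC_ec
    Kt_LAC_en = p.Kt_LAC_en
    Kt_LAC_gc = p.Kt_LAC_gc
    Kt_LAC_ge = p.Kt_LAC_ge
    LAC_a = p.LAC_a
    M_cyto_g = p.M_cyto_g
    M_cyto_n = p.M_cyto_n
    M_mito_g = p.M_mito_g
    M_mito_n = p.M_mito_n
    N_tot = p.N_tot
    Na_e = p.Na_e
    O2_a = p.O2_a
    PScapVg = p.PScapVg
    PScapVn = p.PScapVn
    RT_F = p.RT_F
    SmVn = p.SmVn
    T_NADH_g = p.T_NADH_g
    T_NADH_n = p.T_NADH_n
    Tmax_GLC_ce = p.Tmax_GLC_ce
    Tmax_GLC_cg = p.Tmax_GLC_cg
    Tmax_GLC_eg = p.Tmax_GLC_eg
    Tmax_GLC_en = p.Tmax_GLC_en
    Tmax_LAC_ec = p.Tmax_LAC_ec
    Tmax_LAC_gc = p.Tmax_LAC_gc
    Tmax_LAC_ge = p.Tmax_LAC_ge
    Tmax_LAC_ne = p.Tmax_LAC_ne
    Vcap = p.Vcap
    Vmax_in_g = p.Vmax_in_g
    Vmax_in_n = p.Vmax_in_n
    Vmax_out_g = p.Vmax_out_g
    Vmax_out_n = p.Vmax_out_n
    Vv0 = p.Vv0
    alpha_v = p.alpha_v
    gNa_g = p.gNa_g
    gNa_n = p.gNa_n
    kCKm_g = p.kCKm_g
    kCKm_n = p.kCKm_n
    kCKp_g = p.kCKp_g
    kCKp_n = p.kCKp_n
    kHKPFK_g = p.kHKPFK_g
    kHKPFK_n = p.kHKPFK_n
    kLDHm_g = p.kLDHm_g
    kLDHm_n = p.kLDHm_n
    kLDHp_g = p.kLDHp_g
    kLDHp_n = p.kLDHp_n
    kPGK_g = p.kPGK_g
    kPGK_n = p.kPGK_n
    kPK_g = p.kPK_g
    kPK_n = p.kPK_n
    kpump_g = p.kpump_g
    kpump_n = p.kpump_n
    nH = p.nH
    nh_O2 = p.nh_O2
    psi_g = p.psi_g
    psi_n = p.psi_n
    qAK = p.qAK
    tau_v = p.tau_v
    return (Na_n, Na_g, GLC_n, GLC_g, GAP_n, GAP_g, PEP_n, PEP_g, PYR_n, PYR_g, LAC_n, LAC_g, NADHcyto_n, NADHcyto_g, NADHmito_n, NADHmito_g, ATP_n, ATP_g, PCr_n, PCr_g, O2_n, O2_g, O2_c, GLC_c, LAC_c, Vv, dHb, GLC_e, LAC_e), (A_tot, C_tot, F0, Faraday, GLC_a, HbOP, JATPases_g, JATPases_n, Jpump0_g, KI_ATP, KO2, KO2_mito, Kg, Km_ADP_g, Km_ADP_n, Km_NADH_g, Km_NADH_n, Km_NAD_g, Km_NAD_n, Km_mito, Km_pump, Kt_GLC_ce, Kt_GLC_cg, Kt_GLC_eg, Kt_GLC_en, Kt_LAC_ec, Kt_LAC_en, Kt_LAC_gc, Kt_LAC_ge, LAC_a, M_cyto_g, M_cyto_n, M_mito_g, M_mito_n, N_tot, Na_e, O2_a, PScapVg, PScapVn, RT_F, SmVn, T_NADH_g, T_NADH_n, Tmax_GLC_ce, Tmax_GLC_cg, Tmax_GLC_eg, Tmax_GLC_en, Tmax_LAC_ec, Tmax_LAC_gc, Tmax_LAC_ge, Tmax_LAC_ne, Vcap, Vmax_in_g, Vmax_in_n, Vmax_out_g, Vmax_out_n, Vv0, alpha_v, gNa_g, gNa_n, kCKm_g, kCKm_n, kCKp_g, kCKp_n, kHKPFK_g, kHKPFK_n, kLDHm_g, kLDHm_n, kLDHp_g, kLDHp_n, kPGK_g, kPGK_n, kPK_g, kPK_n, kpump_g, kpump_n, nH, nh_O2, psi_g, psi_n, qAK, tau_v)


def rates(y, F, vstim_n, vstim_g, p):
    """All 67 unidirectional rates, mM/s, registry order."""
    (Na_n, Na_g, GLC_n, GLC_g, GAP_n, GAP_g, PEP_n, PEP_g, PYR_n, PYR_g, LAC_n, LAC_g, NADHcyto_n, NADHcyto_g, NADHmito_n, NADHmito_g, ATP_n, ATP_g, PCr_n, PCr_g, O2_n, O2_g, O2_c, GLC_c, LAC_c, Vv, dHb, GLC_e, LAC_e), (A_tot, C_tot, F0, Faraday, GLC_a, HbOP, JATPases_g, JATPases_n, Jpump0_g, KI_ATP, KO2, KO2_mito, Kg, Km_ADP_g, Km_ADP_n, Km_NADH_g, Km_NADH_n, Km_NAD_g, Km_NAD_n, Km_mito, Km_pump, Kt_GLC_ce, Kt_GLC_cg, Kt_GLC_eg, Kt_GLC_en, Kt_LAC_ec, Kt_LAC_en, Kt_LAC_gc, Kt_LAC_ge, LAC_a, M_cyto_g, M_cyto_n, M_mito_g, M_mito_n, N_tot, Na_e, O2_a, PScapVg, PScapVn, RT_F, SmVn, T_NADH_g, T_NADH_n, Tmax_GLC_ce, Tmax_GLC_cg, Tmax_GLC_eg, Tmax_GLC_en, Tmax_LAC_ec, Tmax_LAC_gc, Tmax_LAC_ge, Tmax_LAC_ne, Vcap, Vmax_in_g, Vmax_in_n, Vmax_out_g, Vmax_out_n, Vv0, alpha_v, gNa_g, gNa_n, kCKm_g, kCKm_n, kCKp_g, kCKp_n, kHKPFK_g, kHKPFK_n, kLDHm_g, kLDHm_n, kLDHp_g, kLDHp_n, kPGK_g, kPGK_n, kPK_g, kPK_n, kpump_g, kpump_n, nH, nh_O2, psi_g, psi_n, qAK, tau_v) = _unpack(y, p)
    x0 = SmVn/Faraday
    x1 = (Km_pump)**(-1)
    x2 = ATP_n*Na_n*SmVn*kpump_n/(ATP_n*x1 + 1)
    x3 = ATP_g*Na_g*SmVn*kpump_g/(ATP_g*x1 + 1)
    x4 = (KI_ATP)**(-1)
    x5 = ATP_n*GLC_n*kHKPFK_n/((GLC_n + Kg)*((ATP_n*x4)**(nH) + 1))
    x6 = ATP_g*GLC_g*kHKPFK_g/((GLC_g + Kg)*((ATP_g*x4)**(nH) + 1))
    x7 = -N_tot
    x8 = NADHcyto_n + x7
    x9 = (ATP_n)**(-1)
    x10 = 4*A_tot
    x11 = qAK - 4
    x12 = (qAK*(x10*x9 + x11))**(1/2)
    x13 = (1/2)*ATP_n*(qAK - x12)
    x14 = GAP_n*kPGK_n*x13*x8/NADHcyto_n
    x15 = NADHcyto_g + x7
    x16 = (ATP_g)**(-1)
    x17 = (qAK*(x10*x16 + x11))**(1/2)
    x18 = (1/2)*ATP_g*(qAK - x17)
    x19 = GAP_g*kPGK_g*x15*x18/NADHcyto_g
    x20 = PEP_n*kPK_n*x13
    x21 = PEP_g*kPK_g*x18
    x22 = NADHmito_n + x7
    x23 = NADHmito_n*O2_n*Vmax_out_n*x13/((KO2_mito + O2_n)*(-Km_ADP_n + x13)*(Km_NADH_n + NADHmito_n))
    x24 = NADHmito_g + x7
    x25 = NADHmito_g*O2_g*Vmax_out_g*x18/((KO2_mito + O2_g)*(-Km_ADP_g + x18)*(Km_NADH_g + NADHmito_g))
    x26 = NADHcyto_n/x8
    x27 = x22/NADHmito_n
    x28 = NADHcyto_g/x15
    x29 = x24/NADHmito_g
    x30 = PCr_n*kCKp_n*x13
    x31 = ATP_n*kCKm_n*(C_tot - PCr_n)
    x32 = PCr_g*kCKp_g*x18
    x33 = ATP_g*kCKm_g*(C_tot - PCr_g)
    x34 = KO2*(HbOP/O2_c - 1)**(-1/nh_O2)
    x35 = (Vcap)**(-1)
    x36 = 2*F
    x37 = x36*(O2_a - O2_c)
    x38 = x35*x36
    x39 = A_tot*qAK
    x40 = (1/2)*qAK - 2
    x41 = (-1/2*x12 + x40 + x39*x9/x12)**(-1)
    x42 = (x16*x39/x17 - 1/2*x17 + x40)**(-1)
    x43 = (Vv0)**(-1)
    x44 = tau_v*(x43)**(1/2)/(Vv)**(1/2)
    x45 = F0*(F*x44 + (Vv*x43)**((alpha_v)**(-1)))/(F0*x44 + 1)
    out = np.empty(67)
    out[0] = gNa_n*x0*(RT_F*math.log(Na_e/Na_n) - psi_n)
    out[1] = gNa_g*x0*(RT_F*math.log(Na_e/Na_g) - psi_g)
    out[2] = x2
    out[3] = x3
    out[4] = GLC_e*Tmax_GLC_en/(GLC_e + Kt_GLC_en)
    out[5] = GLC_n*Tmax_GLC_en/(GLC_n + Kt_GLC_en)
    out[6] = GLC_e*Tmax_GLC_eg/(GLC_e + Kt_GLC_eg)
    out[7] = GLC_g*Tmax_GLC_eg/(GLC_g + Kt_GLC_eg)
    out[8] = GLC_c*Tmax_GLC_cg/(GLC_c + Kt_GLC_cg)
    out[9] = GLC_g*Tmax_GLC_cg/(GLC_g + Kt_GLC_cg)
    out[10] = GLC_c*Tmax_GLC_ce/(GLC_c + Kt_GLC_ce)
    out[11] = GLC_e*Tmax_GLC_ce/(GLC_e + Kt_GLC_ce)
    out[12] = x5
    out[13] = x6
    out[14] = x14
    out[15] = x19
    out[16] = -x20
    out[17] = -x21
    out[18] = NADHcyto_n*PYR_n*kLDHp_n
    out[19] = -LAC_n*kLDHm_n*x8
    out[20] = NADHcyto_g*PYR_g*kLDHp_g
    out[21] = -LAC_g*kLDHm_g*x15
    out[22] = LAC_n*Tmax_LAC_ne/(Kt_LAC_en + LAC_n)
    out[23] = LAC_e*Tmax_LAC_ne/(Kt_LAC_en + LAC_e)
    out[24] = LAC_g*Tmax_LAC_ge/(Kt_LAC_ge + LAC_g)
    out[25] = LAC_e*Tmax_LAC_ge/(Kt_LAC_ge + LAC_e)
    out[26] = LAC_g*Tmax_LAC_gc/(Kt_LAC_gc + LAC_g)
    out[27] = LAC_c*Tmax_LAC_gc/(Kt_LAC_gc + LAC_c)
    out[28] = LAC_e*Tmax_LAC_ec/(Kt_LAC_ec + LAC_e)
    out[29] = LAC_c*Tmax_LAC_ec/(Kt_LAC_ec + LAC_c)
    out[30] = -PYR_n*Vmax_in_n*x22/((Km_mito + PYR_n)*(Km_NAD_n - NADHmito_n + N_tot))
    out[31] = x23
    out[32] = -PYR_g*Vmax_in_g*x24/((Km_mito + PYR_g)*(Km_NAD_g - NADHmito_g + N_tot))
    out[33] = x25
    out[34] = T_NADH_n*x26*x27/((M_cyto_n - x26)*(M_mito_n - x27))
    out[35] = T_NADH_g*x28*x29/((M_cyto_g - x28)*(M_mito_g - x29))
    out[36] = -x30
    out[37] = x31
    out[38] = -x32
    out[39] = x33
    out[40] = PScapVn*(-O2_n + x34)
    out[41] = PScapVg*(-O2_g + x34)
    out[42] = x35*x37
    out[43] = x38*(GLC_a - GLC_c)
    out[44] = x38*(LAC_a - LAC_c)
    out[45] = -JATPases_n*x41
    out[46] = -JATPases_g*x42
    out[47] = -Jpump0_g*x42
    out[48] = F - x45
    out[49] = x37
    out[50] = dHb*x45/Vv
    out[51] = vstim_n
    out[52] = vstim_g
    out[53] = -x41*x5
    out[54] = -x42*x6
    out[55] = -x14*x41
    out[56] = -x19*x42
    out[57] = x20*x41
    out[58] = x21*x42
    out[59] = -x2*x41
    out[60] = -x3*x42
    out[61] = -x23*x41
    out[62] = -x25*x42
    out[63] = x30*x41
    out[64] = -x31*x41
    out[65] = x32*x42
    out[66] = -x33*x42
    return out


def rate_gradients(y, F, vstim_n, vstim_g, p):
    """d(rates)/d(state): dense (67, 29) array of analytic partials."""
    (Na_n, Na_g, GLC_n, GLC_g, GAP_n, GAP_g, PEP_n, PEP_g, PYR_n, PYR_g, LAC_n, LAC_g, NADHcyto_n, NADHcyto_g, NADHmito_n, NADHmito_g, ATP_n, ATP_g, PCr_n, PCr_g, O2_n, O2_g, O2_c, GLC_c, LAC_c, Vv, dHb, GLC_e, LAC_e), (A_tot, C_tot, F0, Faraday, GLC_a, HbOP, JATPases_g, JATPases_n, Jpump0_g, KI_ATP, KO2, KO2_mito, Kg, Km_ADP_g, Km_ADP_n, Km_NADH_g, Km_NADH_n, Km_NAD_g, Km_NAD_n, Km_mito, Km_pump, Kt_GLC_ce, Kt_GLC_cg, Kt_GLC_eg, Kt_GLC_en, Kt_LAC_ec, Kt_LAC_en, Kt_LAC_gc, Kt_LAC_ge, LAC_a, M_cyto_g, M_cyto_n, M_mito_g, M_mito_n, N_tot, Na_e, O2_a, PScapVg, PScapVn, RT_F, SmVn, T_NADH_g, T_NADH_n, Tmax_GLC_ce, Tmax_GLC_cg, Tmax_GLC_eg, Tmax_GLC_en, Tmax_LAC_ec, Tmax_LAC_gc, Tmax_LAC_ge, Tmax_LAC_ne, Vcap, Vmax_in_g, Vmax_in_n, Vmax_out_g, Vmax_out_n, Vv0, alpha_v, gNa_g, gNa_n, kCKm_g, kCKm_n, kCKp_g, kCKp_n, kHKPFK_g, kHKPFK_n, kLDHm_g, kLDHm_n, kLDHp_g, kLDHp_n, kPGK_g, kPGK_n, kPK_g, kPK_n, kpump_g, kpump_n, nH, nh_O2, psi_g, psi_n, qAK, tau_v) = _unpack(y, p)
    x0 = RT_F*SmVn/Faraday
    x1 = (Km_pump)**(-1)
    x2 = ATP_n*x1
    x3 = (x2 + 1)**(-1)
    x4 = SmVn*kpump_n*x3
    x5 = ATP_n*x4
    x6 = x2*x3 - 1
    x7 = Na_n*x4
    x8 = ATP_g*x1
    x9 = (x8 + 1)**(-1)
    x10 = SmVn*kpump_g*x9
    x11 = ATP_g*x10
    x12 = x8*x9 - 1
    x13 = Na_g*x10
    x14 = (GLC_e + Kt_GLC_en)**(-1)
    x15 = (GLC_n + Kt_GLC_en)**(-1)
    x16 = (GLC_e + Kt_GLC_eg)**(-1)
    x17 = (GLC_g + Kt_GLC_eg)**(-1)
    x18 = (GLC_c + Kt_GLC_cg)**(-1)
    x19 = (GLC_g + Kt_GLC_cg)**(-1)
    x20 = (GLC_c + Kt_GLC_ce)**(-1)
    x21 = (GLC_e + Kt_GLC_ce)**(-1)
    x22 = (GLC_n + Kg)**(-1)
    x23 = GLC_n*x22
    x24 = x23 - 1
    x25 = (KI_ATP)**(-1)
    x26 = (ATP_n*x25)**(nH)
    x27 = (x26 + 1)**(-1)
    x28 = kHKPFK_n*x27
    x29 = ATP_n*x22*x28
    x30 = nH*x26*x27 - 1
    x31 = x23*x28
    x32 = (GLC_g + Kg)**(-1)
    x33 = GLC_g*x32
    x34 = x33 - 1
    x35 = (ATP_g*x25)**(nH)
    x36 = (x35 + 1)**(-1)
    x37 = kHKPFK_g*x36
    x38 = ATP_g*x32*x37
    x39 = nH*x35*x36 - 1
    x40 = x33*x37
    x41 = (ATP_n)**(-1)
    x42 = 4*A_tot
    x43 = qAK - 4
    x44 = qAK*(x41*x42 + x43)
    x45 = (x44)**(1/2)
    x46 = qAK - x45
    x47 = ATP_n*x46
    x48 = (1/2)*x47
    x49 = (NADHcyto_n)**(-1)
    x50 = -N_tot
    x51 = NADHcyto_n + x50
    x52 = x49*x51
    x53 = kPGK_n*x52
    x54 = x48*x53
    x55 = 1 - x52
    x56 = GAP_n*kPGK_n*x49
    x57 = (1/2)*qAK
    x58 = A_tot*qAK
    x59 = x41*x58/x45
    x60 = -1/2*x45 + x57 + x59
    x61 = GAP_n*x53
    x62 = (ATP_g)**(-1)
    x63 = qAK*(x42*x62 + x43)
    x64 = (x63)**(1/2)
    x65 = qAK - x64
    x66 = ATP_g*x65
    x67 = (1/2)*x66
    x68 = (NADHcyto_g)**(-1)
    x69 = NADHcyto_g + x50
    x70 = x68*x69
    x71 = kPGK_g*x70
    x72 = x67*x71
    x73 = 1 - x70
    x74 = GAP_g*kPGK_g*x68
    x75 = x58*x62/x64
    x76 = x57 - 1/2*x64 + x75
    x77 = GAP_g*x71
    x78 = kPK_n*x48
    x79 = PEP_n*kPK_n
    x80 = kPK_g*x67
    x81 = PEP_g*kPK_g
    x82 = (Kt_LAC_en + LAC_n)**(-1)
    x83 = (Kt_LAC_en + LAC_e)**(-1)
    x84 = (Kt_LAC_ge + LAC_g)**(-1)
    x85 = (Kt_LAC_ge + LAC_e)**(-1)
    x86 = (Kt_LAC_gc + LAC_g)**(-1)
    x87 = (Kt_LAC_gc + LAC_c)**(-1)
    x88 = (Kt_LAC_ec + LAC_e)**(-1)
    x89 = (Kt_LAC_ec + LAC_c)**(-1)
    x90 = (Km_mito + PYR_n)**(-1)
    x91 = PYR_n*x90
    x92 = NADHmito_n + x50
    x93 = (Km_NAD_n - NADHmito_n + N_tot)**(-1)
    x94 = x92*x93
    x95 = (Km_NADH_n + NADHmito_n)**(-1)
    x96 = NADHmito_n*x95
    x97 = x96 - 1
    x98 = -2*Km_ADP_n + x47
    x99 = -1/x98
    x100 = (KO2_mito + O2_n)**(-1)
    x101 = O2_n*x100
    x102 = Vmax_out_n*x101*x99
    x103 = x102*x47*x95
    x104 = 2*x59
    x105 = x104 + x46
    x106 = x105*x47
    x107 = x101 - 1
    x108 = Vmax_out_n*x96
    x109 = x100*x108*x47*x99
    x110 = (Km_mito + PYR_g)**(-1)
    x111 = PYR_g*x110
    x112 = NADHmito_g + x50
    x113 = (Km_NAD_g - NADHmito_g + N_tot)**(-1)
    x114 = x112*x113
    x115 = (Km_NADH_g + NADHmito_g)**(-1)
    x116 = NADHmito_g*x115
    x117 = x116 - 1
    x118 = -2*Km_ADP_g + x66
    x119 = -1/x118
    x120 = (KO2_mito + O2_g)**(-1)
    x121 = O2_g*x120
    x122 = Vmax_out_g*x119*x121
    x123 = x115*x122*x66
    x124 = 2*x75
    x125 = x124 + x65
    x126 = x125*x66
    x127 = x121 - 1
    x128 = Vmax_out_g*x116
    x129 = x119*x120*x128*x66
    x130 = (x51)**(-1)
    x131 = NADHcyto_n*x130
    x132 = (M_cyto_n - x131)**(-1)
    x133 = -NADHcyto_n/x51
    x134 = (NADHmito_n)**(-1)
    x135 = x134*x92
    x136 = -x135
    x137 = (M_mito_n + x136)**(-1)
    x138 = x135*x137
    x139 = T_NADH_n*x132
    x140 = x136 + 1
    x141 = (x69)**(-1)
    x142 = NADHcyto_g*x141
    x143 = (M_cyto_g - x142)**(-1)
    x144 = -NADHcyto_g/x69
    x145 = (NADHmito_g)**(-1)
    x146 = x112*x145
    x147 = -x146
    x148 = (M_mito_g + x147)**(-1)
    x149 = x146*x148
    x150 = T_NADH_g*x143
    x151 = x147 + 1
    x152 = PCr_n*kCKp_n
    x153 = kCKp_n*x48
    x154 = kCKm_n*(C_tot - PCr_n)
    x155 = ATP_n*kCKm_n
    x156 = PCr_g*kCKp_g
    x157 = kCKp_g*x67
    x158 = kCKm_g*(C_tot - PCr_g)
    x159 = ATP_g*kCKm_g
    x160 = (nh_O2)**(-1)
    x161 = HbOP/O2_c - 1
    x162 = HbOP*KO2*x160*(x161)**(-x160)/((O2_c)**(2)*x161)
    x163 = 2*F
    x164 = -x163/Vcap
    x165 = (x44)**(-3/2)
    x166 = x60 - 2
    x167 = (A_tot)**(2)
    x168 = (qAK)**(2)
    x169 = x167*x168
    x170 = 2*x169
    x171 = (x63)**(-3/2)
    x172 = x76 - 2
    x173 = x170*x171/((ATP_g)**(3)*(x172)**(2))
    x174 = (Vv)**(-3/2)
    x175 = (Vv0)**(-1)
    x176 = (x175)**(-1/2)
    x177 = (Vv)**(-1)
    x178 = (alpha_v)**(-1)
    x179 = (Vv*x175)**(x178)
    x180 = x177*x178*x179
    x181 = tau_v*x175*x176
    x182 = x174*x181
    x183 = x181/(Vv)**(1/2)
    x184 = F*x183 + x179
    x185 = (F0*x183 + 1)**(-1)
    x186 = F0*x185
    x187 = x184*x186
    x188 = (x105 - 4)**(-1)
    x189 = 2*x188
    x190 = (ATP_n)**(-2)
    x191 = 4*x169
    x192 = x165*x188*x190*x191
    x193 = (x125 - 4)**(-1)
    x194 = 2*x193
    x195 = (ATP_g)**(-2)
    x196 = x171*x191*x193*x195
    x197 = (x166)**(-1)
    x198 = x105 - 4*x165*x167*x168*x188*x190*x46
    x199 = (x172)**(-1)
    x200 = x125 - 4*x167*x168*x171*x193*x195*x65
    x201 = x188*x198
    x202 = x193*x200
    x203 = (x98)**(-1)
    x204 = -qAK
    x205 = (x118)**(-1)
    out = np.zeros((67, 29))
    out[0, 0] = -gNa_n*x0/Na_n
    out[1, 1] = -gNa_g*x0/Na_g
    out[2, 0] = x5
    out[2, 16] = -x6*x7
    out[3, 1] = x11
    out[3, 17] = -x12*x13
    out[4, 27] = Tmax_GLC_en*x14*(-GLC_e*x14 + 1)
    out[5, 2] = Tmax_GLC_en*x15*(-GLC_n*x15 + 1)
    out[6, 27] = Tmax_GLC_eg*x16*(-GLC_e*x16 + 1)
    out[7, 3] = Tmax_GLC_eg*x17*(-GLC_g*x17 + 1)
    out[8, 23] = Tmax_GLC_cg*x18*(-GLC_c*x18 + 1)
    out[9, 3] = Tmax_GLC_cg*x19*(-GLC_g*x19 + 1)
    out[10, 23] = Tmax_GLC_ce*x20*(-GLC_c*x20 + 1)
    out[11, 27] = Tmax_GLC_ce*x21*(-GLC_e*x21 + 1)
    out[12, 2] = -x24*x29
    out[12, 16] = -x30*x31
    out[13, 3] = -x34*x38
    out[13, 17] = -x39*x40
    out[14, 4] = x54
    out[14, 12] = x48*x55*x56
    out[14, 16] = x60*x61
    out[15, 5] = x72
    out[15, 13] = x67*x73*x74
    out[15, 17] = x76*x77
    out[16, 6] = -x78
    out[16, 16] = -x60*x79
    out[17, 7] = -x80
    out[17, 17] = -x76*x81
    out[18, 8] = NADHcyto_n*kLDHp_n
    out[18, 12] = PYR_n*kLDHp_n
    out[19, 10] = -kLDHm_n*x51
    out[19, 12] = -LAC_n*kLDHm_n
    out[20, 9] = NADHcyto_g*kLDHp_g
    out[20, 13] = PYR_g*kLDHp_g
    out[21, 11] = -kLDHm_g*x69
    out[21, 13] = -LAC_g*kLDHm_g
    out[22, 10] = Tmax_LAC_ne*x82*(-LAC_n*x82 + 1)
    out[23, 28] = Tmax_LAC_ne*x83*(-LAC_e*x83 + 1)
    out[24, 11] = Tmax_LAC_ge*x84*(-LAC_g*x84 + 1)
    out[25, 28] = Tmax_LAC_ge*x85*(-LAC_e*x85 + 1)
    out[26, 11] = Tmax_LAC_gc*x86*(-LAC_g*x86 + 1)
    out[27, 24] = Tmax_LAC_gc*x87*(-LAC_c*x87 + 1)
    out[28, 28] = Tmax_LAC_ec*x88*(-LAC_e*x88 + 1)
    out[29, 24] = Tmax_LAC_ec*x89*(-LAC_c*x89 + 1)
    out[30, 8] = Vmax_in_n*x90*x94*(x91 - 1)
    out[30, 14] = -Vmax_in_n*x91*x93*(x94 + 1)
    out[31, 14] = x103*x97
    out[31, 16] = -x102*x96*(x105 + x106*x99)
    out[31, 20] = x107*x109
    out[32, 9] = Vmax_in_g*x110*x114*(x111 - 1)
    out[32, 15] = -Vmax_in_g*x111*x113*(x114 + 1)
    out[33, 15] = x117*x123
    out[33, 17] = -x116*x122*(x119*x126 + x125)
    out[33, 21] = x127*x129
    out[34, 12] = x130*x138*x139*(-x131 - x132*x133*(x133 + 1) + 1)
    out[34, 14] = x131*x134*x137*x139*(x138*x140 + x140)
    out[35, 13] = x141*x149*x150*(-x142 - x143*x144*(x144 + 1) + 1)
    out[35, 15] = x142*x145*x148*x150*(x149*x151 + x151)
    out[36, 16] = -x152*x60
    out[36, 18] = -x153
    out[37, 16] = x154
    out[37, 18] = -x155
    out[38, 17] = -x156*x76
    out[38, 19] = -x157
    out[39, 17] = x158
    out[39, 19] = -x159
    out[40, 20] = -PScapVn
    out[40, 22] = PScapVn*x162
    out[41, 21] = -PScapVg
    out[41, 22] = PScapVg*x162
    out[42, 22] = x164
    out[43, 23] = x164
    out[44, 24] = x164
    out[45, 16] = JATPases_n*x165*x170/((ATP_n)**(3)*(x166)**(2))
    out[46, 17] = JATPases_g*x173
    out[47, 17] = Jpump0_g*x173
    out[48, 25] = x186*((1/2)*F*tau_v*x174*x175*x176 - x180 - 1/2*x182*x187)
    out[49, 22] = -x163
    out[50, 25] = dHb*x186*((1/2)*F0*tau_v*x175*x176*x184*x185/(Vv)**(5/2) - 1/2*x177*(F*x182 - 2*x180) - x184/(Vv)**(2))
    out[50, 26] = x177*x187
    out[53, 2] = x189*x24*x29
    out[53, 16] = x189*x31*(x192 + x30)
    out[54, 3] = x194*x34*x38
    out[54, 17] = x194*x40*(x196 + x39)
    out[55, 4] = -x197*x54
    out[55, 12] = -x188*x47*x55*x56
    out[55, 16] = -x188*x198*x61
    out[56, 5] = -x199*x72
    out[56, 13] = -x193*x66*x73*x74
    out[56, 17] = -x193*x200*x77
    out[57, 6] = x197*x78
    out[57, 16] = x201*x79
    out[58, 7] = x199*x80
    out[58, 17] = x202*x81
    out[59, 0] = -x197*x5
    out[59, 16] = x189*x7*(x192 + x6)
    out[60, 1] = -x11*x199
    out[60, 17] = x13*x194*(x12 + x196)
    out[61, 14] = -x103*x189*x97
    out[61, 16] = x101*x108*x189*x203*(-x104 + x106*x203 + x192*x46 + x204 + x45)
    out[61, 20] = -x107*x109*x189
    out[62, 15] = -x117*x123*x194
    out[62, 17] = x121*x128*x194*x205*(-x124 + x126*x205 + x196*x65 + x204 + x64)
    out[62, 21] = -x127*x129*x194
    out[63, 16] = x152*x201
    out[63, 18] = x153*x197
    out[64, 16] = x154*x189*(4*x165*x167*x168*x188*x190 - 1)
    out[64, 18] = x155*x197
    out[65, 17] = x156*x202
    out[65, 19] = x157*x199
    out[66, 17] = x158*x194*(4*x167*x168*x171*x193*x195 - 1)
    out[66, 19] = x159*x199
    return out
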