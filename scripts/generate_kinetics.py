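"""Generate braincsp/_kinetics.py: rate laws and analytic rate gradients.

Builds every unidirectional rate law symbolically (including the
adenine-pool closure ADP(ATP), the S1/S2 stoichiometry-regularisation
factors and the venous balloon outflow), differentiates with respect to
the 29 state variables, and emits a plain-Python module with the
common-subexpression-eliminated results.  Run from the repository root:

    python scripts/generate_kinetics.py

The generated file is committed; regenerating it requires sympy.
"""

from __future__ import annotations

import sys
from pathlib import Path

import sympy as sp
from sympy.printing.pycode import PythonCodePrinter

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from braincsp.registry import LABELS  # noqa: E402
from braincsp.state import STATE_NAMES  # noqa: E402

PARAM_NAMES = [
    "SmVn", "SmVg", "RT_F", "Faraday", "psi_n", "psi_g", "Na_e",
    "gNa_n", "gNa_g", "kpump_n", "kpump_g", "Jpump0_g", "Km_pump",
    "Tmax_GLC_en", "Tmax_GLC_ce", "Tmax_GLC_eg", "Tmax_GLC_cg",
    "Kt_GLC_en", "Kt_GLC_eg", "Kt_GLC_cg", "Kt_GLC_ce",
    "kHKPFK_n", "kHKPFK_g", "KI_ATP", "nH", "Kg",
    "kPGK_n", "kPGK_g", "kPK_n", "kPK_g",
    "kLDHp_n", "kLDHp_g", "kLDHm_n", "kLDHm_g",
    "Tmax_LAC_gc", "Tmax_LAC_ne", "Tmax_LAC_ge", "Tmax_LAC_ec",
    "Kt_LAC_en", "Kt_LAC_ge", "Kt_LAC_gc", "Kt_LAC_ec",
    "Vmax_in_n", "Vmax_in_g", "Km_mito", "Km_NAD_n", "Km_NAD_g",
    "Km_ADP_n", "Km_ADP_g", "Km_NADH_n", "Km_NADH_g",
    "KO2_mito", "Vmax_out_n", "Vmax_out_g",
    "M_cyto_n", "M_cyto_g", "M_mito_n", "M_mito_g", "T_NADH_n", "T_NADH_g",
    "C_tot", "kCKp_n", "kCKp_g", "kCKm_n", "kCKm_g",
    "KO2", "HbOP", "nh_O2", "PScapVn", "PScapVg",
    "O2_a", "GLC_a", "LAC_a",
    "tau_v", "alpha_v", "Vv0",
    "N_tot", "A_tot", "qAK", "JATPases_n", "JATPases_g",
    "F0", "Vcap",
]


def build_rate_expressions():
    s = {name: sp.Symbol(name, positive=True) for name in STATE_NAMES}
    p = {name: sp.Symbol(name) for name in PARAM_NAMES}
    F = sp.Symbol("F", positive=True)           # instantaneous CBF, 1/s
    vstim_n = sp.Symbol("vstim_n")
    vstim_g = sp.Symbol("vstim_g")

    def adp(atp):
        return atp / 2 * (-p["qAK"] + sp.sqrt(
            p["qAK"] ** 2 + 4 * p["qAK"] * (p["A_tot"] / atp - 1)))

    ADP_n = adp(s["ATP_n"])
    ADP_g = adp(s["ATP_g"])

    def s_factor(atp):
        # S = (1 - dAMP/dATP)^-1 with AMP = A - ATP - ADP(ATP)
        amp = p["A_tot"] - atp - adp(atp)
        return 1 / (1 - sp.diff(amp, atp))

    S1 = s_factor(s["ATP_n"])
    S2 = s_factor(s["ATP_g"])

    # venous balloon outflow, closed form of the implicit relation
    # Fout = F0 [ v^(1/alpha) + tau_v/Vv0 v^(-1/2) dVv/dt ], dVv/dt = F - Fout
    v = s["Vv"] / p["Vv0"]
    cc = p["F0"] * p["tau_v"] / (p["Vv0"] * sp.sqrt(v))
    Fout = (p["F0"] * v ** (1 / p["alpha_v"]) + cc * F) / (1 + cc)

    def leak(gna, na, psi):
        return (p["SmVn"] * gna / p["Faraday"]) * (
            p["RT_F"] * sp.log(p["Na_e"] / na) - psi)

    def pump(kp, atp, na):
        return p["SmVn"] * kp * atp * na / (1 + atp / p["Km_pump"])

    def carrier(tmax, conc, kt):
        return tmax * conc / (conc + kt)

    def hkpfk(k, atp, glc):
        return k * atp * (glc / (glc + p["Kg"])) / (
            1 + (atp / p["KI_ATP"]) ** p["nH"])

    def pgk(k, gap, adp_, nadh):
        return k * gap * adp_ * (p["N_tot"] - nadh) / nadh

    def tca(vmax, pyr, nadh_m, km_nad):
        nad = p["N_tot"] - nadh_m
        return vmax * (pyr / (pyr + p["Km_mito"])) * (nad / (nad + km_nad))

    def etc(vmax, o2, adp_, km_adp, nadh_m, km_nadh):
        return (vmax * (o2 / (o2 + p["KO2_mito"]))
                * (adp_ / (adp_ + km_adp))
                * (nadh_m / (nadh_m + km_nadh)))

    def shuttle(t_nadh, nadh_c, nadh_m, m_cyto, m_mito):
        r_minus = nadh_c / (p["N_tot"] - nadh_c)
        r_plus = (p["N_tot"] - nadh_m) / nadh_m
        return (t_nadh * (r_minus / (r_minus + m_cyto))
                * (r_plus / (r_plus + m_mito)))

    def o2_exchange(ps, o2x):
        return ps * (p["KO2"] * (p["HbOP"] / s["O2_c"] - 1) ** (-1 / p["nh_O2"])
                     - o2x)

    R: dict[str, sp.Expr] = {}
    R["1"] = leak(p["gNa_n"], s["Na_n"], p["psi_n"])
    R["2"] = leak(p["gNa_g"], s["Na_g"], p["psi_g"])
    R["3"] = pump(p["kpump_n"], s["ATP_n"], s["Na_n"])
    R["4"] = pump(p["kpump_g"], s["ATP_g"], s["Na_g"])
    R["5f"] = carrier(p["Tmax_GLC_en"], s["GLC_e"], p["Kt_GLC_en"])
    R["5b"] = carrier(p["Tmax_GLC_en"], s["GLC_n"], p["Kt_GLC_en"])
    R["6f"] = carrier(p["Tmax_GLC_eg"], s["GLC_e"], p["Kt_GLC_eg"])
    R["6b"] = carrier(p["Tmax_GLC_eg"], s["GLC_g"], p["Kt_GLC_eg"])
    R["7f"] = carrier(p["Tmax_GLC_cg"], s["GLC_c"], p["Kt_GLC_cg"])
    R["7b"] = carrier(p["Tmax_GLC_cg"], s["GLC_g"], p["Kt_GLC_cg"])
    R["8f"] = carrier(p["Tmax_GLC_ce"], s["GLC_c"], p["Kt_GLC_ce"])
    R["8b"] = carrier(p["Tmax_GLC_ce"], s["GLC_e"], p["Kt_GLC_ce"])
    R["9"] = hkpfk(p["kHKPFK_n"], s["ATP_n"], s["GLC_n"])
    R["10"] = hkpfk(p["kHKPFK_g"], s["ATP_g"], s["GLC_g"])
    R["11"] = pgk(p["kPGK_n"], s["GAP_n"], ADP_n, s["NADHcyto_n"])
    R["12"] = pgk(p["kPGK_g"], s["GAP_g"], ADP_g, s["NADHcyto_g"])
    R["13"] = p["kPK_n"] * s["PEP_n"] * ADP_n
    R["14"] = p["kPK_g"] * s["PEP_g"] * ADP_g
    R["15f"] = p["kLDHp_n"] * s["PYR_n"] * s["NADHcyto_n"]
    R["15b"] = p["kLDHm_n"] * s["LAC_n"] * (p["N_tot"] - s["NADHcyto_n"])
    R["16f"] = p["kLDHp_g"] * s["PYR_g"] * s["NADHcyto_g"]
    R["16b"] = p["kLDHm_g"] * s["LAC_g"] * (p["N_tot"] - s["NADHcyto_g"])
    R["17f"] = carrier(p["Tmax_LAC_ne"], s["LAC_n"], p["Kt_LAC_en"])
    R["17b"] = carrier(p["Tmax_LAC_ne"], s["LAC_e"], p["Kt_LAC_en"])
    R["18f"] = carrier(p["Tmax_LAC_ge"], s["LAC_g"], p["Kt_LAC_ge"])
    R["18b"] = carrier(p["Tmax_LAC_ge"], s["LAC_e"], p["Kt_LAC_ge"])
    R["19f"] = carrier(p["Tmax_LAC_gc"], s["LAC_g"], p["Kt_LAC_gc"])
    R["19b"] = carrier(p["Tmax_LAC_gc"], s["LAC_c"], p["Kt_LAC_gc"])
    R["20f"] = carrier(p["Tmax_LAC_ec"], s["LAC_e"], p["Kt_LAC_ec"])
    R["20b"] = carrier(p["Tmax_LAC_ec"], s["LAC_c"], p["Kt_LAC_ec"])
    R["21"] = tca(p["Vmax_in_n"], s["PYR_n"], s["NADHmito_n"], p["Km_NAD_n"])
    R["22"] = etc(p["Vmax_out_n"], s["O2_n"], ADP_n, p["Km_ADP_n"],
                  s["NADHmito_n"], p["Km_NADH_n"])
    R["23"] = tca(p["Vmax_in_g"], s["PYR_g"], s["NADHmito_g"], p["Km_NAD_g"])
    R["24"] = etc(p["Vmax_out_g"], s["O2_g"], ADP_g, p["Km_ADP_g"],
                  s["NADHmito_g"], p["Km_NADH_g"])
    R["25"] = shuttle(p["T_NADH_n"], s["NADHcyto_n"], s["NADHmito_n"],
                      p["M_cyto_n"], p["M_mito_n"])
    R["26"] = shuttle(p["T_NADH_g"], s["NADHcyto_g"], s["NADHmito_g"],
                      p["M_cyto_g"], p["M_mito_g"])
    R["27f"] = p["kCKp_n"] * ADP_n * s["PCr_n"]
    R["27b"] = p["kCKm_n"] * s["ATP_n"] * (p["C_tot"] - s["PCr_n"])
    R["28f"] = p["kCKp_g"] * ADP_g * s["PCr_g"]
    R["28b"] = p["kCKm_g"] * s["ATP_g"] * (p["C_tot"] - s["PCr_g"])
    R["29"] = o2_exchange(p["PScapVn"], s["O2_n"])
    R["30"] = o2_exchange(p["PScapVg"], s["O2_g"])
    R["31"] = 2 * F / p["Vcap"] * (p["O2_a"] - s["O2_c"])
    R["32"] = 2 * F / p["Vcap"] * (p["GLC_a"] - s["GLC_c"])
    R["33"] = 2 * F / p["Vcap"] * (p["LAC_a"] - s["LAC_c"])
    R["34"] = S1 * p["JATPases_n"]
    R["35"] = S2 * p["JATPases_g"]
    R["36"] = S2 * p["Jpump0_g"]
    R["37"] = F - Fout
    R["38"] = 2 * F * (p["O2_a"] - s["O2_c"])
    R["39"] = Fout * s["dHb"] / s["Vv"]
    R["40"] = vstim_n
    R["41"] = vstim_g
    R["54"] = S1 * R["9"]
    R["55"] = S2 * R["10"]
    R["56"] = S1 * R["11"]
    R["57"] = S2 * R["12"]
    R["58"] = S1 * R["13"]
    R["59"] = S2 * R["14"]
    R["60"] = S1 * R["3"]
    R["61"] = S2 * R["4"]
    R["62"] = S1 * R["22"]
    R["63"] = S2 * R["24"]
    R["64f"] = S1 * R["27f"]
    R["64b"] = S1 * R["27b"]
    R["65f"] = S2 * R["28f"]
    R["65b"] = S2 * R["28b"]

    assert set(R) == set(LABELS)
    # Jpump0_g needed in param list for R36
    return s, R


class _Printer(PythonCodePrinter):
    def _print_Pow(self, expr):  # keep ** notation, avoid math.pow noise
        base, exp = expr.as_base_exp()
        return f"({self._print(base)})**({self._print(exp)})"


def _emit(exprs: list[sp.Expr], printer: _Printer) -> tuple[list[str], list[str]]:
    temps, reduced = sp.cse(exprs, optimizations="basic")
    lines = [f"    {sym} = {printer.doprint(e)}" for sym, e in temps]
    outs = [printer.doprint(e) for e in reduced]
    return lines, outs


def main() -> None:
    s, R = build_rate_expressions()
    states = [s[name] for name in STATE_NAMES]
    exprs = [R[lab] for lab in LABELS]
    printer = _Printer()

    rate_lines, rate_outs = _emit(exprs, printer)

    grads: list[tuple[int, int, sp.Expr]] = []
    for k, e in enumerate(exprs):
        free = e.free_symbols
        for j, st in enumerate(states):
            if st in free:
                d = sp.diff(e, st)
                if d != 0:
                    grads.append((k, j, d))
    grad_lines, grad_outs = _emit([g[2] for g in grads], printer)

    out = Path(__file__).resolve().parents[1] / "src" / "braincsp" / "_kinetics.py"
    with open(out, "w") as fh:
        fh.write('"""Generated by scripts/generate_kinetics.py -- do not edit.\n\n')
        fh.write("Unidirectional rate laws and their analytic gradients with\n")
        fh.write("respect to the state, in the canonical registry/state order.\n")
        fh.write('"""\n\n')
        fh.write("import math\n\nimport numpy as np\n\n")
        fh.write(f"N_STATES = {len(states)}\nN_REACTIONS = {len(exprs)}\n\n\n")
        fh.write("def _unpack(y, p):\n")
        fh.write(f"    ({', '.join(STATE_NAMES)}) = y\n")
        used = sorted({sym.name for e in exprs for sym in e.free_symbols
                       if sym.name in PARAM_NAMES})
        for name in used:
            fh.write(f"    {name} = p.{name}\n")
        fh.write(f"    return ({', '.join(STATE_NAMES)}), ({', '.join(used)})\n\n\n")
        fh.write("def rates(y, F, vstim_n, vstim_g, p):\n")
        fh.write('    """All 67 unidirectional rates, mM/s, registry order."""\n')
        fh.write(f"    ({', '.join(STATE_NAMES)}), ({', '.join(used)}) = _unpack(y, p)\n")
        for line in rate_lines:
            fh.write(line + "\n")
        fh.write(f"    out = np.empty({len(exprs)})\n")
        for k, e in enumerate(rate_outs):
            fh.write(f"    out[{k}] = {e}\n")
        fh.write("    return out\n\n\n")
        fh.write("def rate_gradients(y, F, vstim_n, vstim_g, p):\n")
        fh.write('    """d(rates)/d(state): dense (67, 29) array of analytic partials."""\n')
        fh.write(f"    ({', '.join(STATE_NAMES)}), ({', '.join(used)}) = _unpack(y, p)\n")
        for line in grad_lines:
            fh.write(line + "\n")
        fh.write(f"    out = np.zeros(({len(exprs)}, {len(states)}))\n")
        for (k, j, _), e in zip(grads, grad_outs):
            fh.write(f"    out[{k}, {j}] = {e}\n")
        fh.write("    return out\n")
    print(f"wrote {out} ({out.stat().st_size/1024:.1f} KiB, "
          f"{len(grads)} nonzero gradient entries)")


if __name__ == "__main__":
    main()
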