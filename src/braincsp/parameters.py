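"""Model parameters.

All kinetic, transport, vascular and bookkeeping constants of the
neuron-astrocyte energy metabolism model, with the units used throughout
the package (concentrations mM, time s, voltages mV, conductances
mS/cm^2, surface-to-volume ratios 1/cm).  In these units the sodium leak
expression SmV * gNa * (RT/F log(Nae/Na) - psi) / Faraday evaluates
directly to mM/s.

A parameter file (YAML mapping of names to numbers) can override any
subset of values; see :func:`load_parameters`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class ParameterSet:
    # --- volume fractions and ratios -------------------------------------
    Ve: float = 0.2            # extracellular volume fraction
    Vcap: float = 0.0055       # capillary volume fraction
    Vg: float = 0.25           # astrocytic volume fraction
    Vn: float = 0.45           # neuronal volume fraction
    xi: float = 0.07           # mitochondrial fraction of cell volume

    # --- membrane geometry and electrochemistry --------------------------
    SmVn: float = 2.5e4        # neuronal surface-to-volume ratio, 1/cm
    SmVg: float = 2.5e4        # astrocytic surface-to-volume ratio, 1/cm
    RT_F: float = 26.73        # thermal voltage at body temperature, mV
    Faraday: float = 9.64853e4  # C/mol
    psi_n: float = -73.59      # neuronal membrane potential, mV
    psi_g: float = -70.0       # astrocytic membrane potential, mV
    Na_e: float = 150.0        # extracellular sodium, mM

    # --- Na,K-ATPase and sodium leak -------------------------------------
    gNa_n: float = 0.0136      # mS/cm^2
    gNa_g: float = 0.0061      # mS/cm^2
    gKpas: float = 0.2035      # mS/cm^2 (unused in this scenario; kept for fidelity)
    kpump_n: float = 2.2e-6    # cm mM^-1 s^-1
    kpump_g: float = 4.5e-7    # cm mM^-1 s^-1
    Jpump0_g: float = 0.0687   # astrocytic pump offset, mM/s
    Km_pump: float = 0.5       # mM

    # --- glucose transport ------------------------------------------------
    Tmax_GLC_en: float = 0.041   # extracellular -> neuron, mM/s
    Tmax_GLC_ce: float = 0.239   # capillary -> extracellular, mM/s
    Tmax_GLC_eg: float = 0.147   # extracellular -> astrocyte, mM/s
    Tmax_GLC_cg: float = 0.0016  # capillary -> astrocyte, mM/s
    Kt_GLC_en: float = 8.0
    Kt_GLC_eg: float = 8.0
    Kt_GLC_cg: float = 8.0
    Kt_GLC_ge: float = 8.0
    # Not printed separately; every other glucose carrier Kt is 8 mM.
    Kt_GLC_ce: float = 8.0

    # --- glycolysis --------------------------------------------------------
    kHKPFK_n: float = 0.0504   # 1/s
    kHKPFK_g: float = 0.185    # 1/s
    KI_ATP: float = 1.0        # mM
    nH: float = 4.0            # Hill coefficient of ATP inhibition
    Kg: float = 0.05           # mM
    kPGK_n: float = 3.97       # mM^-1 s^-1
    kPGK_g: float = 135.2      # mM^-1 s^-1
    kPK_n: float = 36.7        # mM^-1 s^-1
    kPK_g: float = 401.7       # mM^-1 s^-1

    # --- lactate dehydrogenase and transport -------------------------------
    kLDHp_n: float = 72.3      # mM^-1 s^-1
    kLDHp_g: float = 1.59
    kLDHm_n: float = 0.72
    kLDHm_g: float = 0.071
    Tmax_LAC_gc: float = 0.00243
    Tmax_LAC_ne: float = 24.3
    Tmax_LAC_ge: float = 106.1
    Tmax_LAC_ec: float = 0.25
    Kt_LAC_en: float = 0.74
    Kt_LAC_ge: float = 3.5
    Kt_LAC_gc: float = 1.0
    Kt_LAC_ec: float = 1.0

    # --- mitochondrial metabolism -----------------------------------------
    Vmax_in_n: float = 0.1303  # TCA input, mM/s
    Vmax_in_g: float = 5.7
    Km_mito: float = 0.04      # mM
    Km_NAD_n: float = 0.409    # mM
    Km_NAD_g: float = 40.3     # mM
    Km_ADP_n: float = 3.41e-3  # mM
    Km_ADP_g: float = 0.483e-3
    Km_NADH_n: float = 4.44e-2
    Km_NADH_g: float = 2.69e-2
    KO2_mito: float = 0.001    # mM
    Vmax_out_n: float = 0.164  # electron transport chain, mM/s
    Vmax_out_g: float = 0.064

    # --- NADH shuttles ------------------------------------------------------
    M_cyto_n: float = 4.9e-8
    M_cyto_g: float = 2.5e-4
    M_mito_n: float = 3.93e5
    M_mito_g: float = 1.06e4
    T_NADH_n: float = 10330.0  # mM/s
    T_NADH_g: float = 150.0

    # --- creatine kinase ----------------------------------------------------
    C_tot: float = 10.0        # total creatine + phosphocreatine, mM
    kCKp_n: float = 0.0433     # mM^-1 s^-1
    kCKp_g: float = 0.00135
    kCKm_n: float = 0.00028
    kCKm_g: float = 1.0e-5

    # --- oxygen exchange ------------------------------------------------------
    KO2: float = 0.0361        # mM
    HbOP: float = 8.6          # mM
    nh_O2: float = 2.73        # Hill exponent of hemoglobin
    PScapVn: float = 1.66      # 1/s
    PScapVg: float = 0.87      # 1/s

    # --- arterial concentrations ----------------------------------------------
    O2_a: float = 8.35         # mM
    GLC_a: float = 4.75        # mM
    LAC_a: float = 0.506       # mM

    # --- venous balloon ----------------------------------------------------------
    tau_v: float = 35.0        # s
    alpha_v: float = 0.5
    Vv0: float = 0.02          # baseline venous volume fraction
    dHb0: float = 0.058        # baseline deoxyhemoglobin, mM

    # --- conserved pools and energy bookkeeping -----------------------------------
    # Total NAD pool.  The published table prints "212 mM", a units slip
    # (212 uM): only N = 0.212 mM is consistent with the printed resting
    # NADH concentrations of 0.006-0.12 mM.
    N_tot: float = 0.212       # mM
    A_tot: float = 2.212       # total adenine nucleotides, mM
    qAK: float = 0.92          # adenylate kinase equilibrium constant
    JATPases_n: float = 0.1695  # housekeeping ATPase offset, mM/s
    JATPases_g: float = 0.1404

    # --- hemodynamics and BOLD ----------------------------------------------------
    F0: float = 0.012          # baseline cerebral blood flow, 1/s
    k1: float = 2.22
    k2: float = 0.46
    k3: float = 0.43

    # ------------------------------------------------------------------
    # Derived volume-ratio constants used by the stoichiometric matrix.
    # c1/c2 convert per-cell-volume fluxes to per-cytosolic / mitochondrial
    # volume; r1..r5 convert between cell, extracellular and capillary
    # volumes (consistent with the published ren, reg, rce, rcn, rcg).
    @property
    def c1(self) -> float:
        return 1.0 / (1.0 - self.xi)

    @property
    def c2(self) -> float:
        return 1.0 / self.xi

    @property
    def r1(self) -> float:
        return self.Vn / self.Vcap

    @property
    def r2(self) -> float:
        return self.Vg / self.Vcap

    @property
    def r3(self) -> float:
        return self.Ve / self.Vcap

    @property
    def r4(self) -> float:
        return self.Vn / self.Ve

    @property
    def r5(self) -> float:
        return self.Vg / self.Ve

    def __post_init__(self) -> None:
        if self.Ve + self.Vcap + self.Vg + self.Vn > 1.0 + 1e-12:
            raise ValueError("volume fractions exceed unity")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name in ("psi_n", "psi_g"):
                if v >= 0:
                    raise ValueError(f"membrane potential {f.name} must be negative")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be positive, got {v}")

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def default_parameters() -> ParameterSet:
    return ParameterSet()


def load_parameters(path: str | Path | None = None) -> ParameterSet:
    """Load parameters, optionally overriding defaults from a YAML file.

    The file is a flat mapping of parameter names to numbers; unknown
    names raise ``KeyError``.
    """
    params = ParameterSet()
    if path is None:
        return params
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(overrides) - known
    if unknown:
        raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
    return params.replace(**{k: float(v) for k, v in overrides.items()})


def dump_parameters(params: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.as_dict(), fh, sort_keys=False)
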