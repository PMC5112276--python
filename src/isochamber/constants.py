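"""Physical constants and unit conversions shared across the pipeline.

All values are module-level so they can be overridden through
:class:`isochamber.config.Constants` where a run needs a different
convention (e.g. another V-PDB ratio from a later IUPAC compilation).
"""

#: 13C/12C isotope ratio of the V-PDB standard (Craig/Allison value).
R_VPDB = 0.0111802

#: Magnus saturation-vapour-pressure coefficients (hPa, dimensionless, degC).
MAGNUS_A = 6.112
MAGNUS_B = 17.62
MAGNUS_C = 243.12

#: Reference conditions for converting volumetric flow (l min^-1) to molar
#: flow (mol s^-1): 25 degC and standard sea-level pressure.
FLOW_REF_T_K = 298.15
FLOW_REF_P_PA = 101325.0

#: Ideal gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618

#: Multiplier applied to x626 + x636 to approximate total CO2 including the
#: rarer isotopologues (17O/18O substituted). Off (1.0) by default because the
#: factor cancels in concentration differences.
TOTAL_CO2_SCALE = 1.0

SECONDS_PER_DAY = 86400.0


def lpm_to_mol_s(flow_lpm: float, t_kelvin: float = FLOW_REF_T_K,
                 p_pascal: float = FLOW_REF_P_PA) -> float:
    """Convert a volumetric flow in l min^-1 to mol air s^-1 (ideal gas)."""
    m3_per_s = flow_lpm / 1000.0 / 60.0
    return m3_per_s * p_pascal / (R_GAS * t_kelvin)


def esat_hpa(t_celsius):
    """Saturation vapour pressure over water (hPa), Magnus form."""
    import numpy as np

    t = np.asarray(t_celsius, dtype=float)
    out = MAGNUS_A * np.exp(MAGNUS_B * t / (MAGNUS_C + t))
    return out if out.ndim else float(out)
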