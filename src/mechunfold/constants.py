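"""Physical constants and unit conversions.

Internal unit policy: lengths in nm, times in ns, forces in pN,
energies in kcal/mol (per-molecule mechanical energies in pN·nm).
All conversions live here and in the readers/writers; the analysis
code never converts units.
"""

#: pN per kJ/(mol·nm): 1e3 J / N_A / 1e-9 m expressed in pN (1/N_A scaling).
#: GROMACS pull forces are printed in kJ/(mol·nm); a spring constant of
#: 500 kJ/(mol·nm²) is therefore ≈ 830 pN/nm.
KJ_PER_MOL_NM_TO_PN = 1.6605390

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K expressed in pN·nm).
KB_PN_NM_PER_K = 0.0138065

#: Gas constant in kcal/(mol·K) — molar Boltzmann constant.
KB_KCAL_PER_MOL_K = 0.0019872

#: ps → ns
PS_TO_NS = 1e-3

#: Å → nm
ANGSTROM_TO_NM = 0.1

#: Default simulation temperature (thermostat), K.
DEFAULT_TEMPERATURE = 300.0


def kt_pn_nm(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in pN·nm (4.142 pN·nm at 300 K)."""
    return KB_PN_NM_PER_K * temperature


def kt_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in kcal/mol (0.59616 kcal/mol at 300 K)."""
    return KB_KCAL_PER_MOL_K * temperature


def gmx_spring_to_pn_per_nm(k_kj_mol_nm2: float) -> float:
    """Convert a spring constant from kJ/(mol·nm²) to pN/nm."""
    return k_kj_mol_nm2 * KJ_PER_MOL_NM_TO_PN
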