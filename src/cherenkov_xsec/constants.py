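"""Physical constants, nuclide data and stock material definitions.

Units project-wide: depths in cm, energies in MeV, times in s, densities in
g/cm^3, cross sections in mbarn (1 mbarn = 1e-27 cm^2) unless stated.
"""

from __future__ import annotations

# -- fundamental constants (CODATA) -----------------------------------------
PROTON_MASS_MEV = 938.27208816      # proton rest energy
ELECTRON_MASS_MEV = 0.51099895      # electron rest energy
AVOGADRO = 6.02214076e23            # 1/mol
ELEMENTARY_CHARGE_C = 1.602176634e-19
FINE_STRUCTURE = 7.2973525693e-3

# Bethe prefactor K = 4 pi N_A r_e^2 m_e c^2  [MeV cm^2 / mol]
K_BETHE = 0.307075
# Bohr straggling prefactor K * m_e c^2  [MeV^2 cm^2 / mol]
K_BOHR = K_BETHE * ELECTRON_MASS_MEV

MBARN_CM2 = 1e-27
BARN_CM2 = 1e-24

# -- elements: Z, standard atomic weight (g/mol) -----------------------------
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Si": (14, 28.085),
}

# -- positron emitters produced from oxygen (and the fast 14O nuisance) ------
# half-lives: evaluated nuclear data; endpoint energies: maximum beta+ kinetic
# energy of the dominant branch; branching: beta+ fraction.
NUCLIDE_DATA: dict[str, dict] = {
    "15O": {"half_life_s": 122.2, "positron_endpoint_mev": 1.732, "branching_ratio": 0.999},
    "13N": {"half_life_s": 597.9, "positron_endpoint_mev": 1.199, "branching_ratio": 0.998},
    "11C": {"half_life_s": 1222.0, "positron_endpoint_mev": 0.960, "branching_ratio": 0.998},
    # 14O decays almost entirely before the 120 s analysis window opens and is
    # excluded by default; available as a nuisance component.
    "14O": {"half_life_s": 70.62, "positron_endpoint_mev": 1.808, "branching_ratio": 0.999},
}

# -- stock materials ---------------------------------------------------------
# mean excitation energies: ICRU values.  SiO2 density: synthetic fused
# quartz standard.  Refractive indices at visible wavelengths.
MATERIAL_DATA: dict[str, dict] = {
    "water": {
        "density": 1.000,
        "composition": [("H", 2), ("O", 1)],
        "mean_excitation_energy_ev": 75.0,
        "refractive_index": 1.333,
    },
    "quartz": {
        "density": 2.20,
        "composition": [("Si", 1), ("O", 2)],
        "mean_excitation_energy_ev": 139.2,
        "refractive_index": 1.458,
    },
    "polyethylene": {
        "density": 0.94,
        "composition": [("C", 1), ("H", 2)],
        "mean_excitation_energy_ev": 57.4,
        "refractive_index": 1.51,
    },
}

# Default per-formula-unit proton removal cross sections (barn) used by the
# flux-attenuation correction: the sum of nonelastic nuclear cross sections of
# the constituent nuclei near 70 MeV.  Gives ~1 %/cm in water.
DEFAULT_REMOVAL_BARN: dict[str, float] = {
    "water": 0.30,         # O ~0.30 b (H negligible below pion threshold)
    "quartz": 1.04,        # Si ~0.44 b + 2 O
    "polyethylene": 0.21,  # C ~0.21 b
}
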