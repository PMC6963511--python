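"""Element parameter tables used by the charge and surface descriptors.

Values are fixed constants of the published schemes; changing them changes
the meaning of every electrostatic descriptor, so they are code, not config.
"""

# Sanderson electronegativities (SR scale), dimensionless.
SANDERSON_EN: dict[str, float] = {
    "H": 2.592,
    "Li": 0.670,
    "Be": 1.810,
    "B": 2.275,
    "C": 2.746,
    "N": 3.194,
    "O": 3.654,
    "F": 4.000,
    "Na": 0.560,
    "Mg": 1.318,
    "Al": 1.714,
    "Si": 2.138,
    "P": 2.515,
    "S": 2.957,
    "Cl": 3.475,
    "K": 0.445,
    "Br": 3.219,
    "I": 2.778,
}

# Bondi van der Waals radii in Angstrom.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "Br": 1.85,
    "Kr": 2.02,
    "I": 1.98,
    "Xe": 2.16,
}

# Fallback radius for elements missing from the Bondi table.
DEFAULT_VDW_RADIUS = 1.70

# Empirical scaling constant of the Zefirov/Sanderson one-shot charge formula.
ZEFIROV_SCALE = 2.08
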