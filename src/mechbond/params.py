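"""Element tables and nonbonded constants used across the package.

Units are fixed package-wide: Å, ns, pN, kcal/mol, degrees, elementary
charges and atomic mass units.
"""

from __future__ import annotations

#: Coulomb constant in kcal·Å·mol⁻¹·e⁻², the MD-community convention.
COULOMB_K = 332.0636

#: van der Waals radii (Å), Bondi-style element-keyed table used by the
#: Shrake–Rupley solvent-accessible-surface quadrature.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "FE": 1.40,
    "CA": 2.31,
}

#: Atomic masses (amu) for mass-centre computations.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "ZN": 65.38,
    "FE": 55.845,
    "CA": 40.078,
}

#: Default per-atom-name nonbonded parameters for the synthetic glycine-like
#: residues: (partial charge e, LJ well depth kcal/mol, LJ rmin/2 Å).
#: Values follow the additive protein force-field backbone conventions so the
#: interface-energy stage produces chemically sensible magnitudes.
BACKBONE_NONBONDED: dict[str, tuple[float, float, float]] = {
    "N": (-0.47, 0.20, 1.85),
    "H": (0.31, 0.046, 0.2245),
    "CA": (0.07, 0.055, 2.175),
    "C": (0.51, 0.11, 2.00),
    "O": (-0.51, 0.12, 1.70),
}


def vdw_radius(element: str) -> float:
    """Look up the van der Waals radius for an element symbol.

    Raises ``KeyError``-free, domain-specific errors at the call sites; this
    helper only normalises the symbol.
    """
    return VDW_RADII[element.upper()]


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES[element.upper()]
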