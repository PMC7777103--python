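"""Physical constants and unit conversions used throughout the package.

Internal conventions: lengths in Å, times in ps, frequencies in cm⁻¹,
charges in elementary charge e, energies in kcal/mol or kT as stated.
"""

#: speed of light in cm/ps (converts wavenumber ν [cm⁻¹] to frequency ν·c [1/ps])
C_CM_PER_PS = 0.0299792458

#: Boltzmann constant in kcal/(mol·K)
KB_KCAL_MOL_K = 0.0019872043

#: Coulomb energy prefactor: q1*q2/r with q in e, r in Å -> kcal/mol
COULOMB_KCAL = 332.06

#: electric field of a point charge: q/r^2 with q in e, r in Å -> V/Å
EFIELD_V_PER_A = 14.3996

#: V/Å expressed in MV/cm
V_PER_A_TO_MV_PER_CM = 100.0

#: field–bond-dipole energy factor: μ [Debye] × E [MV/cm] -> kcal/mol
FIELD_DIPOLE_KCAL_FACTOR = 0.048

#: ambient liquid water number density, molecules/Å³
BULK_WATER_DENSITY = 0.0334

#: bulk water molarity (mol/L) used for per-molecule spectral scaling
BULK_WATER_MOLARITY = 55.35


def sphere_volume(radius: float) -> float:
    """Volume of a sphere of the given radius (Å -> Å³)."""
    from math import pi

    return 4.0 / 3.0 * pi * radius**3
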