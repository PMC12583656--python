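"""Internal unit system of the patchy-particle simulator.

Length is measured in Angstrom, time in femtoseconds, and energy in units
of k_B T at the reference temperature 300 K.  The derived mass unit is

    M0 = E0 * t0^2 / L0^2 = 4.141947e-31 kg,

so an 18 kDa enzyme weighs ~7.2e7 M0 and thermal velocities are a few
1e-4 A/fs, comfortably resolved by the 30 fs default timestep.  Stokes
drags (6*pi*eta*a translational, 8*pi*eta*a^3 rotational) convert from SI
with the factors below.
"""

KB = 1.380649e-23          # J/K
T_REF = 300.0              # K
E0 = KB * T_REF            # J            (= 1 energy unit)
L0 = 1e-10                 # m            (= 1 A)
T0 = 1e-15                 # s            (= 1 fs)
M0 = E0 * T0**2 / L0**2    # kg           (= 1 mass unit)
AMU = 1.66053906660e-27    # kg

#: drag conversion: (kg/s) -> (M0/fs)
DRAG_SI = M0 / T0
#: rotational drag conversion: (kg m^2/s) -> (M0 A^2/fs)
RDRAG_SI = M0 * L0**2 / T0

AVOGADRO = 6.02214076e23


def mass_from_da(daltons: float) -> float:
    """Particle mass in simulation units from molecular weight in Da."""
    return daltons * AMU / M0


def stokes_drag(viscosity_pa_s: float, radius_angstrom: float) -> float:
    """Translational Stokes drag 6*pi*eta*a in simulation units (M0/fs)."""
    import math
    return 6.0 * math.pi * viscosity_pa_s * (radius_angstrom * L0) / DRAG_SI


def stokes_rotational_drag(viscosity_pa_s: float, radius_angstrom: float) -> float:
    """Rotational Stokes drag 8*pi*eta*a^3 in simulation units (M0 A^2/fs)."""
    import math
    return 8.0 * math.pi * viscosity_pa_s * (radius_angstrom * L0) ** 3 / RDRAG_SI


def box_side_from_concentration(copies: int, molar: float) -> float:
    """Cubic box side (A) holding `copies` particles at `molar` mol/L."""
    if copies < 1 or molar <= 0:
        raise ValueError("need copies >= 1 and molar > 0")
    volume_l = copies / (AVOGADRO * molar)        # litres
    volume_a3 = volume_l * 1e27                    # 1 L = 1e27 A^3
    return volume_a3 ** (1.0 / 3.0)
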