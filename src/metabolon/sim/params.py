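"""Parameters of the patchy-particle reaction-diffusion model.

Each enzyme is a rigid sphere (diameter 20 A) carrying two small patches
(diameter 8 A): a PPI patch whose identity is the enzyme type, and an
active-site patch whose identity is the substrate state it converts.
Ligands are 8 A spheres carrying a chemical state S_0..S_9 or the absorbing
product P.  Nonspecific excluded volume and weak stickiness are
Lennard-Jones (eps 0.8 kT); specific binding is a Morse well: PPI
patch-patch with alpha 2.2 /A, r0 17.056 A, cutoff 20 A and depth taken
from the fluorescence matrix via a stepwise MFI -> K_D map, and cognate
active-site/ligand binding with alpha 1 /A, r0 12.7 A, capture 2.5 A and
depth 5 kT.  Per-attempt reaction probabilities derive from catalytic
efficiencies sampled as log10(kcat/KM) ~ Normal(5, 1), normalized by the
diffusion limit 1e8 /M/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import units


@dataclass(frozen=True)
class SpeciesSpec:
    n_types: int = 10
    sigma_enz: float = 20.0        # core diameter, A
    sigma_patch: float = 8.0       # patch diameter, A
    sigma_ligand: float = 8.0      # ligand diameter, A
    patch_offset: float = 2.7      # patch displacement from core center, A
    enzyme_mass_da: float = 18_000.0
    ligand_mass_da: float = 300.0

    @property
    def core_radius(self) -> float:
        return self.sigma_enz / 2.0


@dataclass(frozen=True)
class LJParams:
    epsilon: float = 0.8           # kT
    sigma: float = 20.0            # contact distance = sum of radii, A

    def __post_init__(self):
        if self.epsilon < 0 or self.sigma <= 0:
            raise ValueError("epsilon must be >= 0 and sigma > 0")

    @property
    def r_c(self) -> float:
        return 2.5 * self.sigma


@dataclass(frozen=True)
class MorseParams:
    de: float                      # well depth, kT
    alpha: float                   # stiffness, 1/A
    r0: float                      # equilibrium distance, A
    cutoff: float                  # A
    capture_range: float           # bond-formation window beyond r0, A

    def __post_init__(self):
        if self.de < 0 or self.alpha <= 0 or self.cutoff < self.r0:
            raise ValueError("need de >= 0, alpha > 0, cutoff >= r0")


#: PPI patch-patch Morse (depth set per pair from the fluorescence matrix)
PPI_MORSE = MorseParams(de=0.0, alpha=2.2, r0=17.056, cutoff=20.0, capture_range=2.8)
#: cognate active-site / ligand Morse
COGNATE_MORSE = MorseParams(de=5.0, alpha=1.0, r0=12.7, cutoff=12.7 + 2.5,
                            capture_range=2.5)


def lj_energy(r: float, params: LJParams) -> float:
    """Truncated-and-shifted Lennard-Jones energy (kT) at separation r (A)."""
    if r <= 0:
        raise ValueError("r must be positive")
    if r >= params.r_c:
        return 0.0
    sr6 = (params.sigma / r) ** 6
    src6 = (params.sigma / params.r_c) ** 6
    return 4.0 * params.epsilon * ((sr6 * sr6 - sr6) - (src6 * src6 - src6))


def lj_energy_unshifted(r: float, params: LJParams) -> float:
    if r <= 0:
        raise ValueError("r must be positive")
    sr6 = (params.sigma / r) ** 6
    return 4.0 * params.epsilon * (sr6 * sr6 - sr6)


def morse_energy(r: float, params: MorseParams) -> float:
    """Truncated-and-shifted Morse energy (kT) at separation r (A)."""
    if r < 0:
        raise ValueError("r must be >= 0")
    if r >= params.cutoff:
        return 0.0
    return morse_energy_unshifted(r, params) - morse_energy_unshifted(params.cutoff, params)


def morse_energy_unshifted(r: float, params: MorseParams) -> float:
    x = r - params.r0
    return params.de * (math.exp(-2.0 * params.alpha * x)
                        - 2.0 * math.exp(-params.alpha * x))


# ---------------------------------------------------------------------------
# fluorescence -> binding energetics

def kd_from_mfi(mfi: float) -> float:
    """Stepwise dissociation constant (M) from mean fluorescence intensity."""
    if mfi < 0:
        raise ValueError("mfi must be >= 0")
    if mfi > 1000.0:
        return 1e-5        # 10 uM
    if mfi > 800.0:
        return 2e-4        # 200 uM
    if mfi > 650.0:
        return 5e-4        # 500 uM
    return 0.1             # 100 mM


def de_from_kd(kd: float, reference: float = 1.0) -> float:
    """Morse well depth (kT) from K_D: |ln(K_D / 1 M)| magnitude convention."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    return abs(math.log(kd / reference))


@dataclass
class PPIEnergyMap:
    """Symmetric per-type-pair PPI well depths (kT) derived from MFI."""

    de: np.ndarray                 # (n_types, n_types)
    kd: np.ndarray | None = None   # (n_types, n_types), M

    def __post_init__(self):
        self.de = np.asarray(self.de, dtype=float)
        if self.de.ndim != 2 or self.de.shape[0] != self.de.shape[1]:
            raise ValueError("de must be square")
        if not np.allclose(self.de, self.de.T):
            raise ValueError("de must be symmetric")
        if (self.de < 0).any():
            raise ValueError("well depths must be >= 0")

    @classmethod
    def from_mfi(cls, mfi: np.ndarray) -> "PPIEnergyMap":
        mfi = np.asarray(mfi, dtype=float)
        kd = np.vectorize(kd_from_mfi)(mfi)
        de = np.vectorize(de_from_kd)(kd)
        return cls(de=de, kd=kd)

    @classmethod
    def from_matrix(cls, matrix, proteins) -> "PPIEnergyMap":
        """From a PPIMatrix restricted to an ordered 10-protein pathway list."""
        n = len(proteins)
        mfi = np.zeros((n, n))
        for i, a in enumerate(proteins):
            for j, b in enumerate(proteins):
                mfi[i, j] = 0.0 if matrix.is_missing(a, b) else matrix.value(a, b)
        mfi = np.maximum(mfi, mfi.T)
        return cls.from_mfi(mfi)

    def zeroed(self) -> "PPIEnergyMap":
        """PPI-off control: all patch-patch depths set to zero."""
        return PPIEnergyMap(de=np.zeros_like(self.de), kd=self.kd)


# ---------------------------------------------------------------------------
# reactions

@dataclass
class ReactionScheme:
    """Sequential cascade S_0 -> S_1 -> ... -> S_9 -> P.

    ``eta`` are diffusion-limit-normalized catalytic efficiencies; the
    per-timestep attempt probability is min(scale * eta, 1).
    """

    eta: np.ndarray
    p_scale: float = 1.0

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        if (self.eta < 0).any():
            raise ValueError("efficiencies must be >= 0")

    @property
    def n_reactions(self) -> int:
        return len(self.eta)

    @property
    def p_react(self) -> np.ndarray:
        return np.minimum(self.p_scale * self.eta, 1.0)

    @classmethod
    def sample(cls, seed=None, n_reactions: int = 10,
               log10_mean: float = 5.0, log10_sd: float = 1.0,
               diffusion_limit: float = 1e8, p_scale: float = 1.0) -> "ReactionScheme":
        rng = np.random.default_rng(seed)
        log10_kcat_km = rng.normal(log10_mean, log10_sd, size=n_reactions)
        eta = 10.0 ** log10_kcat_km / diffusion_limit
        return cls(eta=np.minimum(eta, 1.0), p_scale=p_scale)


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class LangevinConfig:
    """Langevin/Brownian run settings.

    ``concentration`` is molar per enzyme type and, with
    ``copies_per_type``, fixes the cubic box side.  The published-scale
    settings (300 copies/type at 50 uM, 10 us, viscosity 1e-3 Pa s) are
    cluster-scale; :func:`desk_config` returns the scaled-down defaults
    used by the analysis scripts and tests.
    """

    temperature: float = 300.0         # K
    viscosity: float = 1e-3            # Pa s
    dt: float = 30.0                   # fs
    copies_per_type: int = 300
    concentration: float = 50e-6       # M per enzyme type
    ligand_factor: float = 3.0         # ligands per enzyme
    n_steps: int = 2_000_000
    confine_frac: float = 0.1
    confinement_radius: float | str = "auto"   # A; 'auto' keeps published density
    confine_ligands: bool = True
    confinement_k: float = 0.5         # kT/A^2 harmonic wall
    integrator: str = "langevin"       # or 'brownian'
    n_replicas: int = 5
    seed: int = 0
    record_interval: int = 500
    frame_interval: int = 2000
    force_cap: float = 1000.0          # kT/A numerical guard on site forces

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.integrator not in ("langevin", "brownian"):
            raise ValueError("integrator must be 'langevin' or 'brownian'")

    @property
    def kt(self) -> float:
        return self.temperature / units.T_REF

    def box_side(self) -> float:
        return units.box_side_from_concentration(self.copies_per_type,
                                                 self.concentration)

    def resolve_confinement_radius(self, n_enzymes: int) -> float:
        side = self.box_side()
        if self.confinement_radius == "auto":
            # keep the published enzyme number density: 3000 enzymes / 400 A sphere
            radius = 400.0 * (n_enzymes / 3000.0) ** (1.0 / 3.0)
        else:
            radius = float(self.confinement_radius)
        return min(radius, 0.45 * side)


def desk_config(**overrides) -> LangevinConfig:
    """Scaled-down configuration resolvable on a single CPU in minutes.

    Six copies per enzyme type at 0.5 mM per type (box side ~272 A), two
    ligands per enzyme, Brownian propagation at the published 30 fs step
    with viscosity 1e-4 Pa s.  The reduced viscosity uniformly speeds
    diffusion in both the PPI-on and PPI-off arms; only ratios between the
    two arms are interpreted.
    """
    cfg = LangevinConfig(
        viscosity=1e-4,
        copies_per_type=6,
        concentration=5e-4,
        ligand_factor=2.0,
        n_steps=80_000,
        confine_frac=0.15,
        integrator="brownian",
        record_interval=500,
        frame_interval=2000,
    )
    return replace(cfg, **overrides)


def flux_desk_config(**overrides) -> LangevinConfig:
    """Desk-scale conditions for the paired PPI-on / PPI-off flux experiment.

    Three copies per enzyme type at the published 50 uM per-type
    concentration (box side ~464 A), three ligands per enzyme, 6e5 Brownian
    steps of 15 fs at viscosity 1e-4 Pa s, with the first 10% of steps
    confined to a 50 A nucleation sphere.  The run must (i) resolve the
    narrow PPI Morse well (per-step noise below the 1/alpha = 0.45 A well
    width), (ii) outlive the evaporation of the monomeric control's initial
    blob, and (iii) keep bulk enzyme spacing large enough that sequential
    intermediate hand-off is diffusion-starved outside clusters; these
    settings are the smallest that satisfy all three.
    """
    cfg = desk_config(copies_per_type=3, concentration=5e-5, n_steps=600_000,
                      dt=15.0, confine_frac=0.1, confinement_radius=50.0,
                      ligand_factor=3.0)
    return replace(cfg, **overrides)


#: uniform upward rescale of the per-attempt reaction probabilities used in
#: desk-scale flux runs (reported in run parameters; only on/off flux
#: ratios are interpreted, which the common factor leaves invariant)
FLUX_DESK_P_SCALE = 50.0
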