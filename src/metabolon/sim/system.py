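"""Patchy-particle system state and construction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .params import LangevinConfig, PPIEnergyMap, SpeciesSpec


def random_rotation_matrices(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotations via quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    mats = np.empty((n, 3, 3))
    mats[:, 0, 0] = 1 - 2 * (y * y + z * z)
    mats[:, 0, 1] = 2 * (x * y - z * w)
    mats[:, 0, 2] = 2 * (x * z + y * w)
    mats[:, 1, 0] = 2 * (x * y + z * w)
    mats[:, 1, 1] = 1 - 2 * (x * x + z * z)
    mats[:, 1, 2] = 2 * (y * z - x * w)
    mats[:, 2, 0] = 2 * (x * z - y * w)
    mats[:, 2, 1] = 2 * (y * z + x * w)
    mats[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return mats


def rotate_matrices(rot: np.ndarray, omega: np.ndarray, dt: float) -> None:
    """Left-multiply each rotation matrix by the rotation omega*dt (Rodrigues)."""
    theta = np.linalg.norm(omega, axis=1) * dt
    mask = theta > 1e-12
    if not mask.any():
        return
    axis = np.zeros_like(omega)
    axis[mask] = omega[mask] / np.linalg.norm(omega[mask], axis=1, keepdims=True)
    k = axis[mask]
    th = theta[mask]
    kx = np.zeros((mask.sum(), 3, 3))
    kx[:, 0, 1], kx[:, 0, 2] = -k[:, 2], k[:, 1]
    kx[:, 1, 0], kx[:, 1, 2] = k[:, 2], -k[:, 0]
    kx[:, 2, 0], kx[:, 2, 1] = -k[:, 1], k[:, 0]
    eye = np.eye(3)[None, :, :]
    r_inc = (eye + np.sin(th)[:, None, None] * kx
             + (1 - np.cos(th))[:, None, None] * (kx @ kx))
    rot[mask] = r_inc @ rot[mask]


@dataclass
class PatchySystem:
    """Full mutable simulation state.

    Enzyme ``i`` has type ``enz_type[i]``; its PPI patch sits at
    ``pos + rot[:, :, 2] * offset`` and the active-site patch at the
    antipode.  Ligand states run 0..9 (substrate/intermediates) with 10 the
    absorbing product.  ``ppi_partner`` / ``lig_bound`` carry the
    single-valent bond bookkeeping (-1 = free).
    """

    species: SpeciesSpec
    energy: PPIEnergyMap
    box: float
    pos: np.ndarray           # (n_enz, 3)
    vel: np.ndarray
    rot: np.ndarray           # (n_enz, 3, 3)
    angvel: np.ndarray        # (n_enz, 3)
    enz_type: np.ndarray      # (n_enz,)
    lig_pos: np.ndarray       # (n_lig, 3)
    lig_vel: np.ndarray
    lig_state: np.ndarray     # (n_lig,)
    ppi_partner: np.ndarray   # (n_enz,)
    lig_bound: np.ndarray     # (n_lig,)
    reaction_counts: np.ndarray   # (n_reactions,)
    time_fs: float = 0.0
    pos_unwrapped: np.ndarray | None = None
    lig_pos_unwrapped: np.ndarray | None = None

    def __post_init__(self):
        if self.pos_unwrapped is None:
            self.pos_unwrapped = self.pos.copy()
        if self.lig_pos_unwrapped is None:
            self.lig_pos_unwrapped = self.lig_pos.copy()

    @property
    def n_enzymes(self) -> int:
        return len(self.pos)

    @property
    def n_ligands(self) -> int:
        return len(self.lig_pos)

    def patch_positions(self):
        """PPI and active-site patch coordinates (each (n_enz, 3))."""
        axis = self.rot[:, :, 2] * self.species.patch_offset
        return self.pos + axis, self.pos - axis

    def copy(self) -> "PatchySystem":
        return PatchySystem(
            species=self.species, energy=self.energy, box=self.box,
            pos=self.pos.copy(), vel=self.vel.copy(), rot=self.rot.copy(),
            angvel=self.angvel.copy(), enz_type=self.enz_type.copy(),
            lig_pos=self.lig_pos.copy(), lig_vel=self.lig_vel.copy(),
            lig_state=self.lig_state.copy(), ppi_partner=self.ppi_partner.copy(),
            lig_bound=self.lig_bound.copy(),
            reaction_counts=self.reaction_counts.copy(), time_fs=self.time_fs,
            pos_unwrapped=self.pos_unwrapped.copy(),
            lig_pos_unwrapped=self.lig_pos_unwrapped.copy(),
        )


def _place_in_sphere(n: int, radius: float, center: np.ndarray, min_dist: float,
                     rng: np.random.Generator, max_tries: int = 200_000,
                     obstacles: np.ndarray | None = None,
                     obstacle_dist: float = 0.0):
    placed = np.empty((n, 3))
    count = 0
    tries = 0
    min2 = min_dist * min_dist
    obs2 = obstacle_dist * obstacle_dist
    while count < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} particles with spacing {min_dist} A in a "
                f"{radius} A sphere; packing fraction too high")
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = radius * rng.random() ** (1.0 / 3.0)
        cand = center + u * r
        if count and ((placed[:count] - cand) ** 2).sum(axis=1).min() < min2:
            continue
        if obstacles is not None and len(obstacles) and \
                ((obstacles - cand) ** 2).sum(axis=1).min() < obs2:
            continue
        placed[count] = cand
        count += 1
    return placed


def build_system(species: SpeciesSpec, energy: PPIEnergyMap,
                 config: LangevinConfig, rng: np.random.Generator,
                 n_reactions: int = 10) -> PatchySystem:
    """Place enzymes (and ligands) in the confinement sphere, draw
    Maxwell-Boltzmann velocities, and initialize bond/reaction state."""
    n_enz = species.n_types * config.copies_per_type
    n_lig = int(round(config.ligand_factor * n_enz))
    box = config.box_side()
    r_conf = config.resolve_confinement_radius(n_enz)
    center = np.full(3, box / 2.0)

    pos = _place_in_sphere(n_enz, max(r_conf - species.core_radius, species.core_radius),
                           center, species.sigma_enz, rng)
    lig_radius = r_conf if config.confine_ligands else box / 2.0
    if n_lig:
        clearance = 0.95 * (species.core_radius + species.sigma_ligand / 2.0)
        lig_pos = _place_in_sphere(
            n_lig, lig_radius, center, 0.95 * species.sigma_ligand, rng,
            obstacles=pos, obstacle_dist=clearance)
        lig_pos %= box
    else:
        lig_pos = np.empty((0, 3))

    kt = config.kt
    m_enz = units.mass_from_da(species.enzyme_mass_da)
    m_lig = units.mass_from_da(species.ligand_mass_da)
    inertia = 0.4 * m_enz * species.core_radius ** 2
    vel = rng.normal(0.0, np.sqrt(kt / m_enz), size=(n_enz, 3))
    angvel = rng.normal(0.0, np.sqrt(kt / inertia), size=(n_enz, 3))
    lig_vel = rng.normal(0.0, np.sqrt(kt / m_lig), size=(n_lig, 3))

    return PatchySystem(
        species=species, energy=energy, box=box,
        pos=pos % box, vel=vel,
        rot=random_rotation_matrices(n_enz, rng), angvel=angvel,
        enz_type=np.repeat(np.arange(species.n_types), config.copies_per_type),
        lig_pos=lig_pos, lig_vel=lig_vel,
        lig_state=np.zeros(n_lig, dtype=np.int64),
        ppi_partner=np.full(n_enz, -1, dtype=np.int64),
        lig_bound=np.full(n_lig, -1, dtype=np.int64),
        reaction_counts=np.zeros(n_reactions, dtype=np.int64),
    )
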