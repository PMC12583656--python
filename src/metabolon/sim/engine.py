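"""Langevin / Brownian propagation of the patchy-particle system.

The equation of motion is m r'' = F_c - gamma v + F_r with conservative
forces from the pair potentials, Stokes drag gamma = 6*pi*eta*a and
fluctuation-dissipation-consistent noise <F_r F_r'> = 2 gamma kT delta.
(The published expression for the damping coefficient, kT/(6*pi*eta*a), is
dimensionally a diffusion coefficient; drag units are required here, and
the two agree through D = kT/gamma.)  Translation uses the BAOAB splitting,
which reduces to velocity Verlet when the thermostat is off; rotation of
the rigid enzyme frames integrates the angular velocity with the scalar
moment of inertia of the core sphere and rotational drag 8*pi*eta*a^3.  An
overdamped Brownian integrator (r += D F dt / kT + sqrt(2 D dt) xi) is the
faster desk-scale alternative.

PPI patch-patch attraction acts pairwise between all patches within the
20 A cutoff; patch valence is limited geometrically by the steep Morse
inner wall and core excluded volume (the `ppi_valence` diagnostic reports
it), with the nearest in-range partner tracked per patch for analysis.
Active sites are strictly single-valent by explicit bookkeeping: one
cognate ligand per site, captured and released at r0 + 2.5 A.  A bound
ligand in state S_k on an enzyme of type k advances to S_{k+1} with
probability p_react[k] per timestep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from . import units
from .params import (COGNATE_MORSE, PPI_MORSE, LangevinConfig, PPIEnergyMap,
                     ReactionScheme, SpeciesSpec)
from .system import PatchySystem, build_system, rotate_matrices

PRODUCT_STATE = 10


@dataclass
class Forcefield:
    """Scalars and tables consumed by the force kernel."""

    eps_pp: float
    eps_pl: float
    eps_nc: float
    sigma_core: float
    sigma_core_lig: float
    sigma_patch_lig: float
    de_ppi: np.ndarray
    m_enz: float
    m_lig: float
    inertia: float
    gamma_enz: float
    gamma_lig: float
    gamma_rot: float

    @classmethod
    def build(cls, species: SpeciesSpec, energy: PPIEnergyMap,
              config: LangevinConfig) -> "Forcefield":
        a_enz = species.core_radius
        a_lig = species.sigma_ligand / 2.0
        return cls(
            eps_pp=0.8, eps_pl=0.8, eps_nc=0.8,
            sigma_core=species.sigma_enz,
            sigma_core_lig=species.core_radius + a_lig,
            sigma_patch_lig=species.sigma_patch / 2.0 + a_lig,
            de_ppi=np.ascontiguousarray(energy.de),
            m_enz=units.mass_from_da(species.enzyme_mass_da),
            m_lig=units.mass_from_da(species.ligand_mass_da),
            inertia=0.4 * units.mass_from_da(species.enzyme_mass_da) * a_enz ** 2,
            gamma_enz=units.stokes_drag(config.viscosity, a_enz),
            gamma_lig=units.stokes_drag(config.viscosity, a_lig),
            gamma_rot=units.stokes_rotational_drag(config.viscosity, a_enz),
        )


@njit(cache=True)
def _min_image(d, box):
    return d - box * np.round(d / box)


@njit(cache=True)
def _lj_shift(eps, sigma, rc):
    sr6 = (sigma / rc) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6)


@njit(cache=True)
def _morse_shift(de, alpha, r0, rc):
    x = rc - r0
    return de * (math.exp(-2.0 * alpha * x) - 2.0 * math.exp(-alpha * x))


@njit(cache=True)
def _pair_forces(pos, ppi_pos, act_pos, lig_pos, enz_type, lig_state,
                 ppi_partner, lig_bound, box,
                 eps_pp, eps_pl, eps_nc, sigma_core, sigma_cl, sigma_pl,
                 de_ppi, ppi_alpha, ppi_r0, ppi_rc,
                 cog_de, cog_alpha, cog_r0, cog_rc, force_cap,
                 f_core, f_ppi, f_act, f_lig):
    """Accumulate pair forces; returns total potential energy (kT)."""
    n_enz = pos.shape[0]
    n_lig = lig_pos.shape[0]
    energy = 0.0

    rc_core = 2.5 * sigma_core
    rc_cl = 2.5 * sigma_cl
    rc_pl = 2.5 * sigma_pl
    sh_core = _lj_shift(eps_pp, sigma_core, rc_core)
    sh_cl = _lj_shift(eps_pl, sigma_cl, rc_cl)
    sh_pl = _lj_shift(eps_nc, sigma_pl, rc_pl)
    sh_ll = sh_pl
    sh_ppi_base = _morse_shift(1.0, ppi_alpha, ppi_r0, ppi_rc)
    sh_cog = _morse_shift(cog_de, cog_alpha, cog_r0, cog_rc)

    # core-core LJ
    for i in range(n_enz):
        for j in range(i + 1, n_enz):
            dx = _min_image(pos[i, 0] - pos[j, 0], box)
            dy = _min_image(pos[i, 1] - pos[j, 1], box)
            dz = _min_image(pos[i, 2] - pos[j, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc_core * rc_core:
                continue
            r = math.sqrt(r2)
            sr6 = (sigma_core / r) ** 6
            energy += 4.0 * eps_pp * (sr6 * sr6 - sr6) - sh_core
            fs = 24.0 * eps_pp * (2.0 * sr6 * sr6 - sr6) / r
            if fs > force_cap:
                fs = force_cap
            elif fs < -force_cap:
                fs = -force_cap
            fx, fy, fz = fs * dx / r, fs * dy / r, fs * dz / r
            f_core[i, 0] += fx; f_core[i, 1] += fy; f_core[i, 2] += fz
            f_core[j, 0] -= fx; f_core[j, 1] -= fy; f_core[j, 2] -= fz

    # core-ligand LJ
    for i in range(n_enz):
        for l in range(n_lig):
            dx = _min_image(pos[i, 0] - lig_pos[l, 0], box)
            dy = _min_image(pos[i, 1] - lig_pos[l, 1], box)
            dz = _min_image(pos[i, 2] - lig_pos[l, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc_cl * rc_cl:
                continue
            r = math.sqrt(r2)
            sr6 = (sigma_cl / r) ** 6
            energy += 4.0 * eps_pl * (sr6 * sr6 - sr6) - sh_cl
            fs = 24.0 * eps_pl * (2.0 * sr6 * sr6 - sr6) / r
            if fs > force_cap:
                fs = force_cap
            elif fs < -force_cap:
                fs = -force_cap
            fx, fy, fz = fs * dx / r, fs * dy / r, fs * dz / r
            f_core[i, 0] += fx; f_core[i, 1] += fy; f_core[i, 2] += fz
            f_lig[l, 0] -= fx; f_lig[l, 1] -= fy; f_lig[l, 2] -= fz

    # ligand-ligand LJ
    for i in range(n_lig):
        for j in range(i + 1, n_lig):
            dx = _min_image(lig_pos[i, 0] - lig_pos[j, 0], box)
            dy = _min_image(lig_pos[i, 1] - lig_pos[j, 1], box)
            dz = _min_image(lig_pos[i, 2] - lig_pos[j, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc_pl * rc_pl:
                continue
            r = math.sqrt(r2)
            sr6 = (sigma_pl / r) ** 6
            energy += 4.0 * eps_nc * (sr6 * sr6 - sr6) - sh_ll
            fs = 24.0 * eps_nc * (2.0 * sr6 * sr6 - sr6) / r
            if fs > force_cap:
                fs = force_cap
            elif fs < -force_cap:
                fs = -force_cap
            fx, fy, fz = fs * dx / r, fs * dy / r, fs * dz / r
            f_lig[i, 0] += fx; f_lig[i, 1] += fy; f_lig[i, 2] += fz
            f_lig[j, 0] -= fx; f_lig[j, 1] -= fy; f_lig[j, 2] -= fz

    # PPI patch-patch Morse: pairwise within the cutoff; the steep inner
    # wall (alpha 2.2/A) plus core excluded volume limits patch valence
    for i in range(n_enz):
      for j in range(i + 1, n_enz):
        de = de_ppi[enz_type[i], enz_type[j]]
        if de <= 0.0:
            continue
        dx = _min_image(ppi_pos[i, 0] - ppi_pos[j, 0], box)
        dy = _min_image(ppi_pos[i, 1] - ppi_pos[j, 1], box)
        dz = _min_image(ppi_pos[i, 2] - ppi_pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= ppi_rc * ppi_rc or r2 <= 0.0:
            continue
        r = math.sqrt(r2)
        x = r - ppi_r0
        e2 = math.exp(-2.0 * ppi_alpha * x)
        e1 = math.exp(-ppi_alpha * x)
        energy += de * (e2 - 2.0 * e1) - de * sh_ppi_base
        fs = 2.0 * ppi_alpha * de * (e2 - e1)   # -dU/dr
        if fs > force_cap:
            fs = force_cap
        elif fs < -force_cap:
            fs = -force_cap
        fx, fy, fz = fs * dx / r, fs * dy / r, fs * dz / r
        f_ppi[i, 0] += fx; f_ppi[i, 1] += fy; f_ppi[i, 2] += fz
        f_ppi[j, 0] -= fx; f_ppi[j, 1] -= fy; f_ppi[j, 2] -= fz

    # patch-ligand: cognate Morse for bound pairs, else weak LJ (both patches)
    for l in range(n_lig):
        bound_to = lig_bound[l]
        for i in range(n_enz):
            # active-site patch
            dx = _min_image(act_pos[i, 0] - lig_pos[l, 0], box)
            dy = _min_image(act_pos[i, 1] - lig_pos[l, 1], box)
            dz = _min_image(act_pos[i, 2] - lig_pos[l, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            if bound_to == i:
                r = math.sqrt(r2)
                if 0.0 < r < cog_rc:
                    x = r - cog_r0
                    e2 = math.exp(-2.0 * cog_alpha * x)
                    e1 = math.exp(-cog_alpha * x)
                    energy += cog_de * (e2 - 2.0 * e1) - sh_cog
                    fs = 2.0 * cog_alpha * cog_de * (e2 - e1)
                    if fs > force_cap:
                        fs = force_cap
                    elif fs < -force_cap:
                        fs = -force_cap
                    fx, fy, fz = fs * dx / r, fs * dy / r, fs * dz / r
                    f_act[i, 0] += fx; f_act[i, 1] += fy; f_act[i, 2] += fz
                    f_lig[l, 0] -= fx; f_lig[l, 1] -= fy; f_lig[l, 2] -= fz
            elif r2 < rc_pl * rc_pl:
                r = math.sqrt(r2)
                sr6 = (sigma_pl / r) ** 6
                energy += 4.0 * eps_nc * (sr6 * sr6 - sr6) - sh_pl
                fs = 24.0 * eps_nc * (2.0 * sr6 * sr6 - sr6) / r
                if fs > force_cap:
                    fs = force_cap
                elif fs < -force_cap:
                    fs = -force_cap
                fx, fy, fz = fs * dx / r, fs * dy / r, fs * dz / r
                f_act[i, 0] += fx; f_act[i, 1] += fy; f_act[i, 2] += fz
                f_lig[l, 0] -= fx; f_lig[l, 1] -= fy; f_lig[l, 2] -= fz
            # PPI patch: always non-cognate with ligands
            dx = _min_image(ppi_pos[i, 0] - lig_pos[l, 0], box)
            dy = _min_image(ppi_pos[i, 1] - lig_pos[l, 1], box)
            dz = _min_image(ppi_pos[i, 2] - lig_pos[l, 2], box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc_pl * rc_pl:
                r = math.sqrt(r2)
                sr6 = (sigma_pl / r) ** 6
                energy += 4.0 * eps_nc * (sr6 * sr6 - sr6) - sh_pl
                fs = 24.0 * eps_nc * (2.0 * sr6 * sr6 - sr6) / r
                if fs > force_cap:
                    fs = force_cap
                elif fs < -force_cap:
                    fs = -force_cap
                fx, fy, fz = fs * dx / r, fs * dy / r, fs * dz / r
                f_ppi[i, 0] += fx; f_ppi[i, 1] += fy; f_ppi[i, 2] += fz
                f_lig[l, 0] -= fx; f_lig[l, 1] -= fy; f_lig[l, 2] -= fz
    return energy


def _min_image_np(d, box):
    return d - box * np.round(d / box)


def _cross_rows(a, b):
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


@njit(cache=True)
def _bonds_kernel(ppi_pos, act_pos, lig_pos, enz_type, lig_state,
                  partner, lig_bound, de, box,
                  ppi_rc2, ppi_capture2, cog_rc2, product_state):
    n_enz = ppi_pos.shape[0]
    n_lig = lig_pos.shape[0]

    # PPI partner diagnostic: nearest interacting patch within capture range
    for i in range(n_enz):
        best = -1
        best_d2 = ppi_capture2
        for j in range(n_enz):
            if j == i or de[enz_type[i], enz_type[j]] <= 0.0:
                continue
            dx = _min_image(ppi_pos[i, 0] - ppi_pos[j, 0], box)
            dy = _min_image(ppi_pos[i, 1] - ppi_pos[j, 1], box)
            dz = _min_image(ppi_pos[i, 2] - ppi_pos[j, 2], box)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 <= best_d2:
                best = j
                best_d2 = d2
        partner[i] = best

    # cognate ligand binding: release, then greedy capture
    occupied = np.full(n_enz, -1, dtype=np.int64)
    for l in range(n_lig):
        e = lig_bound[l]
        if e >= 0:
            if lig_state[l] != enz_type[e]:
                lig_bound[l] = -1
                continue
            dx = _min_image(act_pos[e, 0] - lig_pos[l, 0], box)
            dy = _min_image(act_pos[e, 1] - lig_pos[l, 1], box)
            dz = _min_image(act_pos[e, 2] - lig_pos[l, 2], box)
            if dx * dx + dy * dy + dz * dz > cog_rc2:
                lig_bound[l] = -1
            else:
                occupied[e] = l
    max_c = n_lig * 8
    cl = np.empty(max_c, dtype=np.int64)
    ce = np.empty(max_c, dtype=np.int64)
    cd = np.empty(max_c)
    m = 0
    for l in range(n_lig):
        if lig_bound[l] >= 0 or lig_state[l] >= product_state:
            continue
        for e in range(n_enz):
            if occupied[e] >= 0 or enz_type[e] != lig_state[l]:
                continue
            dx = _min_image(act_pos[e, 0] - lig_pos[l, 0], box)
            dy = _min_image(act_pos[e, 1] - lig_pos[l, 1], box)
            dz = _min_image(act_pos[e, 2] - lig_pos[l, 2], box)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 <= cog_rc2 and m < max_c:
                cl[m] = l
                ce[m] = e
                cd[m] = d2
                m += 1
    if m:
        order = np.argsort(cd[:m], kind="mergesort")
        for k in order:
            l, e = cl[k], ce[k]
            if lig_bound[l] < 0 and occupied[e] < 0:
                lig_bound[l] = e
                occupied[e] = l


def compute_forces(system: PatchySystem, ff: Forcefield, confine_on: bool,
                   config: LangevinConfig, r_conf: float):
    """Body forces, torques, ligand forces and total potential energy."""
    ppi_pos, act_pos = system.patch_positions()
    n_enz, n_lig = system.n_enzymes, system.n_ligands
    f_core = np.zeros((n_enz, 3))
    f_ppi = np.zeros((n_enz, 3))
    f_act = np.zeros((n_enz, 3))
    f_lig = np.zeros((n_lig, 3))
    energy = _pair_forces(
        system.pos, ppi_pos, act_pos, system.lig_pos,
        system.enz_type, system.lig_state, system.ppi_partner, system.lig_bound,
        system.box, ff.eps_pp, ff.eps_pl, ff.eps_nc,
        ff.sigma_core, ff.sigma_core_lig, ff.sigma_patch_lig,
        ff.de_ppi, PPI_MORSE.alpha, PPI_MORSE.r0, PPI_MORSE.cutoff,
        COGNATE_MORSE.de, COGNATE_MORSE.alpha, COGNATE_MORSE.r0,
        COGNATE_MORSE.cutoff, config.force_cap,
        f_core, f_ppi, f_act, f_lig)

    if confine_on:
        center = system.box / 2.0
        for arr, farr in ((system.pos, f_core),
                          (system.lig_pos, f_lig) if config.confine_ligands else (None, None)):
            if arr is None or len(arr) == 0:
                continue
            d = arr - center
            dist = np.linalg.norm(d, axis=1)
            out = dist > r_conf
            if out.any():
                over = dist[out] - r_conf
                energy += float(0.5 * config.confinement_k * (over ** 2).sum())
                farr[out] -= (config.confinement_k * over / dist[out])[:, None] * d[out]

    body_force = f_core + f_ppi + f_act
    arm_ppi = ppi_pos - system.pos
    arm_act = act_pos - system.pos
    torque = _cross_rows(arm_ppi, f_ppi) + _cross_rows(arm_act, f_act)
    return body_force, torque, f_lig, energy


# ---------------------------------------------------------------------------
# bond bookkeeping

def update_bonds(system: PatchySystem) -> None:
    """Refresh PPI partner diagnostics and cognate occupancy.

    Each PPI patch records its nearest interacting patch within the capture
    range (analysis only; forces are pairwise).  Cognate active-site /
    ligand occupancy is strictly one-to-one: held ligands are released past
    the r0 + 2.5 A radius or on state change, then free cognate ligands are
    captured greedily by distance.
    """
    ppi_pos, act_pos = system.patch_positions()
    _bonds_kernel(ppi_pos, act_pos, system.lig_pos,
                  system.enz_type, system.lig_state,
                  system.ppi_partner, system.lig_bound,
                  system.energy.de, system.box,
                  PPI_MORSE.cutoff ** 2,
                  (PPI_MORSE.r0 + PPI_MORSE.capture_range) ** 2,
                  COGNATE_MORSE.cutoff ** 2, PRODUCT_STATE)


@njit(cache=True)
def _bd_chunk(pos, rot, lig_pos, pos_unw, lig_unw, enz_type, lig_state,
              ppi_partner, lig_bound, reaction_counts, box,
              eps_pp, eps_pl, eps_nc, sigma_core, sigma_cl, sigma_pl,
              de_ppi, ppi_alpha, ppi_r0, ppi_rc, ppi_capture,
              cog_de, cog_alpha, cog_r0, cog_rc, force_cap,
              patch_offset, dt, kt, d_enz, d_lig, d_rot,
              confine_on, r_conf, k_conf, confine_ligands,
              p_react, product_state,
              noise_e, noise_r, noise_l, react_u, max_drift):
    """Advance n_sub Brownian steps in one compiled pass.

    Noise arrays carry pre-drawn standard normals, shape (n_sub, n, 3);
    ``react_u`` carries one uniform per ligand per substep.  Returns the
    largest per-step displacement (A) for the instability check.
    """
    n_sub = noise_e.shape[0]
    n_enz = pos.shape[0]
    n_lig = lig_pos.shape[0]
    f_core = np.empty((n_enz, 3))
    f_ppi = np.empty((n_enz, 3))
    f_act = np.empty((n_enz, 3))
    f_lig = np.empty((n_lig, 3))
    ppi_pos = np.empty((n_enz, 3))
    act_pos = np.empty((n_enz, 3))
    sq_t = math.sqrt(2.0 * d_enz * dt)
    sq_l = math.sqrt(2.0 * d_lig * dt)
    sq_r = math.sqrt(2.0 * d_rot * dt)
    center = box / 2.0
    max_disp = 0.0

    for s in range(n_sub):
        for i in range(n_enz):
            ox = rot[i, 0, 2] * patch_offset
            oy = rot[i, 1, 2] * patch_offset
            oz = rot[i, 2, 2] * patch_offset
            ppi_pos[i, 0] = pos[i, 0] + ox
            ppi_pos[i, 1] = pos[i, 1] + oy
            ppi_pos[i, 2] = pos[i, 2] + oz
            act_pos[i, 0] = pos[i, 0] - ox
            act_pos[i, 1] = pos[i, 1] - oy
            act_pos[i, 2] = pos[i, 2] - oz
        f_core[:] = 0.0
        f_ppi[:] = 0.0
        f_act[:] = 0.0
        f_lig[:] = 0.0
        _pair_forces(pos, ppi_pos, act_pos, lig_pos, enz_type, lig_state,
                     ppi_partner, lig_bound, box,
                     eps_pp, eps_pl, eps_nc, sigma_core, sigma_cl, sigma_pl,
                     de_ppi, ppi_alpha, ppi_r0, ppi_rc,
                     cog_de, cog_alpha, cog_r0, cog_rc, force_cap,
                     f_core, f_ppi, f_act, f_lig)
        if confine_on:
            for i in range(n_enz):
                dx = pos[i, 0] - center
                dy = pos[i, 1] - center
                dz = pos[i, 2] - center
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                if d > r_conf:
                    g = k_conf * (d - r_conf) / d
                    f_core[i, 0] -= g * dx
                    f_core[i, 1] -= g * dy
                    f_core[i, 2] -= g * dz
            if confine_ligands:
                for l in range(n_lig):
                    dx = lig_pos[l, 0] - center
                    dy = lig_pos[l, 1] - center
                    dz = lig_pos[l, 2] - center
                    d = math.sqrt(dx * dx + dy * dy + dz * dz)
                    if d > r_conf:
                        g = k_conf * (d - r_conf) / d
                        f_lig[l, 0] -= g * dx
                        f_lig[l, 1] -= g * dy
                        f_lig[l, 2] -= g * dz

        # enzymes: translation + rotation
        for i in range(n_enz):
            fx = f_core[i, 0] + f_ppi[i, 0] + f_act[i, 0]
            fy = f_core[i, 1] + f_ppi[i, 1] + f_act[i, 1]
            fz = f_core[i, 2] + f_ppi[i, 2] + f_act[i, 2]
            dx = d_enz / kt * fx * dt
            dy = d_enz / kt * fy * dt
            dz = d_enz / kt * fz * dt
            dn = math.sqrt(dx * dx + dy * dy + dz * dz)
            if dn > max_drift:
                g = max_drift / dn
                dx *= g; dy *= g; dz *= g
            dx += sq_t * noise_e[s, i, 0]
            dy += sq_t * noise_e[s, i, 1]
            dz += sq_t * noise_e[s, i, 2]
            disp = math.sqrt(dx * dx + dy * dy + dz * dz)
            if disp > max_disp:
                max_disp = disp
            pos[i, 0] = (pos[i, 0] + dx) % box
            pos[i, 1] = (pos[i, 1] + dy) % box
            pos[i, 2] = (pos[i, 2] + dz) % box
            pos_unw[i, 0] += dx; pos_unw[i, 1] += dy; pos_unw[i, 2] += dz

            # torque about the body center (arms at force evaluation time)
            rx = rot[i, 0, 2] * patch_offset
            ry = rot[i, 1, 2] * patch_offset
            rz = rot[i, 2, 2] * patch_offset
            tx = (ry * f_ppi[i, 2] - rz * f_ppi[i, 1]) \
                + (-ry * f_act[i, 2] + rz * f_act[i, 1])
            ty = (rz * f_ppi[i, 0] - rx * f_ppi[i, 2]) \
                + (-rz * f_act[i, 0] + rx * f_act[i, 2])
            tz = (rx * f_ppi[i, 1] - ry * f_ppi[i, 0]) \
                + (-rx * f_act[i, 1] + ry * f_act[i, 0])
            wx = d_rot / kt * tx * dt + sq_r * noise_r[s, i, 0]
            wy = d_rot / kt * ty * dt + sq_r * noise_r[s, i, 1]
            wz = d_rot / kt * tz * dt + sq_r * noise_r[s, i, 2]
            th = math.sqrt(wx * wx + wy * wy + wz * wz)
            if th > 1e-12:
                kx = wx / th; ky = wy / th; kz = wz / th
                c = math.cos(th); sn = math.sin(th); oc = 1.0 - c
                r00 = c + kx * kx * oc
                r01 = kx * ky * oc - kz * sn
                r02 = kx * kz * oc + ky * sn
                r10 = ky * kx * oc + kz * sn
                r11 = c + ky * ky * oc
                r12 = ky * kz * oc - kx * sn
                r20 = kz * kx * oc - ky * sn
                r21 = kz * ky * oc + kx * sn
                r22 = c + kz * kz * oc
                for col in range(3):
                    a0 = rot[i, 0, col]
                    a1 = rot[i, 1, col]
                    a2 = rot[i, 2, col]
                    rot[i, 0, col] = r00 * a0 + r01 * a1 + r02 * a2
                    rot[i, 1, col] = r10 * a0 + r11 * a1 + r12 * a2
                    rot[i, 2, col] = r20 * a0 + r21 * a1 + r22 * a2

        for l in range(n_lig):
            dx = d_lig / kt * f_lig[l, 0] * dt
            dy = d_lig / kt * f_lig[l, 1] * dt
            dz = d_lig / kt * f_lig[l, 2] * dt
            dn = math.sqrt(dx * dx + dy * dy + dz * dz)
            if dn > max_drift:
                g = max_drift / dn
                dx *= g; dy *= g; dz *= g
            dx += sq_l * noise_l[s, l, 0]
            dy += sq_l * noise_l[s, l, 1]
            dz += sq_l * noise_l[s, l, 2]
            disp = math.sqrt(dx * dx + dy * dy + dz * dz)
            if disp > max_disp:
                max_disp = disp
            lig_pos[l, 0] = (lig_pos[l, 0] + dx) % box
            lig_pos[l, 1] = (lig_pos[l, 1] + dy) % box
            lig_pos[l, 2] = (lig_pos[l, 2] + dz) % box
            lig_unw[l, 0] += dx; lig_unw[l, 1] += dy; lig_unw[l, 2] += dz

        # refresh patch positions, then bonds and reactions
        for i in range(n_enz):
            ox = rot[i, 0, 2] * patch_offset
            oy = rot[i, 1, 2] * patch_offset
            oz = rot[i, 2, 2] * patch_offset
            ppi_pos[i, 0] = pos[i, 0] + ox
            ppi_pos[i, 1] = pos[i, 1] + oy
            ppi_pos[i, 2] = pos[i, 2] + oz
            act_pos[i, 0] = pos[i, 0] - ox
            act_pos[i, 1] = pos[i, 1] - oy
            act_pos[i, 2] = pos[i, 2] - oz
        _bonds_kernel(ppi_pos, act_pos, lig_pos, enz_type, lig_state,
                      ppi_partner, lig_bound, de_ppi, box,
                      ppi_rc * ppi_rc, ppi_capture * ppi_capture,
                      cog_rc * cog_rc, product_state)
        for l in range(n_lig):
            e = lig_bound[l]
            if e >= 0:
                st = lig_state[l]
                if st < product_state and react_u[s, l] < p_react[st]:
                    reaction_counts[st] += 1
                    lig_state[l] = st + 1
                    lig_bound[l] = -1
    return max_disp


def ppi_valence(system: PatchySystem) -> np.ndarray:
    """Per-patch count of interacting PPI patches within the capture range.

    Diagnostic for the geometric single-valence property: values above 1
    mark patches transiently shared by more than one partner.
    """
    ppi_pos, _ = system.patch_positions()
    diff = _min_image_np(ppi_pos[:, None, :] - ppi_pos[None, :, :], system.box)
    d2 = (diff ** 2).sum(axis=-1)
    capture2 = (PPI_MORSE.r0 + PPI_MORSE.capture_range) ** 2
    de = system.energy.de[np.ix_(system.enz_type, system.enz_type)]
    close = (d2 <= capture2) & (de > 0)
    np.fill_diagonal(close, False)
    return close.sum(axis=1)


def attempt_reactions(system: PatchySystem, scheme: ReactionScheme,
                      rng: np.random.Generator) -> int:
    """One reaction sweep over ligands held in their cognate capture region."""
    bound = np.where(system.lig_bound >= 0)[0]
    fired = 0
    if len(bound) == 0:
        return 0
    p = scheme.p_react
    u = rng.random(len(bound))
    for l, ul in zip(bound, u):
        state = system.lig_state[l]
        if state >= PRODUCT_STATE:
            continue
        if ul < p[state]:
            system.reaction_counts[state] += 1
            system.lig_state[l] = state + 1
            system.lig_bound[l] = -1     # product of step k leaves enzyme k
            fired += 1
    return fired


# ---------------------------------------------------------------------------
# integrators

class Instability(RuntimeError):
    pass


def _check_displacement(dr, limit):
    if len(dr) == 0:
        return
    m = float(np.abs(dr).max())
    if m > limit:
        raise Instability(
            f"per-step displacement {m:.2f} A exceeds the patch diameter "
            f"{limit} A; reduce the timestep")


def step(system: PatchySystem, config: LangevinConfig, ff: Forcefield,
         rng: np.random.Generator, confine_on: bool = False,
         r_conf: float = 0.0, thermostat: bool = True) -> PatchySystem:
    """Advance one timestep in place (BAOAB Langevin or Brownian)."""
    if config.integrator == "brownian":
        return _step_brownian(system, config, ff, rng, confine_on, r_conf)
    return _step_langevin(system, config, ff, rng, confine_on, r_conf, thermostat)


def _step_langevin(system, config, ff, rng, confine_on, r_conf, thermostat):
    dt = config.dt
    kt = config.kt
    f_body, torque, f_lig, _ = compute_forces(system, ff, confine_on, config, r_conf)

    system.vel += 0.5 * dt * f_body / ff.m_enz
    system.angvel += 0.5 * dt * torque / ff.inertia
    system.lig_vel += 0.5 * dt * f_lig / ff.m_lig

    dr1 = 0.5 * dt * system.vel
    system.pos += dr1
    system.pos_unwrapped += dr1
    rotate_matrices(system.rot, system.angvel, 0.5 * dt)
    dl1 = 0.5 * dt * system.lig_vel
    system.lig_pos += dl1
    system.lig_pos_unwrapped += dl1

    if thermostat:
        c1 = math.exp(-ff.gamma_enz * dt / ff.m_enz)
        c1l = math.exp(-ff.gamma_lig * dt / ff.m_lig)
        c1r = math.exp(-ff.gamma_rot * dt / ff.inertia)
        system.vel *= c1
        system.vel += math.sqrt((1 - c1 * c1) * kt / ff.m_enz) * rng.normal(
            size=system.vel.shape)
        system.lig_vel *= c1l
        if system.n_ligands:
            system.lig_vel += math.sqrt((1 - c1l * c1l) * kt / ff.m_lig) * rng.normal(
                size=system.lig_vel.shape)
        system.angvel *= c1r
        system.angvel += math.sqrt((1 - c1r * c1r) * kt / ff.inertia) * rng.normal(
            size=system.angvel.shape)

    dr2 = 0.5 * dt * system.vel
    system.pos += dr2
    system.pos_unwrapped += dr2
    rotate_matrices(system.rot, system.angvel, 0.5 * dt)
    dl2 = 0.5 * dt * system.lig_vel
    system.lig_pos += dl2
    system.lig_pos_unwrapped += dl2

    _check_displacement(dr1 + dr2, system.species.sigma_patch)
    _check_displacement(dl1 + dl2, system.species.sigma_patch)
    system.pos %= system.box
    system.lig_pos %= system.box
    update_bonds(system)

    f_body, torque, f_lig, _ = compute_forces(system, ff, confine_on, config, r_conf)
    system.vel += 0.5 * dt * f_body / ff.m_enz
    system.angvel += 0.5 * dt * torque / ff.inertia
    system.lig_vel += 0.5 * dt * f_lig / ff.m_lig
    system.time_fs += dt
    return system


def _chunk_args(system, config, ff, confine_on, r_conf):
    kt = config.kt
    return dict(
        pos=system.pos, rot=system.rot, lig_pos=system.lig_pos,
        pos_unw=system.pos_unwrapped, lig_unw=system.lig_pos_unwrapped,
        enz_type=system.enz_type, lig_state=system.lig_state,
        ppi_partner=system.ppi_partner, lig_bound=system.lig_bound,
        reaction_counts=system.reaction_counts, box=system.box,
        eps_pp=ff.eps_pp, eps_pl=ff.eps_pl, eps_nc=ff.eps_nc,
        sigma_core=ff.sigma_core, sigma_cl=ff.sigma_core_lig,
        sigma_pl=ff.sigma_patch_lig, de_ppi=ff.de_ppi,
        ppi_alpha=PPI_MORSE.alpha, ppi_r0=PPI_MORSE.r0,
        ppi_rc=PPI_MORSE.cutoff,
        ppi_capture=PPI_MORSE.r0 + PPI_MORSE.capture_range,
        cog_de=COGNATE_MORSE.de, cog_alpha=COGNATE_MORSE.alpha,
        cog_r0=COGNATE_MORSE.r0, cog_rc=COGNATE_MORSE.cutoff,
        force_cap=config.force_cap, patch_offset=system.species.patch_offset,
        dt=config.dt, kt=kt, d_enz=kt / ff.gamma_enz, d_lig=kt / ff.gamma_lig,
        d_rot=kt / ff.gamma_rot, confine_on=confine_on, r_conf=r_conf,
        k_conf=config.confinement_k, confine_ligands=config.confine_ligands,
        product_state=PRODUCT_STATE,
        # drift clamp: steep repulsive overlaps relax gradually instead of
        # being kicked across a patch diameter
        max_drift=0.25 * system.species.sigma_patch,
    )


def run_chunk(system, config, ff, rng, n_sub, confine_on, r_conf,
              scheme: ReactionScheme | None = None):
    """Advance ``n_sub`` Brownian steps through the compiled kernel."""
    n_enz, n_lig = system.n_enzymes, system.n_ligands
    noise_e = rng.normal(size=(n_sub, n_enz, 3))
    noise_r = rng.normal(size=(n_sub, n_enz, 3))
    noise_l = rng.normal(size=(n_sub, n_lig, 3))
    if scheme is None:
        p_react = np.zeros(1)
        react_u = np.ones((n_sub, n_lig))
    else:
        p_react = scheme.p_react
        react_u = rng.random((n_sub, n_lig))
    args = _chunk_args(system, config, ff, confine_on, r_conf)
    max_disp = _bd_chunk(
        args["pos"], args["rot"], args["lig_pos"], args["pos_unw"],
        args["lig_unw"], args["enz_type"], args["lig_state"],
        args["ppi_partner"], args["lig_bound"], args["reaction_counts"],
        args["box"], args["eps_pp"], args["eps_pl"], args["eps_nc"],
        args["sigma_core"], args["sigma_cl"], args["sigma_pl"],
        args["de_ppi"], args["ppi_alpha"], args["ppi_r0"], args["ppi_rc"],
        args["ppi_capture"], args["cog_de"], args["cog_alpha"],
        args["cog_r0"], args["cog_rc"], args["force_cap"],
        args["patch_offset"], args["dt"], args["kt"], args["d_enz"],
        args["d_lig"], args["d_rot"], args["confine_on"], args["r_conf"],
        args["k_conf"], args["confine_ligands"], p_react,
        args["product_state"], noise_e, noise_r, noise_l, react_u,
        args["max_drift"])
    if max_disp > system.species.sigma_patch:
        raise Instability(
            f"per-step displacement {max_disp:.2f} A exceeds the patch "
            f"diameter {system.species.sigma_patch} A; reduce the timestep")
    system.time_fs += n_sub * config.dt
    return system


def _step_brownian(system, config, ff, rng, confine_on, r_conf):
    return run_chunk(system, config, ff, rng, 1, confine_on, r_conf, scheme=None)


def kinetic_energy(system: PatchySystem, ff: Forcefield):
    """(translational, rotational) kinetic energies in kT units."""
    trans = 0.5 * ff.m_enz * float((system.vel ** 2).sum()) \
        + 0.5 * ff.m_lig * float((system.lig_vel ** 2).sum())
    rot = 0.5 * ff.inertia * float((system.angvel ** 2).sum())
    return trans, rot


def total_energy(system: PatchySystem, ff: Forcefield, config: LangevinConfig,
                 confine_on: bool = False, r_conf: float = 0.0) -> float:
    _, _, _, pot = compute_forces(system, ff, confine_on, config, r_conf)
    trans, rot = kinetic_energy(system, ff)
    return pot + trans + rot


# ---------------------------------------------------------------------------
# full runs

def run(config: LangevinConfig, scheme: ReactionScheme, energy: PPIEnergyMap,
        mode: str = "ppi_on", seed: int | None = None,
        species: SpeciesSpec | None = None):
    """Propagate one trajectory; returns a TrajectorySummary.

    ``mode='ppi_off'`` zeroes every PPI-patch well depth (monomeric control)
    and is otherwise identical, including the seed handling.
    """
    from .analysis import summarize_run

    if mode not in ("ppi_on", "ppi_off"):
        raise ValueError("mode must be 'ppi_on' or 'ppi_off'")
    if species is None:
        species = SpeciesSpec()
    eff_energy = energy if mode == "ppi_on" else energy.zeroed()
    run_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(run_seed)
    system = build_system(species, eff_energy, config, rng,
                          n_reactions=scheme.n_reactions)
    ff = Forcefield.build(species, eff_energy, config)
    r_conf = config.resolve_confinement_radius(system.n_enzymes)
    n_confine = int(config.confine_frac * config.n_steps)

    times, counts_t = [], []
    frames = []
    frame_start = config.n_steps // 2
    update_bonds(system)

    def record():
        times.append(system.time_fs)
        counts_t.append(system.reaction_counts.copy())

    def capture(istep):
        if istep >= frame_start and istep % config.frame_interval == 0:
            ppi_pos, _ = system.patch_positions()
            frames.append((ppi_pos.copy(), system.enz_type.copy(),
                           system.ppi_partner.copy()))

    if config.integrator == "brownian":
        istep = 0
        while istep < config.n_steps:
            boundaries = [config.n_steps,
                          istep + config.record_interval
                          - istep % config.record_interval]
            if istep < n_confine:
                boundaries.append(n_confine)
            nxt = istep + config.frame_interval - istep % config.frame_interval
            if nxt > frame_start:
                boundaries.append(nxt)
            upto = min(boundaries)
            run_chunk(system, config, ff, rng, upto - istep,
                      confine_on=istep < n_confine, r_conf=r_conf,
                      scheme=scheme)
            istep = upto
            if istep % config.record_interval == 0 or istep == config.n_steps:
                record()
            capture(istep)
    else:
        for i in range(config.n_steps):
            step(system, config, ff, rng, confine_on=i < n_confine,
                 r_conf=r_conf)
            attempt_reactions(system, scheme, rng)
            if (i + 1) % config.record_interval == 0 or i == config.n_steps - 1:
                record()
            capture(i + 1)
    return summarize_run(system, scheme, config, mode, run_seed,
                         np.array(times), np.array(counts_t), frames)
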