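"""Synthetic fixtures emulating the study's data shapes.

These generators make the whole pipeline testable without downloads: a
35-protein two-orientation fluorescence table with planted interacting
clusters, homo-oligomer diagonal signal, one-orientation attenuation and
missing wells; a paired TM-score-like similarity matrix with a planted
structurally similar subgroup; virtual-Calpha chains with planted
interaction surfaces of controlled mutual overlap; and two-chain dimers
with a prescribed inter-chain gap.  Background and cluster fluorescence
distributions are not published values; the defaults reproduce the
qualitative regime of the assay (a weak majority below 750, classifiable
planted clusters around 1150).

All generators are deterministic given their seed and attach provenance
metadata (spec + seed) to their outputs where a carrier exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ORIENTATIONS, OrientedMeasurement, PPIMatrix
from .surfaces import CaStructure, InteractionSurface


@dataclass(frozen=True)
class MatrixGeneratorSpec:
    n_proteins: int = 35
    background_mean: float = 600.0
    background_sd: float = 60.0
    clusters: tuple = ()                 # tuple of tuples of protein names
    cluster_mean: float = 1150.0
    cluster_sd: float = 80.0
    diagonal_mean: float = 950.0
    diagonal_sd: float = 250.0
    attenuation_low: float = 0.5         # one orientation scaled by U(low, high)
    attenuation_high: float = 1.0
    missing_fraction: float = 0.03
    min_cells: int = 10_000
    seed: int = 0

    def protein_names(self):
        return [f"P{i:02d}" for i in range(self.n_proteins)]


def default_cluster_spec(seed: int = 0) -> MatrixGeneratorSpec:
    """A 35-protein table with one planted 5-protein cluster (P00..P04)."""
    names = [f"P{i:02d}" for i in range(35)]
    return MatrixGeneratorSpec(clusters=(tuple(names[:5]),), seed=seed)


def synth_mfi(spec: MatrixGeneratorSpec):
    """Two-orientation fluorescence table (list of OrientedMeasurement)."""
    rng = np.random.default_rng(spec.seed)
    proteins = spec.protein_names()
    name_set = set(proteins)
    cluster_pairs = set()
    for cluster in spec.clusters:
        if not set(cluster) <= name_set:
            raise ValueError(f"cluster {cluster} not within the protein list")
        members = list(cluster)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                cluster_pairs.add(tuple(sorted((members[i], members[j]))))

    measurements = []
    for i, a in enumerate(proteins):
        for j in range(i, len(proteins)):
            b = proteins[j]
            if i == j:
                base = max(rng.normal(spec.diagonal_mean, spec.diagonal_sd), 0.0)
            elif (a, b) in cluster_pairs:
                base = max(rng.normal(spec.cluster_mean, spec.cluster_sd), 0.0)
            else:
                base = max(rng.normal(spec.background_mean, spec.background_sd), 0.0)
            atten = rng.uniform(spec.attenuation_low, spec.attenuation_high)
            weak_first = rng.random() < 0.5
            for orient, factor in zip(ORIENTATIONS,
                                      (atten, 1.0) if weak_first else (1.0, atten)):
                missing = rng.random() < spec.missing_fraction
                n_cells = (rng.integers(0, spec.min_cells) if missing
                           else spec.min_cells + int(rng.integers(0, 20_000)))
                noise = rng.normal(0.0, spec.background_sd * 0.1)
                measurements.append(OrientedMeasurement(
                    protein_a=a, protein_b=b, orientation=orient,
                    mfi=max(base * factor + noise, 0.0), n_cells=int(n_cells)))
    return measurements


def synth_tm(spec: MatrixGeneratorSpec, coupling: float = 1.0) -> PPIMatrix:
    """TM-score-like symmetric matrix in [0, 1].

    With coupling c, each planted-cluster pair receives a similarity drawn
    from U(0.5, 0.9) with probability c and from the U(0.1, 0.45)
    background otherwise.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed + 101)
    proteins = spec.protein_names()
    cluster_pairs = set()
    for cluster in spec.clusters:
        members = list(cluster)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                cluster_pairs.add(tuple(sorted((members[i], members[j]))))
    n = len(proteins)
    values = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = tuple(sorted((proteins[i], proteins[j])))
            if pair in cluster_pairs and rng.random() < coupling:
                v = rng.uniform(0.5, 0.9)
            else:
                v = rng.uniform(0.1, 0.45)
            values[i, j] = values[j, i] = v
    return PPIMatrix(proteins, values, symmetric=True)


# ---------------------------------------------------------------------------
# structures

@dataclass(frozen=True)
class PlantedSurface:
    center: int                  # residue number of the patch center
    radius: float                # A
    shared_fraction: float = 0.0   # target overlap with the previous surface

    def __post_init__(self):
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class StructureGeneratorSpec:
    chain_length: int = 60
    geometry: str = "walk"       # 'walk' (compact self-avoiding) or 'helix'
    bond_length: float = 3.8     # virtual Calpha-Calpha bond, A
    exposed_fraction: float = 0.6
    surfaces: tuple = ()         # tuple of PlantedSurface
    seed: int = 0


def _compact_walk(n: int, bond: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding-ish chain with 3.8 A bonds, biased back to the origin."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(2000):
            direction = rng.normal(size=3)
            direction -= 0.15 * coords[i - 1] / max(np.linalg.norm(coords[i - 1]), 1.0)
            direction /= np.linalg.norm(direction)
            cand = coords[i - 1] + bond * direction
            if i < 2 or np.linalg.norm(coords[:i - 1] - cand, axis=1).min() > 3.5:
                coords[i] = cand
                break
        else:
            raise RuntimeError("failed to grow compact chain")
    return coords


def _helix(n: int, bond: float) -> np.ndarray:
    # ideal alpha-helix Calpha trace: radius 2.3 A, rise 1.5 A, 100 deg/res
    t = np.arange(n)
    theta = np.deg2rad(100.0) * t
    return np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * t], axis=1)


def synth_structure(spec: StructureGeneratorSpec):
    """(CaStructure, planted surfaces) with controlled mutual overlap.

    Surfaces are residue balls around their centers; a requested
    ``shared_fraction`` f with the previous surface is realized by seeding
    the new surface with that fraction of the previous surface's residues
    and filling the rest from the spatial neighborhood of its own center.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "helix":
        coords = _helix(spec.chain_length, spec.bond_length)
    elif spec.geometry == "walk":
        coords = _compact_walk(spec.chain_length, spec.bond_length, rng)
    else:
        raise ValueError("geometry must be 'walk' or 'helix'")
    resids = np.arange(1, spec.chain_length + 1)

    # RSA: exposed residues drawn uniformly; guaranteed >= requested fraction
    n_exposed = max(int(np.ceil(spec.exposed_fraction * spec.chain_length)), 1)
    exposed_idx = rng.choice(spec.chain_length, size=n_exposed, replace=False)
    rsa = rng.uniform(0.0, 0.2, size=spec.chain_length)
    rsa[exposed_idx] = rng.uniform(0.3, 1.0, size=n_exposed)
    structure = CaStructure(resids, coords, rsa=rsa)

    surfaces = []
    prev_members = None
    for k, planted in enumerate(spec.surfaces):
        if not 1 <= planted.center <= spec.chain_length:
            raise ValueError(f"surface center {planted.center} outside the chain")
        center_xyz = coords[planted.center - 1]
        d = np.linalg.norm(coords - center_xyz, axis=1)
        ball = [int(r) for r in resids[d <= planted.radius]]
        if prev_members is None or planted.shared_fraction == 0.0:
            members = ball
        else:
            n_target = len(ball)
            n_shared = int(round(planted.shared_fraction * n_target))
            if n_shared > len(prev_members):
                raise ValueError(
                    f"cannot share {n_shared} residues: previous surface has "
                    f"only {len(prev_members)}")
            shared = list(rng.choice(sorted(prev_members), size=n_shared,
                                     replace=False))
            fresh = [r for r in ball if r not in shared]
            members = shared + fresh[:max(n_target - n_shared, 0)]
        if not members:
            raise ValueError(f"surface {k} is empty; increase its radius")
        surfaces.append(InteractionSurface("synthetic", f"partner{k}", members))
        prev_members = set(members)
    return structure, surfaces


def synth_dimer(spec_a: StructureGeneratorSpec, spec_b: StructureGeneratorSpec,
                gap: float = 5.0):
    """Two chains separated so the minimal inter-chain Calpha distance = gap."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    a, _ = synth_structure(spec_a)
    b, _ = synth_structure(spec_b)

    def min_dist(shift):
        d = np.linalg.norm(a.coords[:, None, :]
                           - (b.coords + [shift, 0.0, 0.0])[None, :, :], axis=-1)
        return d.min()

    # bisect the x-shift of chain B so the closest approach equals the gap
    lo = a.coords[:, 0].min() - b.coords[:, 0].max()       # heavy overlap
    hi = a.coords[:, 0].max() - b.coords[:, 0].min() + gap + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < gap:
            lo = mid
        else:
            hi = mid
    chain_b = CaStructure(b.resids, b.coords + [hi, 0.0, 0.0], rsa=b.rsa, chain="B")
    return a, chain_b
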