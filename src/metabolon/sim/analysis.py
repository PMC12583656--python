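"""Trajectory analytics: clusters, contact maps, stoichiometry, flux ratios."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import PPI_MORSE, LangevinConfig, ReactionScheme
from .system import PatchySystem


@dataclass
class TrajectorySummary:
    mode: str
    seed: int
    times_fs: np.ndarray               # (T,)
    reaction_counts_t: np.ndarray      # (T, n_reactions), cumulative
    reaction_counts: np.ndarray        # (n_reactions,), final
    cluster_size_hist: dict            # size -> count (pooled over frames)
    contact_matrix: np.ndarray         # (n_types, n_types) mean bound pairs
    stoichiometry: np.ndarray          # (n_types,) mean composition of clusters >= 2
    p_react: np.ndarray
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "seed": int(self.seed),
            "times_fs": self.times_fs.tolist(),
            "reaction_counts_t": self.reaction_counts_t.tolist(),
            "reaction_counts": self.reaction_counts.tolist(),
            "cluster_size_histogram": {str(k): int(v)
                                       for k, v in sorted(self.cluster_size_hist.items())},
            "contact_matrix": self.contact_matrix.tolist(),
            "stoichiometry": self.stoichiometry.tolist(),
            "p_react": self.p_react.tolist(),
            "parameters": self.parameters,
        }


def _components_from_adjacency(adj: np.ndarray) -> np.ndarray:
    """Connected-component labels via union-find on a boolean adjacency."""
    n = adj.shape[0]
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ii, jj = np.where(np.triu(adj, k=1))
    for a, b in zip(ii, jj):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    return np.array([find(x) for x in range(n)])


def cluster_frame(ppi_pos: np.ndarray, enz_type: np.ndarray, box: float,
                  cutoff: float = PPI_MORSE.cutoff):
    """Cluster one frame: enzymes linked iff PPI patches within cutoff.

    Returns (labels, size histogram dict, per-type contact-count matrix,
    list of per-cluster type compositions for clusters of size >= 2).
    """
    n = len(ppi_pos)
    d = ppi_pos[:, None, :] - ppi_pos[None, :, :]
    d -= box * np.round(d / box)
    dist = np.linalg.norm(d, axis=-1)
    adj = dist <= cutoff
    np.fill_diagonal(adj, False)
    labels = _components_from_adjacency(adj)

    sizes = {}
    comps = {}
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        sizes[len(members)] = sizes.get(len(members), 0) + 1
        comps[lab] = members
    n_types = int(enz_type.max()) + 1 if n else 0
    contact = np.zeros((n_types, n_types))
    ii, jj = np.where(np.triu(adj, k=1))
    for a, b in zip(ii, jj):
        ta, tb = enz_type[a], enz_type[b]
        contact[ta, tb] += 1
        if ta != tb:
            contact[tb, ta] += 1
    compositions = []
    for members in comps.values():
        if len(members) >= 2:
            compositions.append(np.bincount(enz_type[members], minlength=n_types))
    return labels, sizes, contact, compositions


def cluster_analysis(frames, box: float, cutoff: float = PPI_MORSE.cutoff):
    """Pool cluster statistics over trajectory frames.

    ``frames`` is an iterable of (ppi_patch_positions, enzyme_types, _).
    Returns (size histogram, mean contact matrix, mean cluster composition).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    hist = {}
    contact_sum = None
    comp_sum = None
    n_comp = 0
    for ppi_pos, enz_type, _ in frames:
        _, sizes, contact, comps = cluster_frame(ppi_pos, enz_type, box, cutoff)
        for k, v in sizes.items():
            hist[k] = hist.get(k, 0) + v
        contact_sum = contact if contact_sum is None else contact_sum + contact
        for c in comps:
            comp_sum = c.astype(float) if comp_sum is None else comp_sum + c
            n_comp += 1
    contact_mean = contact_sum / len(frames)
    if n_comp:
        stoich = comp_sum / n_comp
    else:
        n_types = contact_mean.shape[0]
        stoich = np.zeros(n_types)
    return hist, contact_mean, stoich


def summarize_run(system: PatchySystem, scheme: ReactionScheme,
                  config: LangevinConfig, mode: str, seed: int,
                  times: np.ndarray, counts_t: np.ndarray,
                  frames) -> TrajectorySummary:
    if len(frames):
        hist, contact, stoich = cluster_analysis(frames, system.box)
    else:
        n_types = system.species.n_types
        hist, contact, stoich = {}, np.zeros((n_types, n_types)), np.zeros(n_types)
    params = {
        "n_steps": config.n_steps, "dt_fs": config.dt,
        "copies_per_type": config.copies_per_type,
        "concentration_molar": config.concentration,
        "viscosity_pa_s": config.viscosity,
        "integrator": config.integrator,
        "box_side_A": system.box,
        "p_scale": scheme.p_scale,
        "n_ligands": system.n_ligands,
    }
    counts_t = np.asarray(counts_t)
    if counts_t.size and (np.diff(counts_t, axis=0) < 0).any():
        raise AssertionError("cumulative reaction counts decreased")
    return TrajectorySummary(
        mode=mode, seed=seed, times_fs=np.asarray(times),
        reaction_counts_t=counts_t,
        reaction_counts=system.reaction_counts.copy(),
        cluster_size_hist=hist, contact_matrix=contact, stoichiometry=stoich,
        p_react=scheme.p_react.copy(), parameters=params,
    )


def write_xyz(system, path, append: bool = False) -> None:
    """Dump one frame of core/patch/ligand coordinates in XYZ format.

    Element tags: E<type> enzyme cores, P<type> PPI patches, A<type>
    active-site patches, L<state> ligands.
    """
    ppi_pos, act_pos = system.patch_positions()
    with open(path, "a" if append else "w") as fh:
        fh.write(f"{3 * system.n_enzymes + system.n_ligands}\n")
        fh.write(f"t= {system.time_fs:.1f} fs box= {system.box:.2f} A\n")
        for tag, arr, types in (("E", system.pos, system.enz_type),
                                ("P", ppi_pos, system.enz_type),
                                ("A", act_pos, system.enz_type)):
            for t, (x, y, z) in zip(types, arr):
                fh.write(f"{tag}{t} {x:.3f} {y:.3f} {z:.3f}\n")
        for s, (x, y, z) in zip(system.lig_state, system.lig_pos):
            fh.write(f"L{s} {x:.3f} {y:.3f} {z:.3f}\n")


def flux_ratio(summary_ppi: TrajectorySummary,
               summary_off: TrajectorySummary) -> np.ndarray:
    """Per-reaction flux ratios (PPI-on counts / PPI-off counts).

    Zero-denominator entries report +inf when the numerator is positive and
    NaN when both counts are zero (no information).
    """
    if not np.allclose(summary_ppi.p_react, summary_off.p_react):
        raise ValueError("summaries come from different reaction schemes")
    on = summary_ppi.reaction_counts.astype(float)
    off = summary_off.reaction_counts.astype(float)
    out = np.empty_like(on)
    for k in range(len(on)):
        if off[k] > 0:
            out[k] = on[k] / off[k]
        elif on[k] > 0:
            out[k] = np.inf
        else:
            out[k] = np.nan
    return out


def smoothed_flux_ratio(summary_ppi: TrajectorySummary,
                        summary_off: TrajectorySummary,
                        pseudocount: float = 1.0) -> np.ndarray:
    """(on + c) / (off + c) — finite variant for aggregating across steps."""
    if not np.allclose(summary_ppi.p_react, summary_off.p_react):
        raise ValueError("summaries come from different reaction schemes")
    on = summary_ppi.reaction_counts.astype(float)
    off = summary_off.reaction_counts.astype(float)
    return (on + pseudocount) / (off + pseudocount)
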