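"""Simulator physics and bookkeeping: integrators, reactions, clusters."""

import numpy as np
import pytest
from scipy import stats

from metabolon.sim import (Instability, LangevinConfig, PPIEnergyMap,
                           ReactionScheme, SpeciesSpec, attempt_reactions,
                           build_system, cluster_frame, desk_config,
                           flux_ratio, kinetic_energy, run,
                           total_energy, units, update_bonds)
from metabolon.sim.engine import Forcefield, ppi_valence, step

STRONG = PPIEnergyMap.from_mfi(np.full((10, 10), 1200.0))


def make_system(copies=1, conc=2e-3, ligand_factor=0.0, seed=0,
                integrator="langevin", energy=STRONG, **kw):
    cfg = LangevinConfig(copies_per_type=copies, concentration=conc,
                         ligand_factor=ligand_factor, n_steps=1,
                         integrator=integrator, confine_frac=0.0, **kw)
    rng = np.random.default_rng(seed)
    sp = SpeciesSpec()
    system = build_system(sp, energy, cfg, rng)
    ff = Forcefield.build(sp, energy, cfg)
    update_bonds(system)
    return system, cfg, ff, rng


class TestBuildSystem:
    def test_box_side_matches_avogadro_arithmetic(self):
        # 30 copies per type at 50 uM per type
        side = units.box_side_from_concentration(30, 5e-5)
        want = (30 / (6.02214076e23 * 5e-5) * 1e27) ** (1 / 3)
        assert side == pytest.approx(want)
        assert side == pytest.approx(998.7, abs=0.5)   # ~0.1 um box

    def test_zero_ligands_is_valid_and_inert(self):
        system, cfg, ff, rng = make_system(ligand_factor=0.0)
        scheme = ReactionScheme(eta=np.full(10, 1.0))
        for _ in range(5):
            step(system, cfg, ff, rng)
            attempt_reactions(system, scheme, rng)
        assert (system.reaction_counts == 0).all()

    def test_same_seed_reproduces_initial_state(self):
        a, *_ = make_system(copies=2, ligand_factor=1.0, seed=3)
        b, *_ = make_system(copies=2, ligand_factor=1.0, seed=3)
        assert np.array_equal(a.pos, b.pos)
        assert np.array_equal(a.rot, b.rot)
        assert np.array_equal(a.lig_pos, b.lig_pos)
        assert np.array_equal(a.vel, b.vel)

    def test_impossible_packing_raises(self):
        cfg = LangevinConfig(copies_per_type=100, concentration=1e-3,
                             confinement_radius=30.0, n_steps=1)
        with pytest.raises(RuntimeError, match="packing"):
            build_system(SpeciesSpec(), STRONG, cfg,
                         np.random.default_rng(0))

    def test_no_initial_core_overlaps(self):
        system, *_ = make_system(copies=3, ligand_factor=2.0, seed=5)
        d = np.linalg.norm(system.pos[:, None] - system.pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= system.species.sigma_enz


class TestStep:
    def test_zero_temperature_isolated_particle_is_stationary(self):
        system, cfg, ff, rng = make_system(temperature=1e-12)
        system.vel[:] = 0.0
        system.angvel[:] = 0.0
        # keep only one enzyme: far outside all cutoffs from the others
        system.pos[0] = system.pos[0]  # others untouched; check a particle
        iso = np.argmax(((system.pos - system.pos.mean(0)) ** 2).sum(1))
        before = system.pos[iso].copy()
        far = np.linalg.norm(system.pos - system.pos[iso], axis=1)
        if (np.sort(far)[1] if len(far) > 1 else np.inf) > 50.0:
            step(system, cfg, ff, rng)
            assert np.allclose(system.pos[iso], before)

    def test_energy_conserved_with_thermostat_off(self):
        """Velocity-Verlet limit: < 1% drift over 1e4 steps at 30 fs."""
        system, cfg, ff, rng = make_system(copies=1, conc=2e-3, seed=0)
        e0 = total_energy(system, ff, cfg)
        worst = 0.0
        for i in range(10_000):
            step(system, cfg, ff, rng, thermostat=False)
            if (i + 1) % 1000 == 0:
                worst = max(worst, abs(total_energy(system, ff, cfg) - e0))
        assert worst / abs(e0) < 0.01

    def test_equipartition_under_thermostat(self):
        """Translational kinetic energy per particle = (3/2) kT within 5%."""
        system, cfg, ff, rng = make_system(copies=2, conc=1e-3,
                                           ligand_factor=1.0, seed=1,
                                           energy=PPIEnergyMap.from_mfi(
                                               np.full((10, 10), 900.0)))
        for _ in range(2000):
            step(system, cfg, ff, rng)
        samples = []
        for i in range(3000):
            step(system, cfg, ff, rng)
            if i % 10 == 0:
                tr, _ = kinetic_energy(system, ff)
                samples.append(tr / (system.n_enzymes + system.n_ligands))
        assert np.mean(samples) == pytest.approx(1.5, rel=0.05)

    def test_free_diffusion_matches_einstein_relation(self):
        """Ensemble MSD of free ligands = 6 D t within 10%, D = kT/(6 pi eta a)."""
        cfg = LangevinConfig(copies_per_type=1, concentration=1e-9,
                             ligand_factor=15.0, n_steps=1, confine_frac=0.0,
                             confine_ligands=False)
        rng = np.random.default_rng(2)
        system = build_system(SpeciesSpec(), STRONG, cfg, rng)
        ff = Forcefield.build(SpeciesSpec(), STRONG, cfg)
        update_bonds(system)
        start = system.lig_pos_unwrapped.copy()
        n_steps = 12_000
        for _ in range(n_steps):
            step(system, cfg, ff, rng)
        msd = ((system.lig_pos_unwrapped - start) ** 2).sum(axis=1).mean()
        d_lig = cfg.kt / ff.gamma_lig
        assert msd == pytest.approx(6 * d_lig * n_steps * cfg.dt, rel=0.10)

    def test_excessive_displacement_raises_instability(self):
        system, cfg, ff, rng = make_system(copies=1)
        system.vel[:] = 1.0   # 30 A per step
        with pytest.raises(Instability, match="timestep"):
            step(system, cfg, ff, rng, thermostat=False)


class TestReactions:
    def _bound_pair(self):
        """One enzyme with its cognate ligand held in the capture region."""
        system, cfg, ff, rng = make_system(copies=1, ligand_factor=1.0, seed=4)
        system.lig_state[:] = 99            # park all ligands out of play
        system.lig_bound[:] = -1
        _, act_pos = system.patch_positions()
        system.lig_state[0] = system.enz_type[0]
        system.lig_pos[0] = act_pos[0] + np.array([0.0, 0.0, 12.7])
        system.lig_bound[0] = 0
        return system, rng

    def test_zero_probability_never_fires(self):
        system, rng = self._bound_pair()
        scheme = ReactionScheme(eta=np.zeros(10))
        for _ in range(200):
            attempt_reactions(system, scheme, rng)
        assert (system.reaction_counts == 0).all()

    def test_unit_probability_fires_immediately(self):
        system, rng = self._bound_pair()
        scheme = ReactionScheme(eta=np.ones(10))
        fired = attempt_reactions(system, scheme, rng)
        k = system.enz_type[0]
        assert fired == 1 and system.reaction_counts[k] == 1
        assert system.lig_state[0] == k + 1
        assert system.lig_bound[0] == -1    # product leaves the site

    def test_waiting_time_is_geometric(self):
        """Attempts to conversion follow the geometric law with mean 1/q."""
        q = 0.1
        waits = []
        system, rng = self._bound_pair()
        k = system.enz_type[0]
        scheme = ReactionScheme(eta=np.full(10, q))
        for rep in range(600):
            system.lig_state[0] = k
            system.lig_bound[0] = 0
            n = 0
            while True:
                n += 1
                if attempt_reactions(system, scheme, rng):
                    break
            waits.append(n)
        waits = np.asarray(waits)
        assert waits.mean() == pytest.approx(1 / q, rel=0.15)
        # chi-square against the geometric distribution, pooled tail
        edges = [1, 2, 3, 5, 8, 13, 21, np.inf]
        observed = np.histogram(waits, bins=edges)[0]
        cdf = lambda n: 1 - (1 - q) ** n
        expected = np.diff([cdf(e - 1) if np.isfinite(e) else 1.0 for e in edges])
        expected = np.array(expected) * len(waits)
        keep = expected > 4
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert stats.chi2.sf(chi2, keep.sum() - 1) > 0.01

    def test_ligand_count_and_counter_bookkeeping(self):
        cfg = desk_config(copies_per_type=2, n_steps=4000)
        scheme = ReactionScheme.sample(seed=3, p_scale=50.0)
        summary = run(cfg, scheme, STRONG, mode="ppi_on", seed=6)
        assert (np.diff(summary.reaction_counts_t, axis=0) >= 0).all()
        # the cascade is strictly sequential: a ligand reaches step k only
        # through step k-1, so cumulative counts are non-increasing in k
        counts = summary.reaction_counts
        for k in range(1, len(counts)):
            assert counts[k] <= counts[k - 1]


class TestRunAndAnalysis:
    def test_run_is_bit_deterministic(self):
        cfg = desk_config(copies_per_type=2, n_steps=1500)
        scheme = ReactionScheme.sample(seed=1, p_scale=50.0)
        a = run(cfg, scheme, STRONG, mode="ppi_on", seed=9)
        b = run(cfg, scheme, STRONG, mode="ppi_on", seed=9)
        assert np.array_equal(a.reaction_counts_t, b.reaction_counts_t)
        assert a.cluster_size_hist == b.cluster_size_hist

    def test_ppi_off_is_invariant_to_the_mfi_matrix(self):
        cfg = desk_config(copies_per_type=2, n_steps=800)
        scheme = ReactionScheme.sample(seed=1)
        weak = PPIEnergyMap.from_mfi(np.full((10, 10), 100.0))
        a = run(cfg, scheme, STRONG, mode="ppi_off", seed=2)
        b = run(cfg, scheme, weak, mode="ppi_off", seed=2)
        assert np.array_equal(a.reaction_counts_t, b.reaction_counts_t)

    def test_strong_matrix_increases_mean_cluster_size(self):
        """Paired seeds: clusters grow when PPI wells are turned on."""
        cfg = desk_config(copies_per_type=3, n_steps=12_000, dt=15.0,
                          confine_frac=0.5, confinement_radius=50.0)
        scheme = ReactionScheme.sample(seed=1)
        wins = 0
        for seed in range(5):
            on = run(cfg, scheme, STRONG, mode="ppi_on", seed=seed)
            off = run(cfg, scheme, STRONG, mode="ppi_off", seed=seed)
            mean = lambda h: (sum(k * v for k, v in h.items())
                              / max(sum(h.values()), 1))
            size_on = sum(k * k * v for k, v in on.cluster_size_hist.items()) \
                / sum(k * v for k, v in on.cluster_size_hist.items())
            size_off = sum(k * k * v for k, v in off.cluster_size_hist.items()) \
                / sum(k * v for k, v in off.cluster_size_hist.items())
            wins += size_on > size_off
        assert wins >= 4

    def test_cluster_frame_matches_networkx_components(self):
        import networkx as nx

        rng = np.random.default_rng(12)
        n = 40
        box = 300.0
        pos = rng.uniform(0, box, size=(n, 3))
        types = rng.integers(0, 10, size=n)
        labels, sizes, contact, comps = cluster_frame(pos, types, box, cutoff=20.0)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i] - pos[j]
                d -= box * np.round(d / box)
                if np.linalg.norm(d) <= 20.0:
                    g.add_edge(i, j)
        want = sorted(sorted(c) for c in nx.connected_components(g))
        got = sorted(sorted(np.where(labels == lab)[0].tolist())
                     for lab in np.unique(labels))
        assert got == want
        assert sum(k * v for k, v in sizes.items()) == n

    def test_all_far_apart_gives_singletons(self):
        pos = np.array([[0.0, 0, 0], [100.0, 0, 0], [0, 100.0, 0]])
        _, sizes, _, comps = cluster_frame(pos, np.array([0, 1, 2]), 1000.0)
        assert sizes == {1: 3} and comps == []

    def test_chain_of_three_is_one_cluster(self):
        pos = np.array([[0.0, 0, 0], [15.0, 0, 0], [30.0, 0, 0]])
        labels, sizes, _, comps = cluster_frame(pos, np.array([0, 1, 2]), 1000.0)
        assert sizes == {3: 1}
        assert len(comps) == 1 and comps[0].sum() == 3

    def test_flux_ratio_identities(self):
        cfg = desk_config(copies_per_type=2, n_steps=300)
        scheme = ReactionScheme.sample(seed=1)
        s = run(cfg, scheme, STRONG, mode="ppi_on", seed=1)
        ratios = flux_ratio(s, s)
        for k, c in enumerate(s.reaction_counts):
            if c > 0:
                assert ratios[k] == 1.0
            else:
                assert np.isnan(ratios[k])
        other = run(cfg, scheme, STRONG, mode="ppi_on", seed=2)
        off = other
        off.reaction_counts = np.zeros_like(off.reaction_counts)
        on = s
        on.reaction_counts = np.ones_like(on.reaction_counts)
        assert np.isinf(flux_ratio(on, off)).all()

    def test_mismatched_schemes_rejected(self):
        cfg = desk_config(copies_per_type=2, n_steps=300)
        a = run(cfg, ReactionScheme.sample(seed=1), STRONG, seed=1)
        b = run(cfg, ReactionScheme.sample(seed=2), STRONG, seed=1)
        with pytest.raises(ValueError, match="schemes"):
            flux_ratio(a, b)

    def test_morse_depth_monotonicity_of_contacts(self):
        """Deepening one pair's well does not reduce its mean contact count."""
        mfi = np.full((10, 10), 100.0)
        weak = PPIEnergyMap.from_mfi(mfi)
        mfi2 = mfi.copy()
        mfi2[0, 1] = mfi2[1, 0] = 1200.0
        strong = PPIEnergyMap.from_mfi(mfi2)
        cfg = desk_config(copies_per_type=3, n_steps=8000, dt=15.0,
                          confine_frac=0.5, confinement_radius=60.0)
        scheme = ReactionScheme.sample(seed=1)
        wins = 0
        for seed in range(5):
            a = run(cfg, scheme, strong, mode="ppi_on", seed=seed)
            b = run(cfg, scheme, weak, mode="ppi_on", seed=seed)
            wins += a.contact_matrix[0, 1] >= b.contact_matrix[0, 1]
        assert wins >= 4

    def test_valence_diagnostic_on_handbuilt_dimer(self):
        system, *_ = make_system(copies=1, conc=1e-6, seed=0)
        # aim enzymes 0 and 1 at each other, patches in bonding range
        system.rot[:] = np.eye(3)
        # park bystanders on a sparse grid far from the dimer
        for i in range(system.n_enzymes):
            system.pos[i] = np.array([1000.0 + 100.0 * i, 1000.0, 1000.0])
        system.pos[0] = np.array([100.0, 100.0, 100.0])
        system.rot[1] = np.diag([1.0, -1.0, -1.0])   # patch points -z
        system.pos[1] = system.pos[0] + np.array([0.0, 0.0, 17.056 + 5.4])
        v = ppi_valence(system)
        assert v[0] == 1 and v[1] == 1 and v[2:].sum() == 0
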