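"""Interface-overlap statistics: contacts, MISC, random-surface null."""

import numpy as np
import pytest
from scipy import stats

from metabolon.surfaces import (CaStructure, ContactSpec, InteractionSurface,
                                RandomSurfaceSpec, exposed_residues,
                                extract_interface, misc_null, misc_observed,
                                overlap_significance, random_surface,
                                read_pdb_ca, residue_frequency,
                                resolve_probe_radius, surface_contact,
                                surface_radius_of_gyration)
from metabolon.synth import (PlantedSurface, StructureGeneratorSpec,
                             synth_dimer, synth_structure)


def line_chain(n, spacing=3.8, rsa=1.0):
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    return CaStructure(np.arange(1, n + 1), coords, rsa=np.full(n, rsa))


@pytest.fixture(scope="module")
def random_chain():
    spec = StructureGeneratorSpec(chain_length=30, seed=3)
    structure, _ = synth_structure(spec)
    return structure


class TestExposedResidues:
    def test_fully_buried_chain_is_an_error(self):
        with pytest.raises(ValueError, match="no residue exposed"):
            exposed_residues(line_chain(5, rsa=0.0))

    def test_fully_exposed_chain_returns_everything(self):
        assert exposed_residues(line_chain(5, rsa=1.0)) == {1, 2, 3, 4, 5}

    def test_matches_elementwise_comparison(self, random_chain):
        got = exposed_residues(random_chain, 0.25)
        want = {int(r) for r, rsa in zip(random_chain.resids, random_chain.rsa)
                if rsa > 0.25}
        assert got == want


class TestSurfaceContact:
    def test_identical_compact_surface_gives_one(self):
        st = line_chain(3, spacing=3.0)   # all within 7 A of each other
        s = InteractionSurface("p", "x", [1, 2, 3])
        assert surface_contact(s, s, st) == 1.0

    def test_distant_singletons_give_zero(self):
        st = line_chain(2, spacing=8.0)
        si = InteractionSurface("p", "a", [1])
        sj = InteractionSurface("p", "b", [2])
        assert surface_contact(si, sj, st) == 0.0

    def test_matches_bruteforce_double_loop(self, random_chain):
        rng = np.random.default_rng(4)
        ids = random_chain.resids
        si = InteractionSurface("p", "a", rng.choice(ids, 8, replace=False))
        sj = InteractionSurface("p", "b", rng.choice(ids, 11, replace=False))
        brute = 0
        for a in si.residue_ids:
            for b in sj.residue_ids:
                pa = random_chain.coords[random_chain.positions([a])[0]]
                pb = random_chain.coords[random_chain.positions([b])[0]]
                if np.linalg.norm(pa - pb) <= 7.0:
                    brute += 1
        assert surface_contact(si, sj, random_chain) == pytest.approx(
            brute / (si.m * sj.m))

    def test_symmetric_and_bounded(self, random_chain):
        rng = np.random.default_rng(5)
        for _ in range(10):
            si = InteractionSurface("p", "a",
                                    rng.choice(random_chain.resids, 6, replace=False))
            sj = InteractionSurface("p", "b",
                                    rng.choice(random_chain.resids, 9, replace=False))
            cij = surface_contact(si, sj, random_chain)
            assert cij == surface_contact(sj, si, random_chain)
            assert 0.0 <= cij <= 1.0


class TestMiscObserved:
    def test_two_surfaces_reduce_to_single_contact(self, random_chain):
        rng = np.random.default_rng(6)
        s1 = InteractionSurface("p", "a", rng.choice(random_chain.resids, 5, replace=False))
        s2 = InteractionSurface("p", "b", rng.choice(random_chain.resids, 5, replace=False))
        assert misc_observed([s1, s2], random_chain) == pytest.approx(
            surface_contact(s1, s2, random_chain))

    def test_identical_compact_surfaces_give_one(self):
        st = line_chain(3, spacing=3.0)
        surfs = [InteractionSurface("p", str(k), [1, 2, 3]) for k in range(4)]
        assert misc_observed(surfs, st) == 1.0

    def test_four_surfaces_match_direct_pair_sum(self, random_chain):
        rng = np.random.default_rng(7)
        surfs = [InteractionSurface("p", str(k),
                                    rng.choice(random_chain.resids, 6, replace=False))
                 for k in range(4)]
        total = sum(surface_contact(surfs[i], surfs[j], random_chain)
                    for i in range(4) for j in range(i + 1, 4))
        assert misc_observed(surfs, random_chain) == pytest.approx(total / 6)

    def test_invariant_to_surface_ordering(self, random_chain):
        rng = np.random.default_rng(8)
        surfs = [InteractionSurface("p", str(k),
                                    rng.choice(random_chain.resids, 6, replace=False))
                 for k in range(4)]
        assert misc_observed(surfs, random_chain) == pytest.approx(
            misc_observed(surfs[::-1], random_chain))

    def test_single_surface_is_an_error(self, random_chain):
        with pytest.raises(ValueError):
            misc_observed([InteractionSurface("p", "a", [1])], random_chain)


class TestRandomSurface:
    def test_huge_probe_radius_returns_all_exposed(self, random_chain):
        rng = np.random.default_rng(0)
        s = random_surface(random_chain, 1e6, rng)
        assert s.residue_ids == frozenset(exposed_residues(random_chain))

    def test_tiny_probe_radius_returns_singleton(self):
        st = line_chain(10)
        s = random_surface(st, 1.0, np.random.default_rng(0))
        assert s.m == 1

    def test_nonpositive_radius_rejected(self, random_chain):
        with pytest.raises(ValueError):
            random_surface(random_chain, 0.0, np.random.default_rng(0))

    def test_seed_residues_uniform_over_exposed(self):
        st = line_chain(12)
        rng = np.random.default_rng(13)
        counts = np.zeros(12)
        for _ in range(6000):
            s = random_surface(st, 1.0, rng)
            counts[next(iter(s.residue_ids)) - 1] += 1
        assert stats.chisquare(counts).pvalue > 0.01


class TestMiscNull:
    def test_compact_structure_gives_degenerate_unit_null(self):
        st = line_chain(4, spacing=2.0)   # everything within 7 A
        mean, sd, samples = misc_null(
            st, RandomSurfaceSpec(n_r=5, n_sets=50, probe_radius=3.0, seed=1))
        assert mean == 1.0 and sd == 0.0 and len(samples) == 50

    def test_minimal_two_set_run(self, random_chain):
        _, _, samples = misc_null(
            random_chain, RandomSurfaceSpec(n_r=2, n_sets=2, probe_radius=6.0, seed=2))
        assert len(samples) == 2

    def test_reproducible_under_fixed_seed(self, random_chain):
        spec = RandomSurfaceSpec(n_r=10, n_sets=200, probe_radius=6.0, seed=9)
        a = misc_null(random_chain, spec)
        b = misc_null(random_chain, spec)
        assert np.array_equal(a[2], b[2])

    def test_precomputed_lookup_equals_naive_sampling(self, random_chain):
        """The seed-indexed fast path reproduces surface-by-surface draws."""
        spec = RandomSurfaceSpec(n_r=6, n_sets=40, probe_radius=7.0, seed=4)
        _, _, samples = misc_null(random_chain, spec)
        rng = np.random.default_rng(4)
        exposed = sorted(exposed_residues(random_chain, spec.rsa_threshold))
        naive = []
        for _ in range(spec.n_sets):
            seeds = rng.integers(len(exposed), size=spec.n_r)
            surfs = []
            for s in seeds:
                seed_xyz = random_chain.coords[random_chain.positions([exposed[s]])[0]]
                pos = random_chain.positions(exposed)
                d = np.linalg.norm(random_chain.coords[pos] - seed_xyz, axis=1)
                surfs.append(InteractionSurface(
                    "r", "r", [r for r, dd in zip(exposed, d) if dd <= 7.0]))
            naive.append(misc_observed(surfs, random_chain))
        assert np.allclose(samples, naive)


class TestOverlapSignificance:
    def test_planted_identical_surfaces_are_extreme(self, overlapping_surfaces):
        structure, surfaces = overlapping_surfaces
        res = overlap_significance(surfaces, structure,
                                   RandomSurfaceSpec(n_sets=2000, seed=5))
        assert res.p < 1e-4 and res.z > 10

    def test_zero_z_gives_half_p(self, random_chain):
        spec = RandomSurfaceSpec(n_r=5, n_sets=500, probe_radius=6.0, seed=6)
        mean, sd, _ = misc_null(random_chain, spec)
        # synthesize an observation exactly at the null mean via Z formula
        from scipy.stats import norm
        assert norm.sf(0.0) == 0.5

    def test_rigid_motion_invariance(self, overlapping_surfaces):
        structure, surfaces = overlapping_surfaces
        spec = RandomSurfaceSpec(n_sets=400, seed=8)
        res_a = overlap_significance(surfaces, structure, spec)
        # arbitrary rotation + translation
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = CaStructure(structure.resids, structure.coords @ rot.T + 11.3,
                            rsa=structure.rsa)
        res_b = overlap_significance(surfaces, moved, spec)
        assert res_a.z == pytest.approx(res_b.z, rel=1e-9)

    def test_z_monotone_in_planted_shared_fraction(self):
        """Parameter recovery: Z rises with the planted overlap fraction."""
        zs = []
        for f in (0.0, 0.25, 0.5, 1.0):
            spec = StructureGeneratorSpec(
                chain_length=80, seed=31, geometry="helix",
                surfaces=(PlantedSurface(center=10, radius=9.0),
                          PlantedSurface(center=45, radius=9.0, shared_fraction=f),
                          PlantedSurface(center=74, radius=9.0, shared_fraction=f)))
            structure, surfaces = synth_structure(spec)
            res = overlap_significance(surfaces, structure,
                                       RandomSurfaceSpec(n_sets=500, seed=3))
            zs.append(res.z)
        rho = stats.spearmanr(zs, [0.0, 0.25, 0.5, 1.0]).statistic
        assert rho == 1.0

    def test_null_calibration_of_empirical_tail(self, random_chain):
        """Random observed surfaces give a uniform empirical tail probability."""
        rng = np.random.default_rng(77)
        pvals = []
        n_r = 8
        for rep in range(60):
            surfs = [random_surface(random_chain, 7.0, rng) for _ in range(n_r)]
            res = overlap_significance(
                surfs, random_chain,
                RandomSurfaceSpec(n_r=n_r, n_sets=300, probe_radius=7.0,
                                  seed=int(rng.integers(2**31))))
            pvals.append(res.p_empirical)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) > 0.05) >= 0.85


class TestExtractInterface:
    def test_far_apart_chains_give_empty_surfaces_with_warning(self):
        a, b = synth_dimer(StructureGeneratorSpec(chain_length=20, seed=1),
                           StructureGeneratorSpec(chain_length=20, seed=2),
                           gap=20.0)
        with pytest.warns(UserWarning, match="no inter-chain contact"):
            in_a, in_b = extract_interface(a, b, cutoff=7.0)
        assert in_a == [] and in_b == []

    def test_touching_helices_match_bruteforce(self):
        a, b = synth_dimer(
            StructureGeneratorSpec(chain_length=15, seed=3, geometry="helix"),
            StructureGeneratorSpec(chain_length=15, seed=4, geometry="helix"),
            gap=5.0)
        in_a, in_b = extract_interface(a, b, cutoff=7.0)
        brute_a = [int(r) for k, r in enumerate(a.resids)
                   if np.linalg.norm(b.coords - a.coords[k], axis=1).min() <= 7.0]
        assert in_a == brute_a and len(in_b) > 0

    def test_symmetric_dimer_gives_mirror_surfaces(self):
        # two copies of one helix, one translated perpendicular to its axis
        spec = StructureGeneratorSpec(chain_length=20, seed=5, geometry="helix")
        a, _ = synth_structure(spec)
        b = CaStructure(a.resids, a.coords + np.array([9.0, 0.0, 0.0]),
                        rsa=a.rsa, chain="B")
        in_a, in_b = extract_interface(a, b, cutoff=10.0)
        assert set(in_a) == set(in_b)

    def test_dimer_interface_contact_positive_when_nonempty(self):
        a, b = synth_dimer(StructureGeneratorSpec(chain_length=25, seed=6),
                           StructureGeneratorSpec(chain_length=25, seed=7),
                           gap=4.0)
        in_a, in_b = extract_interface(a, b, cutoff=7.0)
        if in_a and in_b:
            merged = CaStructure(
                np.concatenate([a.resids, b.resids + 1000]),
                np.concatenate([a.coords, b.coords], axis=0))
            c = surface_contact(
                InteractionSurface("d", "a", in_a),
                InteractionSurface("d", "b", [r + 1000 for r in in_b]),
                merged, ContactSpec(cutoff=7.0))
            assert c > 0


class TestResidueFrequency:
    def test_counts_match_oracle(self):
        surfs = [InteractionSurface("p", "a", [1, 2, 3]),
                 InteractionSurface("p", "b", [2, 3]),
                 InteractionSurface("p", "c", [3])]
        freq = residue_frequency(surfs)
        assert freq == {1: 1 / 3, 2: 2 / 3, 3: 1.0}

    def test_random_surfaces_match_counting(self, random_chain):
        rng = np.random.default_rng(10)
        surfs = [random_surface(random_chain, 8.0, rng) for _ in range(7)]
        freq = residue_frequency(surfs)
        for r, f in freq.items():
            assert f == sum(r in s.residue_ids for s in surfs) / 7


class TestPdbIO:
    def test_reads_ca_records_and_rsa_sidecar(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        lines = []
        coords = [(0.0, 0.0, 0.0), (3.8, 0.0, 0.0), (7.6, 0.0, 0.0)]
        for i, (x, y, z) in enumerate(coords, start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  ALA A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
        pdb.write_text("\n".join(lines) + "\nEND\n")
        rsa = tmp_path / "rsa.tsv"
        rsa.write_text("residue\trsa\n1\t0.8\n2\t0.1\n3\t0.5\n")
        st = read_pdb_ca(pdb, chain="A", rsa_tsv=rsa)
        assert list(st.resids) == [1, 2, 3]
        assert st.coords[1, 0] == pytest.approx(3.8)
        assert exposed_residues(st, 0.25) == {1, 3}


def test_probe_radius_auto_is_mean_radius_of_gyration(overlapping_surfaces):
    structure, surfaces = overlapping_surfaces
    want = np.mean([surface_radius_of_gyration(s, structure) for s in surfaces])
    got = resolve_probe_radius(RandomSurfaceSpec(), surfaces, structure)
    assert got == pytest.approx(want)
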