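"""Energy terms: analytic forces, invariances and term-specific anchors."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import foldswitchlab as fsl
from foldswitchlab import energy as E
from foldswitchlab import params
from foldswitchlab.chain import ReferenceState, StructureError, \
    build_distance_matrix
from foldswitchlab.cv import compute_qdiff


@pytest.fixture(scope="module")
def mem_lib(toy_pair):
    return E.build_memory_library(toy_pair.ref_a)


@pytest.fixture(scope="module")
def bias(qdiff_spec):
    return E.UmbrellaBias(q0=0.5, spec=qdiff_spec)


TERM_BUILDERS = {
    "backbone": lambda c, p, lib, b: E.build_model(c, terms=("backbone",)),
    "contact": lambda c, p, lib, b: E.build_model(c, terms=("contact",)),
    "burial": lambda c, p, lib, b: E.build_model(c, terms=("burial",)),
    "hbond": lambda c, p, lib, b: E.build_model(c, terms=("hbond",)),
    "memory": lambda c, p, lib, b: E.build_model(c, terms=(), memory=lib),
    "umbrella": lambda c, p, lib, b: E.build_model(c, terms=(), umbrella=b),
    "restraint": lambda c, p, lib, b: E.build_model(
        c, terms=(), restraint=E.SeparationRestraint((1, 10), (20, 33),
                                                     min_dist=60.0, k=8.0)),
    "full": lambda c, p, lib, b: E.build_model(c, memory=lib, umbrella=b),
}


class TestForces:
    @pytest.mark.parametrize("term", sorted(TERM_BUILDERS))
    def test_analytic_forces_match_finite_differences(self, term, toy_pair,
                                                      mem_lib, bias):
        coil = fsl.sample_random_coil(toy_pair.sequence, seed=42)
        model = TERM_BUILDERS[term](coil, toy_pair, mem_lib, bias)
        err = E.finite_difference_check(model, n_probe=45, seed=7)
        assert err < 1e-5

    @pytest.mark.parametrize("term", sorted(TERM_BUILDERS))
    def test_rigid_motion_invariance(self, term, toy_pair, mem_lib, bias):
        coil = fsl.sample_random_coil(toy_pair.sequence, seed=43)
        model = TERM_BUILDERS[term](coil, toy_pair, mem_lib, bias)
        e0 = model.energy().total
        rot = Rotation.from_euler("zyx", [33, 75, -12], degrees=True)
        pos = coil.bead_positions()
        moved = rot.apply(pos) + np.array([5.0, -3.0, 11.0])
        e1 = model.energy(moved).total
        assert e1 == pytest.approx(e0, abs=1e-8 * max(1, abs(e0)))

    def test_net_force_is_zero(self, toy_pair, mem_lib, bias):
        coil = fsl.sample_random_coil(toy_pair.sequence, seed=44)
        model = E.build_model(coil, memory=mem_lib, umbrella=bias)
        _, F, _ = model.energy_forces()
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-9)


class TestBackbone:
    def test_stretched_bond_costs_harmonic_increment(self, helix18):
        e0, _, _ = E.eval_backbone(helix18)
        pos = helix18.bead_positions().copy()
        # stretch the terminal CA-CA bond by 1.0 Å along its axis
        u = pos[17] - pos[16]
        u /= np.linalg.norm(u)
        pos[17] += u  # only the (16, 17) CA bond and attached O/CB change?
        model = E.build_model(helix18, terms=("backbone",))
        bd0 = model.energy()
        bd1 = model.energy(pos)
        dk = bd1.detail["bonds"] - bd0.detail["bonds"]
        # CA(17) participates in CA-CA, CA-CB, CA-O and O(16)-CA(17) bonds;
        # moving only CA(17) stretches all four.  Verify the CA-CA part
        # explicitly with a two-bead system instead:
        assert dk > 0.5 * E.DEFAULT_CONSTANTS.bond_k * 1.0 ** 2 * 0.99

    def test_overlapping_beads_repel(self):
        from dataclasses import replace
        chain = fsl.build_ideal_helix(8)
        pos = chain.bead_positions().copy()
        pos[4] = pos[0] + np.array([1.0, 0.0, 0.0])  # CA 1 Å from CA
        # excluded volume in isolation (bond/chirality/basin switched off)
        consts = replace(E.DEFAULT_CONSTANTS, bond_k=0.0, chir_k=0.0,
                         basin_eps=0.0)
        model = E.build_model(chain, consts, terms=("backbone",))
        bd = model.energy(pos)
        assert bd.detail["excluded"] > 10.0
        _, F, _ = model.energy_forces(pos)
        # repulsive force along the separation vector
        d = pos[4] - pos[0]
        assert np.dot(F[4], d) > 0

    def test_ideal_helix_near_backbone_minimum(self, helix18):
        model = E.build_model(helix18, terms=("backbone",))
        bd, F, _ = model.energy_forces()
        assert bd.detail["bonds"] == pytest.approx(0.0, abs=1e-8)
        assert bd.detail["chirality"] == 0.0
        assert bd.detail["excluded"] == 0.0
        # relaxing from the ideal geometry barely moves it
        from foldswitchlab.sampling import (SimulationConfig,
                                            TemperatureSchedule, run_langevin)
        sim = SimulationConfig(n_steps=4000, seed=1, output_stride=4000,
                               schedule=TemperatureSchedule.constant(1.0))
        traj = run_langevin(helix18, model, sim)
        assert fsl.best_fit_rmsd(traj.final_chain, helix18) < 0.7

    def test_mirror_geometry_penalized(self, helix18):
        model = E.build_model(helix18, terms=("backbone",))
        bd0 = model.energy()
        pos = helix18.bead_positions().copy()
        pos[:, 0] *= -1.0  # mirror image flips the chirality determinant
        bd1 = model.energy(pos)
        assert bd1.detail["chirality"] > bd0.detail["chirality"] + 1.0


class TestContact:
    def test_hydrophobic_pair_more_favorable_than_charged(self):
        gamma = params.contact_matrix()
        aa = params.AMINO_ACIDS
        assert gamma[aa.index("I"), aa.index("L")] < \
            gamma[aa.index("K"), aa.index("K")]

    def test_pair_beyond_outer_switch_contributes_zero(self):
        chain = fsl.build_ideal_helix(8, "LLLLLLLL")
        ca = np.zeros((8, 3))
        ca[:, 0] = 30.0 * np.arange(8)  # everything far apart
        pos = chain.with_coordinates(ca, ca + [0, 1.53, 0],
                                     ca + [0, 0, 2.4]).bead_positions()
        model = E.build_model(chain, terms=("contact",))
        assert model.energy(pos).contact == 0.0

    def test_total_matches_brute_force_pair_sum(self, toy_pair):
        coil = fsl.sample_random_coil(toy_pair.sequence, seed=50)
        e, _, _ = E.eval_contact(coil)
        gamma = params.contact_matrix()
        aa = params.AMINO_ACIDS
        c = E.DEFAULT_CONSTANTS
        from foldswitchlab._kernels import _well
        expected = 0.0
        n = coil.n_residues
        for i in range(n):
            for j in range(i + 3, n):
                r = np.linalg.norm(coil.cb_xyz[i] - coil.cb_xyz[j])
                g = c.contact_scale * gamma[aa.index(coil.sequence[i]),
                                            aa.index(coil.sequence[j])]
                expected += g * _well(r, *c.contact_well1)[0]
                expected += c.contact_second_scale * g * \
                    _well(r, *c.contact_well2)[0]
        assert e == pytest.approx(expected, rel=1e-9)


class TestBurial:
    def test_extended_chain_sits_in_low_density_class(self):
        seq = "ILKEILKEILKEILKE"
        chain = fsl.build_ideal_helix(16, seq)
        ca = np.zeros((16, 3))
        ca[:, 0] = 3.8 * np.arange(16)
        ext = chain.with_coordinates(ca, ca + [0, 1.53, 0], ca + [0, 0, 2.4])
        e, _, _ = E.eval_burial(ext)
        gam = params.burial_propensities()
        types = params.residue_type_indices(seq)
        # densities ~0 -> only the low-density well is occupied
        expected = gam[types, 0].sum()
        assert e == pytest.approx(expected, rel=0.05)

    def test_buried_hydrophobic_beats_isolated(self):
        seq = "I" + "A" * 11
        chain = fsl.build_ideal_helix(12, seq)
        pos = chain.bead_positions().copy()
        n = 12
        # pack 6 CB beads around residue 0's CB
        rng = np.random.default_rng(0)
        for k in range(1, 7):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos[n + 2 + k] = pos[n + 0] + 5.0 * direction
        model = E.build_model(chain, terms=("burial",))
        dense = model.energy(pos).burial
        pos_iso = pos.copy()
        pos_iso[n + 0] += np.array([200.0, 0, 0])
        pos_iso[0] += np.array([200.0, 0, 0])
        isolated = model.energy(pos_iso).burial
        assert dense < isolated


class TestHbond:
    def test_ideal_helix_has_helical_not_sheet_energy(self, helix18):
        bd = E.build_model(helix18, terms=("hbond",)).energy()
        assert bd.detail["hbond_additive"] < -1.0
        assert abs(bd.detail["hbond_cooperative"]) < 1e-3

    def test_three_rung_ladder_activates_cooperativity(self):
        # 4-residue strands give 3 usable consecutive rungs (the chain's
        # first residue has no reconstructible amide N)
        ladder = fsl.build_beta_meander(11, 2, turn_len=3)
        bd = E.build_model(ladder, terms=("hbond",)).energy()
        assert bd.detail["hbond_cooperative"] < -1e-4

    def test_two_rung_ladder_has_zero_cooperativity(self):
        # hand-built 2-residue strands: no triplet of consecutive rungs
        from foldswitchlab.synth import _finish_chain
        ca = np.array([[0.0, 0, 0], [3.3, 0, 0],
                       [6.3, 1.8, 0], [7.0, 5.0, 0], [6.3, 8.2, 0],
                       [3.3, 9.7, 0], [0.0, 9.7, 0]])
        chain = _finish_chain(ca, "AAAAAAA")
        bd = E.build_model(chain, terms=("hbond",)).energy()
        assert bd.detail["hbond_cooperative"] == 0.0


class TestMemory:
    def test_reference_attains_analytic_minimum(self, toy_pair, mem_lib):
        bd = E.build_model(toy_pair.state_a, terms=(),
                           memory=mem_lib).energy()
        expected = -sum(mem_lib.lambda_memory * f.weight * f.n_pairs
                        for f in mem_lib.fragments)
        assert bd.memory == pytest.approx(expected, rel=1e-9)
        # any perturbed configuration is higher
        coil = fsl.sample_random_coil(toy_pair.sequence, seed=51)
        bd2 = E.build_model(coil, terms=(), memory=mem_lib).energy()
        assert bd2.memory > bd.memory

    def test_single_pair_displaced_by_sigma(self):
        chain = fsl.build_ideal_helix(12)
        frag = E.MemoryFragment(
            start=1, length=3,
            res_i=np.array([0]), res_j=np.array([2]),
            kind_i=np.array([0]), kind_j=np.array([0]),
            target=np.array([5.0]), weight=1.0)
        lib = E.MemoryLibrary([frag], lambda_memory=0.3)
        sigma = 2 ** 0.15
        ca = chain.ca_xyz.copy()
        ca[2] = ca[0] + [5.0 + sigma, 0, 0]
        pos = chain.with_coordinates(ca, chain.cb_xyz,
                                     chain.o_xyz).bead_positions()
        bd = E.build_model(chain, terms=(), memory=lib).energy(pos)
        assert bd.memory == pytest.approx(-0.3 * np.exp(-0.5), rel=1e-9)

    def test_dual_identical_memory_doubles_energy(self, toy_pair, mem_lib):
        single = E.build_model(toy_pair.state_a, terms=(), memory=mem_lib)
        dual = E.build_model(toy_pair.state_a, terms=(),
                             memory=[mem_lib, mem_lib])
        assert dual.energy().memory == \
            pytest.approx(2 * single.energy().memory, rel=1e-12)

    def test_library_tiling(self, toy_pair):
        ref = toy_pair.ref_a
        lib = E.build_memory_library(ref, regions=[(1, 9)])
        assert len(lib.fragments) == 1
        lib = E.build_memory_library(ref, regions=[(1, 12)])
        assert len(lib.fragments) == 4
        assert [f.start for f in lib.fragments] == [1, 2, 3, 4]

    def test_linker_region_gets_no_fragments(self, anchored_pair):
        a0, a1 = anchored_pair.anchor_range
        l0, l1 = anchored_pair.linker_range
        s0, s1 = anchored_pair.switch_range
        lib = E.build_memory_library(anchored_pair.ref_a,
                                     regions=[(a0, a1), (s0, s1)])
        linker = set(range(l0 - 1, l1))  # 0-based residues
        for frag in lib.fragments:
            covered = set(range(frag.start - 1, frag.start - 1 + frag.length))
            assert not covered & linker

    def test_invalid_fragments_rejected(self):
        with pytest.raises(StructureError):
            E.MemoryFragment(start=1, length=2, res_i=np.array([0]),
                             res_j=np.array([2]), kind_i=np.array([0]),
                             kind_j=np.array([0]), target=np.array([5.0]))
        with pytest.raises(StructureError):
            E.build_memory_library(
                ReferenceState("x", fsl.build_ideal_helix(10),
                               build_distance_matrix(
                                   fsl.build_ideal_helix(10))),
                regions=[(1, 2)])


class TestUmbrellaAndRestraint:
    def test_zero_at_center_and_quadratic_away(self, toy_pair, qdiff_spec):
        bias0 = E.UmbrellaBias(q0=1.0, spec=qdiff_spec, k=1500.0)
        e, F, _ = E.eval_umbrella(toy_pair.state_b, bias0)
        assert e == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(F, 0.0, atol=1e-9)
        bias = E.UmbrellaBias(q0=0.98, spec=qdiff_spec, k=1500.0)
        e, _, _ = E.eval_umbrella(toy_pair.state_b, bias)
        # Q_diff(state B) = 1 exactly: ½ · 1500 · 0.02² = 0.3 kcal/mol
        assert e == pytest.approx(0.3, rel=1e-9)

    def test_umbrella_parameter_validation(self, qdiff_spec):
        with pytest.raises(ValueError):
            E.UmbrellaBias(q0=0.5, spec=qdiff_spec, k=-1.0)
        with pytest.raises(ValueError):
            E.UmbrellaBias(q0=1.5, spec=qdiff_spec)

    def test_restraint_flat_bottom_and_closed_form(self, toy_pair):
        e, _, _ = E.eval_separation_restraint(
            toy_pair.state_a, (1, 14), (20, 33), min_dist=1.0, k_r=10.0)
        assert e == 0.0
        chain = toy_pair.state_a
        d = np.linalg.norm(chain.ca_xyz[:14].mean(axis=0)
                           - chain.ca_xyz[19:].mean(axis=0))
        e, F, _ = E.eval_separation_restraint(
            chain, (1, 14), (20, 33), min_dist=d + 2.0, k_r=10.0)
        assert e == pytest.approx(0.5 * 10.0 * 4.0, rel=1e-9)
        # Newton's third law: group force sums equal and opposite
        n = chain.n_residues
        fa = F[:14].sum(axis=0)
        fb = F[19:n].sum(axis=0)
        np.testing.assert_allclose(fa, -fb, atol=1e-9)
        axis = (chain.ca_xyz[:14].mean(axis=0)
                - chain.ca_xyz[19:].mean(axis=0))
        cos = fa @ axis / np.linalg.norm(fa) / np.linalg.norm(axis)
        assert abs(cos) == pytest.approx(1.0, abs=1e-9)

    def test_overlapping_restraint_groups_rejected(self, toy_pair):
        with pytest.raises(StructureError):
            E.SeparationRestraint((1, 20), (15, 33))


class TestTotal:
    def test_single_term_equals_total(self, coil):
        bd = E.build_model(coil, terms=("backbone",)).energy()
        assert bd.total == bd.backbone

    def test_breakdown_sums_to_total(self, toy_pair, mem_lib, bias):
        for seed in range(10):
            coil = fsl.sample_random_coil(toy_pair.sequence, 600 + seed)
            bd, _, _ = E.total_energy(coil, memory=mem_lib, umbrella=bias)
            s = (bd.backbone + bd.contact + bd.burial + bd.hbond + bd.memory
                 + bd.umbrella + bd.restraint)
            assert bd.total == pytest.approx(s, rel=1e-12)

    def test_qdiff_reported_matches_cv_module(self, toy_pair, qdiff_spec,
                                              mem_lib):
        coil = fsl.sample_random_coil(toy_pair.sequence, seed=61)
        model = E.build_model(coil, memory=mem_lib, qdiff_spec=qdiff_spec)
        _, _, qd = model.energy_forces()
        assert qd == pytest.approx(compute_qdiff(coil, qdiff_spec),
                                   abs=1e-10)
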