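import numpy as np
import pytest

from tetherloc import synthetic_data as sd
from tetherloc.ensemble import (
    EnsembleMember,
    TetherSpec,
    convergence,
    generate_ensemble,
    placement_spread,
    score_ensemble,
    select_best,
)
from tetherloc.structio import RigidTransform
from tetherloc.xlink import CrosslinkRecord, CrosslinkSet


@pytest.fixture(scope="module")
def setup():
    core, mobile, truth = sd.make_toy_complex(
        sd.ToyComplexSpec(n_core_residues=60, n_mobile_residues=40, seed=7)
    )
    spec = TetherSpec(core_anchor=("A", 60), mobile_anchor=("B", 69))
    return core, mobile, truth, spec


@pytest.fixture(scope="module")
def members(setup):
    core, mobile, _, spec = setup
    return generate_ensemble(core, mobile, spec, n=200, seed=3)


@pytest.fixture(scope="module")
def links(setup):
    core, mobile, truth, _ = setup
    asm = sd.assemble(core, mobile, truth)
    return sd.simulate_crosslinks(
        asm, sd.XlinkSimSpec(n_true=15, max_true_distance=30.0, fp_fraction=0.0,
                             seed=5, interchain_only=True)
    )


class TestGenerate:
    def test_deterministic_given_seed(self, setup):
        core, mobile, _, spec = setup
        a = generate_ensemble(core, mobile, spec, n=1, seed=11)
        b = generate_ensemble(core, mobile, spec, n=1, seed=11)
        np.testing.assert_array_equal(a[0].placement.rotation, b[0].placement.rotation)
        np.testing.assert_array_equal(a[0].placement.translation,
                                      b[0].placement.translation)

    def test_constraints_hold_post_hoc(self, setup, members):
        core, mobile, _, spec = setup
        core_pts = core.ca_array()
        anchor = core.ca(*spec.core_anchor)
        m_anchor = mobile.ca(*spec.mobile_anchor)
        for m in members:
            placed = m.placement.apply(mobile.ca_array())
            assert np.linalg.norm(m.placement.apply(m_anchor) - anchor) <= spec.tether_max + 1e-9
            d = np.linalg.norm(core_pts[:, None] - placed[None, :], axis=2)
            assert d.min() >= spec.clash_min - 1e-9

    def test_free_mode_fills_the_tether_shell(self, setup):
        """The sampled anchor positions reach the analytic tether maximum."""
        core, mobile, _, _ = setup
        spec = TetherSpec(core_anchor=("A", 60), mobile_anchor=("B", 69), mode="free")
        ms = generate_ensemble(core, mobile, spec, n=5000, seed=9)
        anchor = core.ca(*spec.core_anchor)
        m_anchor = mobile.ca(*spec.mobile_anchor)
        dists = [np.linalg.norm(m.placement.apply(m_anchor) - anchor) for m in ms]
        assert max(dists) >= spec.tether_max * 0.98

    def test_infeasible_tether_raises(self, setup):
        core, mobile, _, _ = setup
        spec = TetherSpec(core_anchor=("A", 60), mobile_anchor=("B", 69),
                          n_linker_residues=0, per_residue_span=0.1,
                          clash_min=25.0)
        from tetherloc.ensemble import InfeasibleTetherError

        with pytest.raises(InfeasibleTetherError):
            generate_ensemble(core, mobile, spec, n=50, seed=1)

    def test_bad_anchor_rejected(self, setup):
        core, mobile, _, _ = setup
        spec = TetherSpec(core_anchor=("A", 999), mobile_anchor=("B", 69))
        with pytest.raises(ValueError):
            generate_ensemble(core, mobile, spec, n=1, seed=1)


class TestScore:
    def test_truth_placement_scores_zero(self, setup, links):
        core, mobile, truth, _ = setup
        member = EnsembleMember(0, truth)
        info = score_ensemble([member], core, mobile, links, cutoff=30.0)
        assert member.violations == 0
        assert member.mappable_restraints == info["n_restraints"]

    def test_cutoff_boundary_is_inclusive(self):
        from tetherloc.structio import Residue, StructureModel

        core = StructureModel("c", {"A": [
            Residue("A", i, "ALA", np.array([3.8 * i, 0.0, 0.0])) for i in range(1, 5)
        ]})
        mobile = StructureModel("m", {"B": [
            Residue("B", i, "ALA", np.array([3.8 * i, 30.0, 0.0])) for i in range(1, 5)
        ]})
        links = CrosslinkSet([CrosslinkRecord(("A", 1), ("B", 1), "d")])
        member = EnsembleMember(0, RigidTransform.identity())
        score_ensemble([member], core, mobile, links, cutoff=30.0)
        assert member.violations == 0  # distance exactly 30 → satisfied

    def test_violations_match_per_link_loop(self, setup, members, links):
        core, mobile, _, _ = setup
        score_ensemble(members, core, mobile, links, cutoff=30.0)
        nr = links.nonredundant("pooled")
        for m in members[::10]:
            brute = 0
            total = 0.0
            for rec in nr.records:
                ends = []
                for site in (rec.site_a, rec.site_b):
                    p = core.ca(*site)
                    if p is None:
                        p = m.placement.apply(mobile.ca(*site))
                    ends.append(p)
                d = np.linalg.norm(ends[0] - ends[1])
                total += d
                brute += d > 30.0
            assert m.violations == brute
            assert m.sum_restraint_distance == pytest.approx(total)

    def test_internal_links_excluded(self, setup, links):
        core, mobile, _, _ = setup
        with_internal = CrosslinkSet(
            list(links.records) + [CrosslinkRecord(("A", 1), ("A", 2), "d")]
        )
        member = EnsembleMember(0, RigidTransform.identity())
        info = score_ensemble([member], core, mobile, with_internal)
        assert info["n_internal_excluded"] == 1

    def test_unmappable_links_counted_once(self, setup, links):
        core, mobile, _, _ = setup
        odd = CrosslinkSet(
            list(links.records) + [CrosslinkRecord(("A", 1), ("Z", 999), "d")]
        )
        member = EnsembleMember(0, RigidTransform.identity())
        info = score_ensemble([member], core, mobile, odd)
        assert info["n_unmappable_excluded"] == 1

    def test_nothing_to_score_raises(self, setup):
        core, mobile, _, _ = setup
        internal_only = CrosslinkSet([CrosslinkRecord(("A", 1), ("A", 5), "d")])
        with pytest.raises(ValueError):
            score_ensemble([EnsembleMember(0, RigidTransform.identity())],
                           core, mobile, internal_only)

    def test_false_positive_never_lowers_violations(self, setup, members, links):
        core, mobile, truth, _ = setup
        score_ensemble(members, core, mobile, links)
        before = [m.violations for m in members]
        asm = sd.assemble(core, mobile, truth)
        fp = sd.simulate_crosslinks(
            asm, sd.XlinkSimSpec(n_true=1, max_true_distance=30.0, fp_fraction=1.0,
                                 seed=8, interchain_only=True)
        )
        fp_only = [r for r in fp.nonredundant().records
                   if np.linalg.norm(asm.ca(*r.site_a) - asm.ca(*r.site_b)) > 30.0]
        augmented = CrosslinkSet(list(links.records) + fp_only)
        score_ensemble(members, core, mobile, augmented)
        after = [m.violations for m in members]
        assert all(b >= a for a, b in zip(before, after))

    def test_score_invariant_under_global_rigid_motion(self, setup, links):
        core, mobile, truth, _ = setup
        member = EnsembleMember(0, truth)
        score_ensemble([member], core, mobile, links)
        ref = (member.violations, member.sum_restraint_distance)
        Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        g = RigidTransform(Rz, np.array([11.0, -3.0, 6.0]))
        member2 = EnsembleMember(0, g.compose(truth))
        score_ensemble([member2], core.transformed(g), mobile, links)
        assert member2.violations == ref[0]
        assert member2.sum_restraint_distance == pytest.approx(ref[1])


class TestSelect:
    def scored(self, triples):
        out = []
        for i, (v, s) in enumerate(triples):
            m = EnsembleMember(i, RigidTransform.identity())
            m.violations, m.sum_restraint_distance = v, s
            out.append(m)
        return out

    def test_all_equal_scores_tie_break_by_index(self):
        ms = self.scored([(1, 5.0)] * 6)
        assert [m.index for m in select_best(ms, 3)] == [0, 1, 2]

    def test_zero_violation_member_wins(self):
        ms = self.scored([(2, 1.0), (0, 99.0), (1, 0.5)])
        assert select_best(ms, 1)[0].index == 1

    def test_matches_full_sort_oracle(self, rng):
        ms = self.scored([
            (int(rng.integers(0, 5)), float(rng.uniform(10, 500))) for _ in range(100)
        ])
        got = [m.index for m in select_best(ms, 12)]
        oracle = sorted(ms, key=lambda m: (m.violations, m.sum_restraint_distance,
                                           m.index))[:12]
        assert got == [m.index for m in oracle]

    def test_k_beyond_n_warns_and_returns_all(self):
        ms = self.scored([(0, 1.0), (1, 2.0)])
        with pytest.warns(UserWarning):
            out = select_best(ms, 10)
        assert len(out) == 2


class TestConvergenceAndSpread:
    def test_jaccard_arithmetic(self):
        assert convergence({1, 2, 3}, {1, 2, 3}) == {"jaccard": 1.0, "identical": True}
        assert convergence({1, 2}, {3, 4})["jaccard"] == 0.0
        a = set(range(12))
        b = set(range(6, 18))
        assert convergence(a, b)["jaccard"] == pytest.approx(6 / 18)

    def test_duplicated_member_has_zero_spread(self, setup):
        core, mobile, truth, _ = setup
        ms = [EnsembleMember(0, truth), EnsembleMember(1, truth)]
        out = placement_spread(ms, mobile)
        assert out["mean_pairwise_rmsd"] == 0.0
        assert out["orientation_spread_deg"] == pytest.approx(0.0, abs=1e-4)

    def test_pure_rotation_about_centroid_reads_back(self, setup):
        core, mobile, _, _ = setup
        from scipy.spatial.transform import Rotation

        c = mobile.ca_array().mean(axis=0)
        R = Rotation.from_euler("z", 10, degrees=True).as_matrix()
        a = EnsembleMember(0, RigidTransform.identity())
        b = EnsembleMember(1, RigidTransform(R, c - R @ c))
        out = placement_spread([a, b], mobile)
        assert out["orientation_spread_deg"] == pytest.approx(10.0, abs=1e-6)

    def test_spread_matches_brute_force(self, setup, members):
        core, mobile, _, _ = setup
        sel = members[:5]
        out = placement_spread(sel, mobile)
        pts = mobile.ca_array()
        for i in range(5):
            for j in range(5):
                pi = sel[i].placement.apply(pts)
                pj = sel[j].placement.apply(pts)
                brute = np.sqrt(((pi - pj) ** 2).sum(axis=1).mean())
                assert out["rmsd_matrix"][i, j] == pytest.approx(brute)
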