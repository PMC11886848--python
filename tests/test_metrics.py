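"""Metric suite: rates, canonical-key bookkeeping, Wasserstein distances."""

import numpy as np
import pytest
from scipy.optimize import linprog

import ctrldiff as cd
from ctrldiff.metrics import (
    ReferenceStats,
    evaluate_molecules,
    is_connected,
    is_valid,
    w1_discrete,
)
from conftest import random_rotation, rotate_graph


def _w1_lp_oracle(a, b):
    """Optimal-transport linear program between two empirical samples."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    # constraints: row sums = 1/na, column sums = 1/nb
    A_eq = []
    b_eq = []
    for i in range(na):
        row = np.zeros(na * nb)
        row[i * nb : (i + 1) * nb] = 1
        A_eq.append(row)
        b_eq.append(1 / na)
    for j in range(nb):
        col = np.zeros(na * nb)
        col[j::nb] = 1
        A_eq.append(col)
        b_eq.append(1 / nb)
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=np.array(b_eq), method="highs")
    assert res.success
    return res.fun


class TestValidity:
    def test_minimal_fixtures_all_valid(self, minimal_set):
        assert cd.validity_rate(minimal_set) == 100.0

    def test_three_valid_one_pentavalent(self, minimal_set):
        mols = minimal_set[:3] + cd.generate_fixtures("invalid_valence")
        assert cd.validity_rate(mols) == 75.0

    def test_invalid_set_scores_zero(self):
        assert cd.validity_rate(cd.generate_fixtures("invalid_valence")) == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cd.validity_rate([])


class TestConnectivity:
    def test_ethane_counted(self, minimal_set):
        assert is_connected(minimal_set[3])

    def test_disconnected_fixture_not_counted(self):
        assert cd.connectivity_rate(cd.generate_fixtures("disconnected")) == 0.0

    def test_half_connected(self, minimal_set):
        mols = [minimal_set[3]] + cd.generate_fixtures("disconnected")
        assert cd.connectivity_rate(mols) == 50.0


class TestNovelty:
    def test_all_seen_is_zero(self, minimal_set):
        keys = {cd.canonical_key(m) for m in minimal_set}
        assert cd.novelty_rate(minimal_set, keys) == 0.0

    def test_disjoint_sets_fully_novel(self, minimal_set, chains_set):
        keys = {cd.canonical_key(m) for m in chains_set}
        assert cd.novelty_rate(minimal_set, keys) == 100.0

    def test_half_novel(self, minimal_set, chains_set):
        gen = minimal_set[:2] + chains_set[:2]
        keys = {cd.canonical_key(m) for m in chains_set}
        assert cd.novelty_rate(gen, keys) == 50.0

    def test_invalid_molecules_excluded_from_denominator(self, minimal_set):
        gen = minimal_set[:2] + cd.generate_fixtures("invalid_valence")
        keys = {cd.canonical_key(m) for m in minimal_set}
        assert cd.novelty_rate(gen, keys) == 0.0  # both valid molecules are known


class TestUniqueness:
    def test_four_copies_score_25(self, minimal_set):
        ethane = minimal_set[3]
        assert cd.uniqueness_rate([ethane.copy() for _ in range(4)]) == 25.0

    def test_distinct_fixtures_score_100(self, minimal_set):
        assert cd.uniqueness_rate(minimal_set) == 100.0

    def test_atom_permuted_copy_still_counts_as_duplicate(self, minimal_set, rng):
        ethane = minimal_set[3]
        perm = rng.permutation(ethane.n_atoms)
        assert cd.uniqueness_rate([ethane, ethane.permuted(perm)]) == 50.0


class TestBondAngle:
    def test_right_angle(self):
        assert cd.bond_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_collinear_gives_180(self):
        assert cd.bond_angle([-1, 0, 0], [0, 0, 0], [2, 0, 0]) == pytest.approx(180.0)

    def test_zero_length_bond_rejected(self):
        with pytest.raises(ValueError):
            cd.bond_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


class TestW1:
    def test_identical_samples_zero(self, rng):
        s = rng.normal(size=40)
        assert cd.w1_distance(s, s) == 0.0

    def test_point_masses_distance_d(self):
        assert cd.w1_distance([0.0], [2.5]) == pytest.approx(2.5)

    def test_matches_lp_oracle_on_random_samples(self, rng):
        for _ in range(10):
            a = rng.normal(size=50)
            b = rng.normal(loc=rng.normal(), size=50)
            assert cd.w1_distance(a, b) == pytest.approx(_w1_lp_oracle(a, b), abs=1e-8)

    def test_discrete_matches_lp_oracle(self, rng):
        support = np.array([0.0, 1.0, 1.5, 3.0, 4.0])
        for _ in range(10):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            # LP oracle over the discrete ground metric
            cost = np.abs(support[:, None] - support[None, :]).ravel()
            A_eq, b_eq = [], []
            for i in range(5):
                row = np.zeros(25)
                row[i * 5 : (i + 1) * 5] = 1
                A_eq.append(row)
                b_eq.append(p[i])
            for j in range(5):
                col = np.zeros(25)
                col[j::5] = 1
                A_eq.append(col)
                b_eq.append(q[j])
            res = linprog(cost, A_eq=np.array(A_eq), b_eq=np.array(b_eq), method="highs")
            assert w1_discrete(p, q, support) == pytest.approx(res.fun, abs=1e-8)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=20)
        assert cd.w1_distance(a, b) == pytest.approx(cd.w1_distance(b, a), abs=1e-12)


class TestValencyMetric:
    def test_self_reference_is_zero(self, minimal_set):
        ref = ReferenceStats.from_molecules(minimal_set)
        assert cd.valency_metric(minimal_set, ref) == 0.0

    def test_point_mass_shift_by_one(self):
        # reference: all-carbon valency 4 (methane C); generated: valency-3
        # carbon — W1 between the point masses is 1 for the C channel
        ref_mol = cd.generate_fixtures("minimal")[0]  # methane
        gen = ref_mol.copy()
        gen.bonds[0, 4] = gen.bonds[4, 0] = 0  # drop one C-H bond
        ref = ReferenceStats.from_molecules([ref_mol])
        only_c_gen = cd.Molecule3DGraph(
            gen.coords[:1], gen.atom_types[:1], gen.charges[:1], np.zeros((1, 1), dtype=int)
        )
        # a lone carbon (valency 0) against reference carbon valency 4 -> W1 = 4
        assert cd.valency_metric([only_c_gen], ref) == pytest.approx(4.0)

    def test_invariant_under_molecule_order(self, minimal_set, chains_set):
        ref = ReferenceStats.from_molecules(chains_set)
        a = cd.valency_metric(minimal_set, ref)
        b = cd.valency_metric(list(reversed(minimal_set)), ref)
        assert a == pytest.approx(b, abs=1e-12)

    def test_unseen_atom_type_warns_and_skips(self, minimal_set):
        ref = ReferenceStats.from_molecules([minimal_set[0]])  # C/H only
        with pytest.warns(UserWarning, match="absent from reference"):
            cd.valency_metric([minimal_set[1]], ref)  # water has O


class TestGeometryMetrics:
    def test_self_reference_is_zero(self, minimal_set):
        ref = ReferenceStats.from_molecules(minimal_set)
        bondlen, angle = cd.geometry_metrics(minimal_set, ref)
        assert bondlen == pytest.approx(0.0, abs=1e-12)
        assert angle == pytest.approx(0.0, abs=1e-12)

    def test_uniform_bond_stretch_shifts_w1_by_stretch(self):
        methane = cd.generate_fixtures("minimal")[0]
        stretched = methane.copy()
        stretched.coords = methane.coords * (1 + 0.1 / 1.09)  # all C-H +0.1 Å
        ref = ReferenceStats.from_molecules([methane])
        bondlen, _ = cd.geometry_metrics([stretched], ref)
        assert bondlen == pytest.approx(0.1, abs=1e-6)

    def test_methane_has_six_angles(self):
        methane = cd.generate_fixtures("minimal")[0]
        ref = ReferenceStats.from_molecules([methane])
        assert len(ref.angles) == 6  # C(4,2) pairs of bonds at the carbon
        assert np.allclose(ref.angles, 109.47122, atol=1e-3)

    def test_no_bonds_rejected(self):
        lone = cd.Molecule3DGraph(
            np.zeros((1, 3)), np.array([1]), np.array([1]), np.zeros((1, 1), dtype=int)
        )
        ref = ReferenceStats.from_molecules(cd.generate_fixtures("minimal"))
        with pytest.raises(ValueError, match="no bonds"):
            cd.geometry_metrics([lone], ref)


class TestEvaluate:
    def test_reference_against_itself(self, minimal_set, tmp_path):
        report = evaluate_molecules(minimal_set, minimal_set)
        assert report.validity_pct == 100.0
        assert report.connected_pct == 100.0
        assert report.novelty_pct == 0.0
        assert report.uniqueness_pct == 100.0
        assert report.valency_dist == pytest.approx(0.0, abs=1e-12)
        assert report.bondlen_dist == pytest.approx(0.0, abs=1e-12)
        assert report.angle_dist == pytest.approx(0.0, abs=1e-12)

    def test_minimal_vs_chains_fully_novel(self, minimal_set, chains_set):
        report = evaluate_molecules(minimal_set, chains_set)
        assert report.novelty_pct == 100.0

    def test_report_json_round_trip(self, minimal_set, tmp_path):
        report = evaluate_molecules(minimal_set, minimal_set)
        path = tmp_path / "report.json"
        report.to_json(path)
        back = cd.MetricsReport.from_json(path)
        assert back == report

    def test_sdf_entry_point(self, minimal_set, chains_set, tmp_path):
        gen_p, ref_p = tmp_path / "gen.sdf", tmp_path / "ref.sdf"
        cd.write_sdf(minimal_set, gen_p)
        cd.write_sdf(chains_set, ref_p)
        report = cd.evaluate(gen_p, ref_p, out_json=tmp_path / "r.json")
        assert report.n_evaluated == 5
        assert (tmp_path / "r.json").exists()

    def test_rates_invariant_under_rigid_motion_and_order(self, minimal_set, chains_set, rng):
        moved = []
        for mol in minimal_set:
            Q = random_rotation(rng)
            moved.append(rotate_graph(mol, Q, translation=rng.normal(size=3)))
        rng.shuffle(moved)
        a = evaluate_molecules(minimal_set, chains_set)
        b = evaluate_molecules(moved, chains_set)
        assert (a.validity_pct, a.connected_pct, a.novelty_pct, a.uniqueness_pct) == (
            b.validity_pct,
            b.connected_pct,
            b.novelty_pct,
            b.uniqueness_pct,
        )

    def test_report_percentages_validated(self):
        with pytest.raises(ValueError):
            cd.MetricsReport(101.0, 0, 0, 0, 0, 0, 0, n_evaluated=1)
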