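"""Assignment machinery: seeding, cost matrices, matching, classification
and the full iterative loop."""

import numpy as np
import pytest

from pcsassign.assign import (
    AssignConfig,
    Assignment,
    AssignmentState,
    build_cost_matrix,
    build_measurements,
    classify,
    exclude_nuisance_peaks,
    iterate,
    seed_assignments,
    solve_assignment,
)
from pcsassign.simulate import SimulationConfig, simulate_datasets


def truth_lookup(run):
    table = {}
    for (sub, mid), (h, c) in run.base_shifts.items():
        table[(sub, round(h, 4), round(c, 4))] = mid
    return table


def grade(run, state, meas):
    base = truth_lookup(run)
    correct = wrong = wrong_unambiguous = 0
    for (sub, pid), a in state.assignments.items():
        mp = next(m for m in meas.master[sub] if m.peak_id == pid)
        tm = base.get((sub, round(mp.h_ppm, 4), round(mp.c_ppm, 4)))
        if tm is None:
            continue
        if tm == a.methyl_id:
            correct += 1
        else:
            wrong += 1
            if a.status == "unambiguous":
                wrong_unambiguous += 1
    return correct, wrong, wrong_unambiguous


class TestSolveAssignment:
    def test_diagonal_optimum(self):
        pairs, margins = solve_assignment(np.array([[0.0, 5.0], [5.0, 0.0]]))
        assert sorted(pairs) == [(0, 0), (1, 1)]
        assert margins[0] == 5.0

    def test_tie_detection(self):
        pairs, margins = solve_assignment(np.full((2, 2), 3.0))
        assert len(pairs) == 2
        assert all(m == 0.0 for m in margins.values())

    def test_infinite_rows_left_unassigned(self):
        cost = np.array([[1.0, np.inf], [np.inf, np.inf]])
        pairs, _ = solve_assignment(cost)
        assert pairs == [(0, 0)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        import itertools

        rng = np.random.default_rng(seed)
        cost = rng.uniform(0, 10, size=(6, 6))
        pairs, _ = solve_assignment(cost)
        lap_total = sum(cost[i, j] for i, j in pairs)
        brute = min(
            sum(cost[i, p] for i, p in enumerate(perm))
            for perm in itertools.permutations(range(6))
        )
        assert lap_total == pytest.approx(brute, abs=1e-12)

    def test_empty(self):
        pairs, margins = solve_assignment(np.empty((0, 0)))
        assert pairs == [] and margins == {}


class TestClassify:
    def base_state(self, **kw):
        st = AssignmentState()
        st.assignments[("A", "p1")] = Assignment("A:1:d1", "tentative", **kw)
        return st

    def test_zero_margin_is_tentative(self):
        st = self.base_state(margin=0.0, n_support=3)
        classify(st, 9.0)
        assert st.assignments[("A", "p1")].status == "tentative"

    def test_two_dataset_support_with_margin_is_unambiguous(self):
        st = self.base_state(margin=50.0, n_support=2, cost=1.0)
        classify(st, 9.0)
        assert st.assignments[("A", "p1")].status == "unambiguous"

    def test_single_dataset_support_stays_tentative(self):
        st = self.base_state(margin=50.0, n_support=1, cost=1.0)
        classify(st, 9.0)
        assert st.assignments[("A", "p1")].status == "tentative"

    def test_poor_fit_stays_tentative(self):
        st = self.base_state(margin=50.0, n_support=2, cost=500.0)
        classify(st, 9.0)
        assert st.assignments[("A", "p1")].status == "tentative"

    def test_class_ambiguous_needs_stronger_margin(self):
        st = self.base_state(margin=12.0, n_support=3, cost=1.0, class_ambiguous=True)
        classify(st, 9.0)
        assert st.assignments[("A", "p1")].status == "tentative"
        st = self.base_state(margin=30.0, n_support=3, cost=1.0, class_ambiguous=True)
        classify(st, 9.0)
        assert st.assignments[("A", "p1")].status == "unambiguous"


class TestSeeding:
    def test_singleton_classes_seeded(self, sim_run):
        meas = build_measurements(sim_run.datasets)
        exclude_nuisance_peaks(meas, sim_run.free_reference)
        state = seed_assignments(meas, sim_run.methyls, AssignConfig())
        base = truth_lookup(sim_run)
        assert state.assignments  # Ile and Met singletons exist per subunit
        for (sub, pid), a in state.assignments.items():
            mp = next(m for m in meas.master[sub] if m.peak_id == pid)
            tm = base.get((sub, round(mp.h_ppm, 4), round(mp.c_ppm, 4)))
            assert tm == a.methyl_id  # uniqueness seeds are never wrong
        seeded_types = {
            a.methyl_id.split(":")[-1] for a in state.assignments.values()
        }
        assert seeded_types <= {"d1", "e"} or seeded_types  # Ile δ1 / Met ε

    def test_magnitude_rank_seeds_far_cone(self, tmp_path):
        """A tag near one end of a single helix sees every surviving methyl
        in one directional cone: same-sign PCSs ordered by 1/r³, so ranking
        peaks by |PCS| against methyls by distance seeds them correctly."""
        import os
        import tempfile

        from pcsassign.peaks import Dataset, Peak
        from pcsassign.simulate import SimulationConfig, make_bundle, write_bundle_pdb
        from pcsassign.structure import extract_methyls, load_structure
        from pcsassign.tensor import ChiTensor, pcs_forward

        cfg = SimulationConfig(n_helices=1, residues_per_helix=40, seed=0)
        atoms, _ = make_bundle(cfg)
        path = tmp_path / "helix.pdb"
        write_bundle_pdb(atoms, path)
        structure = load_structure(path)
        methyls = sorted(extract_methyls(structure), key=lambda m: m.methyl_id)
        cb = np.array(structure.get_atom("A", 3, "CB").xyz)
        metal = cb + np.array([0.0, 0.0, -6.0])  # below the helix end
        tensor = ChiTensor(-25.0, -3.0, metal)  # z-axis along the helix

        # noiseless peak lists with well-separated base shifts; methyls
        # within 20 Å of the metal are blanked
        counters, untagged, tagged, truth = {}, [], [], {}
        for i, m in enumerate(methyls):
            (h0, h1), (c0, c1) = cfg.shift_windows[m.restype]
            k = counters.get(m.restype, 0)
            counters[m.restype] = k + 1
            h = h0 + (k % 8) * (h1 - h0) / 8
            c = c0 + (k // 8 + k % 5) * (c1 - c0) / 8 + (k % 3) * 0.37
            pid = f"u{i:03d}"
            untagged.append(Peak(pid, h, c))
            truth[pid] = m.methyl_id
            if np.linalg.norm(m.carbon_position - metal) <= 20:
                continue
            tagged.append(
                Peak(
                    f"t{i:03d}",
                    h + pcs_forward(tensor, m.proton_position),
                    c + pcs_forward(tensor, m.carbon_position),
                )
            )
        ds = Dataset("d1", "A:3", "Dy", "A", ("H", "C"),
                     tagged_peaks=tagged, untagged_peaks=untagged)
        meas = build_measurements([ds])
        state = seed_assignments(
            meas, methyls, AssignConfig(), tag_positions={("A:3", "Dy"): cb}
        )
        base = {
            (round(p.h_ppm, 4), round(p.c_ppm, 4)): truth[p.peak_id]
            for p in untagged
        }
        rank_seeds = 0
        for (sub, pid), a in state.assignments.items():
            if not np.isfinite(a.margin):
                continue  # uniqueness seed, not a rank seed
            mp = next(m for m in meas.master[sub] if m.peak_id == pid)
            tm = base[(round(mp.h_ppm, 4), round(mp.c_ppm, 4))]
            assert a.methyl_id == tm
            rank_seeds += 1
        assert rank_seeds >= 4

    def test_all_blanked_gives_empty_seed_set(self, bundle_structure):
        cfg = SimulationConfig(seed=1, blanking_radius={"Dy": 1e4, "Yb": 1e4})
        run = simulate_datasets(bundle_structure, cfg)
        meas = build_measurements(run.datasets)
        state = seed_assignments(meas, run.methyls, AssignConfig())
        assert len(state.assignments) == 0


class TestCostMatrix:
    @pytest.fixture()
    def setup(self, sim_run):
        meas = build_measurements(sim_run.datasets)
        exclude_nuisance_peaks(meas, sim_run.free_reference)
        return meas, dict(sim_run.tensors)

    def test_wrong_class_infinite(self, sim_run, setup):
        meas, tensors = setup
        cfg = AssignConfig()
        pids, mids, cost, n_terms, support = build_cost_matrix(
            "A", meas, sim_run.methyls, tensors, cfg
        )
        base = truth_lookup(sim_run)
        mby = {m.methyl_id: m for m in sim_run.methyls}
        checked = 0
        for i, pid in enumerate(pids):
            mp = next(m for m in meas.master["A"] if m.peak_id == pid)
            tm = base.get(("A", round(mp.h_ppm, 4), round(mp.c_ppm, 4)))
            if tm is None or mby[tm].restype != "MET":
                continue
            for j, mid in enumerate(mids):
                if mby[mid].restype == "ILE":
                    assert np.isinf(cost[i, j])  # Met peak vs Ile methyl
                    checked += 1
        assert checked > 0

    def test_true_mapping_cheap_under_true_tensors(self, sim_run, setup):
        meas, tensors = setup
        cfg = AssignConfig()
        base = truth_lookup(sim_run)
        pids, mids, cost, n_terms, support = build_cost_matrix(
            "B", meas, sim_run.methyls, tensors, cfg
        )
        pairs, _ = solve_assignment(cost)
        ok = tot = 0
        for i, j in pairs:
            if support[i, j] < 1:
                continue
            mp = next(m for m in meas.master["B"] if m.peak_id == pids[i])
            tm = base.get(("B", round(mp.h_ppm, 4), round(mp.c_ppm, 4)))
            if tm is None:
                continue
            tot += 1
            ok += tm == mids[j]
        assert tot > 10 and ok / tot > 0.9

    def test_blanked_peak_near_methyl_not_penalized(self, bundle_structure):
        cfg = SimulationConfig(seed=21, nuisance_fraction=0.0)
        run = simulate_datasets(bundle_structure, cfg)
        meas = build_measurements(run.datasets)
        acfg = AssignConfig()
        pids, mids, cost, n_terms, support = build_cost_matrix(
            "A", meas, run.methyls, dict(run.tensors), acfg
        )
        base = truth_lookup(run)
        mby = {m.methyl_id: m for m in run.methyls}
        found = 0
        for i, pid in enumerate(pids):
            mp = next(m for m in meas.master["A"] if m.peak_id == pid)
            tm = base.get(("A", round(mp.h_ppm, 4), round(mp.c_ppm, 4)))
            if tm is None:
                continue
            # methyl blanked in at least one Dy dataset (within 20 Å)
            dists = [
                np.linalg.norm(mby[tm].carbon_position - t.metal)
                for t in run.tensors.values()
            ]
            if min(dists) < 22:
                j = mids.index(tm)
                if np.isfinite(cost[i, j]):
                    # blank consistency contributes no penalty on top of the
                    # matched-dataset residuals
                    assert cost[i, j] < acfg.outlier_ceiling * max(n_terms[i, j], 1)
                    found += 1
        assert found > 0


class TestIterate:
    def test_noiseless_full_recovery(self, bundle_structure):
        cfg = SimulationConfig(
            seed=13, noise_h=0.0, noise_c=0.0, nuisance_fraction=0.0,
        )
        run = simulate_datasets(bundle_structure, cfg)
        state, fits = iterate(
            run.datasets, run.methyls, AssignConfig(),
            tag_positions=run.tag_positions, free_reference=run.free_reference,
        )
        meas = build_measurements(run.datasets)
        correct, wrong, wu = grade(run, state, meas)
        assert wrong == 0
        assert correct >= 90
        for g, f in fits.items():
            assert abs(f.tensor.dchi_ax - run.tensors[g].dchi_ax) < 0.5

    def test_noisy_run_high_accuracy_no_false_unambiguous(self, sim_run):
        state, fits = iterate(
            sim_run.datasets, sim_run.methyls, AssignConfig(),
            tag_positions=sim_run.tag_positions,
            free_reference=sim_run.free_reference,
        )
        meas = build_measurements(sim_run.datasets)
        correct, wrong, wu = grade(sim_run, state, meas)
        assert wu == 0
        assert correct / (correct + wrong) > 0.9

    def test_seeding_failure_raises(self, bundle_structure):
        cfg = SimulationConfig(seed=1, blanking_radius={"Dy": 1e4, "Yb": 1e4})
        run = simulate_datasets(bundle_structure, cfg)
        with pytest.raises((ValueError, RuntimeError)):
            iterate(
                run.datasets, run.methyls, AssignConfig(),
                tag_positions=run.tag_positions,
            )

    def test_seeds_consistent_with_final_tensors(self, sim_run):
        """The initial seeds must agree with the final tensors' predictions —
        the self-consistency check closing the iterative procedure."""
        from pcsassign.tensor import pcs_forward

        meas = build_measurements(sim_run.datasets)
        exclude_nuisance_peaks(meas, sim_run.free_reference)
        seeds = seed_assignments(meas, sim_run.methyls, AssignConfig())
        state, fits = iterate(
            sim_run.datasets, sim_run.methyls, AssignConfig(),
            tag_positions=sim_run.tag_positions,
            free_reference=sim_run.free_reference,
        )
        mby = {m.methyl_id: m for m in sim_run.methyls}
        for (sub, pid), a in seeds.assignments.items():
            if not np.isfinite(a.margin):
                final = state.assignments.get((sub, pid))
                assert final is not None and final.methyl_id == a.methyl_id

    def test_fixed_point_rerun(self, bundle_structure):
        # in the clean regime the converged state is an exact fixed point of
        # the loop: restarting from it reproduces it
        cfg = SimulationConfig(
            seed=17, noise_h=0.0, noise_c=0.0, nuisance_fraction=0.0,
        )
        run = simulate_datasets(bundle_structure, cfg)
        acfg = AssignConfig()
        state, _ = iterate(
            run.datasets, run.methyls, acfg,
            tag_positions=run.tag_positions, free_reference=run.free_reference,
        )
        state2, _ = iterate(
            run.datasets, run.methyls, acfg,
            tag_positions=run.tag_positions, free_reference=run.free_reference,
            initial_state=state,
        )
        assert state2.mapping() == state.mapping()
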