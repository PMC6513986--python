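"""Loop perturbation, scoring, burial filtering, selection, refinement."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermogate import ensemble, geometry, synth
from thermogate.ensemble import (
    DecoyModel,
    RefinementConfig,
    convergence_metric,
    filter_by_delta_sasa,
    perturb_loops,
    run_refinement,
    select_top_by_energy,
    steric_energy,
)
from thermogate.synth import _structure_from_coords

from .oracles import brute_force_steric, filter_then_top_k, pairwise_rmsd_mean


def make_decoys(values, energies=None):
    base = _structure_from_coords(np.zeros((1, 3)), 1.7, np.array([1]))
    if energies is None:
        energies = range(len(values))
    return [DecoyModel(base, float(e), float(v), 1, i)
            for i, (v, e) in enumerate(zip(values, energies))]


class TestPerturbLoops:
    def test_zero_magnitude_is_identity(self, bundle):
        struct, loops = bundle
        out = perturb_loops(struct, loops, 0.0, seed=1)
        assert np.abs(out.coords - struct.coords).max() < 1e-9

    @pytest.mark.parametrize("seed", [2, 9, 17])
    def test_closure_and_nonloop_contract(self, bundle, seed):
        struct, loops = bundle
        out = perturb_loops(struct, loops, 0.4, seed=seed)
        chain, start, end = loops.segments[0]
        # anchors: backbone of the residue after the segment, every chain
        for ch in "ABCD":
            for nm in ("N", "CA", "C"):
                mask = ((struct.chain_ids == ch)
                        & (struct.res_ids == end + 1)
                        & (struct.atom_names == nm))
                d = np.linalg.norm(out.coords[mask] - struct.coords[mask])
                assert d <= 0.3 + 1e-9
        outside = (struct.res_ids < start) | (struct.res_ids > end)
        assert np.abs(out.coords[outside] - struct.coords[outside]).max() \
            < 1e-9

    def test_loop_rmsd_grows_with_magnitude(self, bundle):
        struct, loops = bundle
        chain, start, end = loops.segments[0]
        mask = ((struct.chain_ids == chain) & (struct.res_ids >= start)
                & (struct.res_ids <= end))
        means = []
        for mag in (0.1, 0.3, 1.0):
            rmsds = []
            for seed in range(40):
                try:
                    out = perturb_loops(struct, loops, mag, seed=seed)
                except ensemble.ClosureError:
                    continue
                d = out.coords[mask] - struct.coords[mask]
                rmsds.append(np.sqrt(np.mean(np.sum(d**2, axis=1))))
            means.append(np.mean(rmsds))
        assert means[0] < means[1] < means[2]

    def test_deterministic_per_seed(self, bundle):
        struct, loops = bundle
        a = perturb_loops(struct, loops, 0.3, seed=5)
        b = perturb_loops(struct, loops, 0.3, seed=5)
        assert np.array_equal(a.coords, b.coords)


class TestStericEnergy:
    def test_separated_atoms_zero_repulsion(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        s = _structure_from_coords(coords, 1.7, np.array([1, 5]))
        assert steric_energy(s) == 0.0

    def test_overlap_squared_closed_form(self):
        d = 0.6
        coords = np.array([[0.0, 0, 0], [1.7 + 1.7 - d, 0, 0]])
        s = _structure_from_coords(coords, 1.7, np.array([1, 5]))
        assert steric_energy(s) == pytest.approx(d**2, rel=1e-12)

    def test_bonded_neighbours_excluded(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        s = _structure_from_coords(coords, 1.7, np.array([1, 2]))
        assert steric_energy(s) == 0.0

    def test_ranking_matches_brute_force(self, bundle):
        struct, loops = bundle
        energies, brute = [], []
        for seed in range(8):
            try:
                out = perturb_loops(struct, loops, 0.5, seed=seed)
            except ensemble.ClosureError:
                continue
            energies.append(steric_energy(out))
            brute.append(brute_force_steric(out))
        np.testing.assert_allclose(energies, brute, rtol=1e-9)
        assert list(np.argsort(energies)) == list(np.argsort(brute))


class TestFilter:
    def test_strict_boundary(self):
        decoys = make_decoys([5.0, 19.9, 20.0, 20.1, 35.0])
        kept = filter_by_delta_sasa(decoys, threshold=20.0)
        assert [d.delta_sasa_at_marker for d in kept] == [20.1, 35.0]

    def test_threshold_zero_keeps_positives(self):
        decoys = make_decoys([0.5, 1.0, 7.0])
        assert len(filter_by_delta_sasa(decoys, threshold=1e-12)) == 3

    def test_empty_list_returns_empty(self):
        assert filter_by_delta_sasa([], threshold=20.0) == []

    def test_survivor_count_matches_oracle(self):
        decoys = synth.make_decoy_set(
            500, delta_sasa_distribution=(20.0, 5.0), seed=11)
        kept = filter_by_delta_sasa(decoys, threshold=20.0)
        truth = decoys[0].spec.params["burial"]
        assert len(kept) == int(np.sum(truth > 20.0))

    def test_computes_missing_burial_from_reference(self, bundle):
        struct, loops = bundle
        decoy_struct = perturb_loops(struct, loops, 0.3, seed=3)
        decoy = DecoyModel(decoy_struct, 0.0, None, 1, 0)
        kept = filter_by_delta_sasa([decoy], open_reference=struct,
                                    marker_site=loops.marker_site,
                                    threshold=-1000.0)
        assert decoy.delta_sasa_at_marker is not None
        assert len(kept) == 1


class TestSelection:
    def test_lowest_energy_selected(self):
        decoys = make_decoys([0, 0, 0], energies=[3.0, 1.0, 2.0])
        top = select_top_by_energy(decoys, 2)
        assert [d.energy for d in top] == [1.0, 2.0]

    def test_short_list_warns_and_returns_all(self):
        decoys = make_decoys([0, 0], energies=[1.0, 2.0])
        with pytest.warns(UserWarning, match="top-5"):
            top = select_top_by_energy(decoys, 5)
        assert len(top) == 2

    def test_matches_sort_prefix_oracle(self):
        decoys = synth.make_decoy_set(1000, seed=23)
        top = select_top_by_energy(decoys, 20)
        oracle = sorted(decoys, key=lambda d: (d.energy, d.decoy_id))[:20]
        assert [d.decoy_id for d in top] == [d.decoy_id for d in oracle]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-50, 80, allow_nan=False),
                              st.floats(-100, 100, allow_nan=False)),
                    min_size=1, max_size=60),
           st.floats(0.1, 40), st.integers(1, 25))
    def test_filter_plus_select_equals_oracle(self, pairs, threshold, k):
        """Composition of strict burial filter and top-k selection equals
        the sort-the-strict-pass-subset oracle on any decoy set."""
        values = [p[0] for p in pairs]
        energies = [p[1] for p in pairs]
        decoys = make_decoys(values, energies)
        survivors = filter_by_delta_sasa(decoys, threshold=threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = select_top_by_energy(survivors, k) if survivors else []
        expected = filter_then_top_k(values, energies,
                                     range(len(values)), threshold, k)
        assert [d.decoy_id for d in got] == expected


class TestConvergence:
    def test_identical_decoys_zero(self, bundle):
        struct, loops = bundle
        decoys = [DecoyModel(struct, 0.0, 0.0, 1, i) for i in range(3)]
        assert convergence_metric(decoys, loops) == 0.0

    def test_unit_translation_gives_one(self, bundle):
        struct, loops = bundle
        moved = struct.copy()
        moved.coords = struct.coords + np.array([1.0, 0.0, 0.0])
        decoys = [DecoyModel(struct, 0.0, 0.0, 1, 0),
                  DecoyModel(moved, 0.0, 0.0, 1, 1)]
        assert convergence_metric(decoys, loops) == pytest.approx(1.0)

    def test_matches_brute_force_pairwise(self, bundle):
        struct, loops = bundle
        decoys = []
        for seed in range(5):
            try:
                decoys.append(DecoyModel(
                    perturb_loops(struct, loops, 0.3, seed=seed),
                    0.0, 0.0, 1, seed))
            except ensemble.ClosureError:
                continue
        from thermogate.ensemble import _segment_backbone_mask
        mask = _segment_backbone_mask(decoys[0].structure, loops)
        oracle = pairwise_rmsd_mean([d.structure.coords[mask]
                                     for d in decoys])
        assert convergence_metric(decoys, loops) == pytest.approx(oracle,
                                                                  rel=1e-12)

    def test_single_decoy_errors(self, bundle):
        struct, loops = bundle
        with pytest.raises(ValueError):
            convergence_metric([DecoyModel(struct, 0.0, 0.0, 1, 0)], loops)


class TestRefinement:
    def test_single_round_final_model_passes_constraint(self, bundle):
        struct, loops = bundle
        cfg = RefinementConfig(loops=loops, n_per_round=40, n_rounds=1,
                               top_k=5, convergence_set_size=3, seed=3)
        res = run_refinement(struct, cfg)
        assert res.status == "completed"
        assert res.final_model.delta_sasa_at_marker \
            > cfg.delta_sasa_threshold

    def test_deterministic_per_seed_and_seed_sensitivity(self, bundle):
        struct, loops = bundle
        cfg = RefinementConfig(loops=loops, n_per_round=30, n_rounds=2,
                               top_k=5, convergence_set_size=3, seed=7)
        a = run_refinement(struct, cfg)
        b = run_refinement(struct, cfg)
        assert np.array_equal(a.final_model.structure.coords,
                              b.final_model.structure.coords)
        assert [r.selected_ids for r in a.rounds] \
            == [r.selected_ids for r in b.rounds]
        cfg2 = RefinementConfig(loops=loops, n_per_round=30, n_rounds=2,
                                top_k=5, convergence_set_size=3, seed=8)
        c = run_refinement(struct, cfg2)
        assert [r.selected_seeds for r in a.rounds] \
            != [r.selected_seeds for r in c.rounds]

    @pytest.mark.parametrize("seed", range(5))
    def test_best_energy_non_increasing(self, bundle, seed):
        struct, loops = bundle
        cfg = RefinementConfig(loops=loops, n_per_round=30, n_rounds=3,
                               top_k=5, convergence_set_size=3, seed=seed)
        res = run_refinement(struct, cfg)
        energies = [r.best_energy for r in res.rounds
                    if r.best_energy is not None]
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))
        if res.final_model is not None:
            assert res.final_model.delta_sasa_at_marker \
                > cfg.delta_sasa_threshold

    def test_impossible_constraint_stops_with_diagnostic(self, bundle):
        struct, loops = bundle
        cfg = RefinementConfig(loops=loops, n_per_round=5, n_rounds=3,
                               top_k=2, delta_sasa_threshold=1e6, seed=0)
        res = run_refinement(struct, cfg)
        assert res.status == "no-survivors"
        assert res.final_model is None
        assert len(res.rounds) == 1 and res.rounds[0].survivor_count == 0

    def test_production_defaults_echo_protocol(self, bundle):
        _, loops = bundle
        cfg = RefinementConfig(loops=loops)
        assert cfg.delta_sasa_threshold == 20.0
        assert cfg.top_k == 20
        assert cfg.n_rounds == 14
        assert cfg.convergence_set_size == 10
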