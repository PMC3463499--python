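"""Discretization, transitions, minimal sets, covariance and the pipeline."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnpipe import (
    ExpressionTimeCourse,
    GeneNetwork,
    InferenceError,
    ProbeMap,
    TransitionSet,
    combine_cov_msa,
    combine_msa_cov,
    covariance_adjacency,
    discretize,
    extract_transitions,
    generate_network,
    minimal_hitting_sets,
    minimal_sets,
    run_pipeline,
    select_model,
    simulate_timecourse,
)

from conftest import brute_force_minimal_hitting_sets


def _tc(rows, series_lengths=None, probes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    probes = probes or [f"p{k}" for k in range(rows.shape[0])]
    return ExpressionTimeCourse(
        probes=probes,
        values=rows,
        series_lengths=series_lengths or [rows.shape[1]],
    )


class TestDiscretize:
    def test_constant_series_maps_to_single_state(self):
        out = discretize(_tc([[5, 5, 5, 5]]), q=7)
        assert (out.values == 0).all()

    def test_strictly_increasing_series_gets_one_state_per_point(self):
        out = discretize(_tc([[1, 2, 3, 5, 8, 13, 21]]), q=7)
        assert list(out.values[0]) == [0, 1, 2, 3, 4, 5, 6]

    def test_equal_frequency_median_split(self):
        out = discretize(_tc([[1, 9, 2, 8]]), q=2)
        assert list(out.values[0]) == [0, 1, 0, 1]

    def test_fewer_distinct_values_than_q_warns_and_uses_fewer_states(self):
        with pytest.warns(UserWarning, match="fewer"):
            out = discretize(_tc([[1, 2, 1, 2]]), q=5)
        assert set(out.values[0]) == {0, 1}

    def test_equal_width_and_agglomerative_are_monotone(self):
        row = [0.0, 1.0, 1.1, 5.0, 9.9, 10.0]
        for method in ("equal-width", "agglomerative"):
            out = discretize(_tc([row]), q=3, method=method)
            codes = out.values[0]
            order = np.argsort(row)
            assert (np.diff(codes[order]) >= 0).all()
            assert codes.max() <= 2

    def test_separate_series_binning_is_per_series(self):
        tc = _tc([[1, 2, 101, 102]], series_lengths=[2, 2])
        joint = discretize(tc, q=2, joint_series=True)
        split = discretize(tc, q=2, joint_series=False)
        assert list(joint.values[0]) == [0, 0, 1, 1]
        assert list(split.values[0]) == [0, 1, 0, 1]

    def test_q_below_two_rejected(self):
        with pytest.raises(InferenceError):
            discretize(_tc([[1, 2, 3]]), q=1)


class TestExtractTransitions:
    def test_single_series_counts(self):
        dtc = discretize(_tc([np.arange(10)]), q=3)
        assert extract_transitions(dtc).n_transitions == 9

    def test_two_series_never_cross_boundary(self):
        dtc = discretize(_tc([np.arange(20)], series_lengths=[10, 10]), q=3)
        ts = extract_transitions(dtc)
        assert ts.n_transitions == 18
        assert all(t <= 8 for _, t in ts.origins)

    def test_length_two_series_yields_single_pair(self):
        dtc = discretize(_tc([[1.0, 4.0]]), q=2)
        ts = extract_transitions(dtc)
        assert ts.n_transitions == 1
        assert ts.inputs[0, 0] == 0 and ts.outputs[0, 0] == 1


class TestMinimalSets:
    def _ts(self, inputs, target_outputs):
        inputs = np.asarray(inputs)
        outputs = np.zeros_like(inputs)
        outputs[:, 0] = target_outputs
        probes = [f"x{k+1}" for k in range(inputs.shape[1])]
        return TransitionSet(
            probes=probes,
            inputs=inputs,
            outputs=outputs,
            origins=[(0, t) for t in range(len(inputs))],
        )

    def test_single_explanatory_variable(self):
        ts = self._ts([(0, 0, 0), (0, 1, 0), (1, 1, 0)], [0, 1, 1])
        fam = minimal_sets(ts, 0)
        assert fam.sets == [frozenset({1})]

    def test_minimal_set_excludes_redundant_variable(self):
        ts = self._ts([(0, 0, 0), (0, 1, 0), (1, 1, 0)], [0, 0, 1])
        fam = minimal_sets(ts, 0)
        assert fam.sets == [frozenset({0})]

    def test_constant_output_depends_on_nothing(self):
        ts = self._ts([(0, 0, 0), (1, 1, 0), (0, 1, 1)], [2, 2, 2])
        fam = minimal_sets(ts, 0)
        assert fam.sets == [frozenset()]

    def test_inconsistent_transitions_error_names_collision(self):
        ts = self._ts([(0, 0, 0), (0, 0, 0)], [0, 1])
        with pytest.raises(InferenceError, match="inconsistent"):
            minimal_sets(ts, 0)

    def test_lenient_mode_drops_later_conflict(self):
        ts = self._ts([(0, 0, 0), (0, 0, 0), (1, 0, 0)], [0, 1, 1])
        with pytest.warns(UserWarning, match="dropping"):
            fam = minimal_sets(ts, 0, lenient=True)
        assert fam.sets == [frozenset({0})]

    def test_family_matches_exhaustive_enumeration_on_random_systems(self):
        rng = np.random.default_rng(23)
        for _ in range(150):
            n_vars = int(rng.integers(2, 9))
            n_sets = int(rng.integers(1, 6))
            collection = []
            for _ in range(n_sets):
                size = int(rng.integers(1, n_vars + 1))
                collection.append(
                    frozenset(rng.choice(n_vars, size=size, replace=False).tolist())
                )
            expected = brute_force_minimal_hitting_sets(collection, n_vars)
            got = minimal_hitting_sets(collection)
            assert sorted(got, key=sorted) == sorted(expected, key=sorted)

    def test_family_is_antichain_and_hits_every_difference_set(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            n_probes, n_trans = 5, 12
            inputs = rng.integers(0, 2, size=(n_trans, n_probes))
            outputs = rng.integers(0, 2, size=(n_trans, n_probes))
            ts = TransitionSet(
                probes=[f"x{k}" for k in range(n_probes)],
                inputs=inputs,
                outputs=outputs,
                origins=[(0, t) for t in range(n_trans)],
            )
            try:
                fam = minimal_sets(ts, 0)
            except InferenceError:
                continue
            for a, b in itertools.combinations(fam.sets, 2):
                assert not (a <= b or b <= a)
            for i, j in itertools.combinations(range(n_trans), 2):
                if outputs[i, 0] != outputs[j, 0]:
                    diff = set(np.flatnonzero(inputs[i] != inputs[j]))
                    assert all(s & diff for s in fam.sets)

    def test_scores_are_normalized_and_favor_frequent_variables(self):
        # difference sets {a,b,c} and {b,d}: b hits both alone
        fam_sets = minimal_hitting_sets([frozenset({0, 1, 2}), frozenset({1, 3})])
        ts_like = minimal_sets  # noqa: F841  (documentational)
        from grnpipe import MinimalSetFamily

        fam = MinimalSetFamily(target=0, sets=fam_sets)
        assert sum(fam.set_scores.values()) == pytest.approx(1.0)
        assert fam.best() == frozenset({1})


class TestSelectModel:
    def _family(self, target, sets):
        from grnpipe import MinimalSetFamily

        return MinimalSetFamily(target=target, sets=[frozenset(s) for s in sets])

    def test_single_candidate_becomes_edge(self):
        net, prov = select_model([self._family(0, [{1}])], ["y", "x2"])
        assert net.entry("y", "x2") == 1
        assert prov["targets"]["y"]["chosen"] == ["x2"]

    def test_crosstalk_violating_candidate_discarded(self):
        modules = {"m": "mesoderm", "e": "ectoderm", "m2": "mesoderm"}
        net, prov = select_model(
            [self._family(0, [{1}, {2}])], ["m", "e", "m2"], modules
        )
        assert net.entry("m", "m2") == 1
        assert net.entry("m", "e") == 0
        assert prov["targets"]["m"]["discarded_by_crosstalk"] == [["e"]]

    def test_all_candidates_violating_keeps_family_with_warning(self):
        modules = {"m": "mesoderm", "e": "ectoderm"}
        with pytest.warns(UserWarning, match="relaxed"):
            net, _ = select_model([self._family(0, [{1}])], ["m", "e"], modules)
        assert net.entry("m", "e") == 1

    def test_empty_family_rejected(self):
        from grnpipe import MinimalSetFamily

        with pytest.raises(InferenceError):
            MinimalSetFamily(target=0, sets=[])


class TestCovariance:
    def test_hand_computed_example(self):
        tc = _tc([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]], probes=["p1", "p2", "p3"])
        net, threshold = covariance_adjacency(tc)
        assert threshold == pytest.approx(5 / 3)
        assert net.entry("p1", "p2") == -1
        assert net.entry("p2", "p1") == -1
        assert net.entry("p1", "p3") == 0
        assert net.entry("p2", "p3") == 0

    def test_identical_probes_are_coupled(self):
        tc = _tc([[1, 5, 2, 7], [1, 5, 2, 7], [3, 3, 4, 3]])
        net, _ = covariance_adjacency(tc)
        assert net.entry("p0", "p1") == -1

    def test_output_is_symmetric(self):
        rng = np.random.default_rng(31)
        tc = _tc(rng.normal(size=(6, 12)))
        net, _ = covariance_adjacency(tc)
        assert (net.adjacency == net.adjacency.T).all()

    def test_at_least_half_of_cells_reach_median_threshold(self):
        rng = np.random.default_rng(37)
        tc = _tc(rng.normal(size=(5, 9)))
        net, _ = covariance_adjacency(tc)
        n_cells = net.n_nodes**2
        assert (net.adjacency == -1).sum() >= n_cells / 2


class TestCombiners:
    def _nets(self, msa_entries, cov_entries, probes=("a", "b")):
        probes = list(probes)
        n = len(probes)
        msa = np.zeros((n, n))
        cov = np.zeros((n, n))
        for i, j in msa_entries:
            msa[i, j] = 1
        for i, j in cov_entries:
            cov[i, j] = -1
            cov[j, i] = -1
        return (
            GeneNetwork(probes, msa),
            GeneNetwork(probes, cov, validate=False),
        )

    def test_msa_cov_keeps_msa_edge_without_cov_support(self):
        msa, cov = self._nets([(0, 1)], [])
        out = combine_msa_cov(msa, cov)
        assert out.entry("a", "b") == 1

    def test_msa_cov_adds_undirected_only_without_either_direction(self):
        msa, cov = self._nets([], [(0, 1)])
        out = combine_msa_cov(msa, cov)
        assert out.entry("a", "b") == out.entry("b", "a") == -1
        msa2, cov2 = self._nets([(1, 0)], [(0, 1)])
        out2 = combine_msa_cov(msa2, cov2)
        assert out2.entry("b", "a") == 1
        assert out2.entry("a", "b") == 0

    def test_undirected_self_loops_discarded(self):
        probes = ["a", "b"]
        msa = GeneNetwork(probes, np.zeros((2, 2)))
        cov = GeneNetwork(probes, np.array([[-1.0, 0.0], [0.0, 0.0]]), validate=False)
        out = combine_msa_cov(msa, cov)
        assert out.entry("a", "a") == 0

    def test_cov_msa_requires_cov_support_for_directed_edge(self):
        msa, cov = self._nets([(0, 1)], [(0, 1)])
        assert combine_cov_msa(cov, msa).entry("a", "b") == 1
        msa2, cov2 = self._nets([(0, 1)], [])
        assert combine_cov_msa(cov2, msa2).entry("a", "b") == 0  # COV vetoes

    def test_cov_msa_reverse_only_msa_direction_gives_absent(self):
        msa, cov = self._nets([(1, 0)], [(0, 1)])
        out = combine_cov_msa(cov, msa)
        assert out.entry("a", "b") == 0
        assert out.entry("b", "a") == 1

    def test_dimension_mismatch_rejected(self):
        msa, _ = self._nets([], [])
        _, cov = self._nets([], [], probes=("a", "b", "c"))
        with pytest.raises(InferenceError):
            combine_msa_cov(msa, cov)

    def test_combined_collapse_uses_unanimity(self):
        probes = ["a1", "a2", "b"]
        pm = ProbeMap({"a1": "A", "a2": "A", "b": "B"})
        msa = np.zeros((3, 3))
        msa[2, 0] = 1  # b <- a1 only
        out = combine_msa_cov(
            GeneNetwork(probes, msa),
            GeneNetwork(probes, np.zeros((3, 3)), validate=False),
            probe_map=pm,
        )
        assert out.entry("B", "A") == 0


class TestPipeline:
    def test_deterministic_under_fixed_seed(self):
        gt = generate_network(8, density=0.2, q=3, seed=3)
        tc, _ = simulate_timecourse(gt, T=12, n_series=2, seed=4)
        a, prov_a = run_pipeline(tc, q=3, module_map=gt.network.module_map, seed=11)
        b, prov_b = run_pipeline(tc, q=3, module_map=gt.network.module_map, seed=11)
        assert a == b
        assert prov_a == prov_b

    def test_cov_msa_directed_edges_subset_of_msa_cov(self):
        for seed in range(5):
            gt = generate_network(8, density=0.2, q=3, seed=seed)
            tc, _ = simulate_timecourse(gt, T=15, n_series=2, seed=seed + 100)
            kwargs = dict(q=3, module_map=gt.network.module_map, seed=0)
            mc, _ = run_pipeline(tc, order="msa-cov", **kwargs)
            cm, _ = run_pipeline(tc, order="cov-msa", **kwargs)
            assert set(cm.directed_edges()) <= set(mc.directed_edges())

    def test_noise_free_families_contain_subset_of_true_parents(self):
        from grnpipe.inference import discretize as _disc

        for seed in range(5):
            gt = generate_network(8, density=0.2, q=3, seed=seed)
            tc, _ = simulate_timecourse(gt, T=15, n_series=2, noise_sd=0.0, seed=seed + 50)
            ts = extract_transitions(_disc(tc, q=3))
            for i, node in enumerate(gt.nodes):
                fam = minimal_sets(ts, i)
                assert any(set(s) <= set(gt.parents[node]) for s in fam.sets)

    def test_provenance_records_parameters_and_choices(self):
        gt = generate_network(6, density=0.2, q=3, seed=9)
        tc, _ = simulate_timecourse(gt, T=10, n_series=2, seed=10)
        net, prov = run_pipeline(tc, q=3, module_map=gt.network.module_map, seed=1)
        assert prov["order"] == "msa-cov"
        assert prov["n_transitions"] == 18
        assert set(prov["msa"]["targets"]) == set(gt.nodes)
        assert "covariance_threshold" in prov
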