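"""The deterministic IG + combined-mAUC structure search."""

import itertools

import numpy as np
import pytest

from helpers import dataset_from, is_direct

import dbnelicit as dl
from dbnelicit.info_scores import information_gain
from dbnelicit.structure_search import (
    InfeasibleCombo,
    SearchConfig,
    best_parent_sets_for_target,
    expand_time2_closure,
    preselect_candidates,
    reduce_to_strongest,
    run_search,
    select_best_structure,
    strongest_interacting_subsets,
)
from dbnelicit.synthetic import make_planted_model, planted_recovery_model, sample_dataset
from dbnelicit.variables import Slice, VariableSpec, message_spec, quantile3, target_spec

TARGET = "intention_change"


def _sorted_sets(mapping):
    return {k: tuple(sorted(v)) for k, v in mapping.items() if v}


class TestBestParentSets:
    def test_recovers_planted_pair_at_n2000(self):
        specs = (
            quantile3("a", Slice.TIME1), quantile3("b", Slice.TIME1),
            quantile3("c", Slice.TIME1), quantile3("d", Slice.TIME1),
            message_spec(), target_spec(),
        )
        model = make_planted_model(specs, {TARGET: ("a", "b")}, strength=0.9, seed=1)
        data = sample_dataset(model, 2000, seed=2)
        best = best_parent_sets_for_target(data, SearchConfig(target=TARGET, size_min=2, size_max=2))
        assert tuple(sorted(best[2])) == ("a", "b")

    def test_pool_of_exactly_k_variables(self):
        specs = (quantile3("a", Slice.TIME1), quantile3("b", Slice.TIME1), target_spec())
        model = make_planted_model(specs, {TARGET: ("a",)}, strength=0.5, seed=3)
        data = sample_dataset(model, 100, seed=4)
        best = best_parent_sets_for_target(data, SearchConfig(target=TARGET, size_min=2, size_max=2))
        assert best[2] == ("a", "b")

    def test_ig_monotone_in_size(self):
        model = planted_recovery_model(seed=5)
        data = sample_dataset(model, 500, seed=6)
        best = best_parent_sets_for_target(data, SearchConfig(target=TARGET, size_min=2, size_max=3))
        ig2 = information_gain(data, TARGET, best[2])
        ig3 = information_gain(data, TARGET, best[3])
        assert ig3 >= ig2 - 1e-12

    def test_pool_smaller_than_size_min_rejected(self):
        specs = (quantile3("a", Slice.TIME1), target_spec())
        model = make_planted_model(specs, {TARGET: ("a",)}, strength=0.5, seed=7)
        data = sample_dataset(model, 50, seed=8)
        with pytest.raises(ValueError, match="pool"):
            best_parent_sets_for_target(data, SearchConfig(target=TARGET, size_min=2, size_max=2))


class TestExpandTime2Closure:
    def test_all_time1_parents_need_no_expansion(self):
        model = planted_recovery_model(seed=9)
        data = sample_dataset(model, 200, seed=10)
        expanded = expand_time2_closure(data, TARGET, ("intention_t1", "t1_02"), 2)
        assert expanded == {}

    def test_planted_mediation_chain_recovered(self):
        model = planted_recovery_model(seed=11)
        data = sample_dataset(model, 2000, seed=12)
        expanded = expand_time2_closure(
            data, TARGET, ("evaluation", "threat", "intention_t1"), 3
        )
        assert _sorted_sets(expanded) == {
            "threat": ("message", "t1_02", "t1_03"),
            "evaluation": ("t1_04", "t1_05", "t1_06"),
        }

    def test_cycle_forming_candidate_excluded(self):
        # p and q are near-copies: each would pick the other first, but the
        # second expansion must avoid closing the cycle
        rng = np.random.default_rng(13)
        n = 600
        p = rng.integers(0, 3, n)
        noise = rng.integers(0, 3, n)
        q = np.where(rng.random(n) < 0.95, p, noise)
        a = np.where(rng.random(n) < 0.6, p, rng.integers(0, 3, n))
        b = np.where(rng.random(n) < 0.6, q, rng.integers(0, 3, n))
        t = rng.integers(0, 5, n)
        data = dataset_from(
            {"a": a, "b": b, "p": p, "q": q, "t": t},
            {"a": 3, "b": 3, "p": 3, "q": 3, "t": 5},
            {"a": Slice.TIME1, "b": Slice.TIME1,
             "p": Slice.TIME2, "q": Slice.TIME2, "t": Slice.TARGET},
        )
        expanded = expand_time2_closure(data, "t", ("p", "q"), 2)
        assert "q" in expanded["p"] or "p" in expanded["q"]
        assert not ("q" in expanded["p"] and "p" in expanded["q"])

    def test_infeasible_when_pool_too_small(self):
        specs = (quantile3("a", Slice.TIME1), quantile3("m", Slice.TIME2), target_spec())
        model = make_planted_model(specs, {TARGET: ("m",), "m": ("a",)}, strength=0.5, seed=14)
        data = sample_dataset(model, 100, seed=15)
        with pytest.raises(InfeasibleCombo):
            expand_time2_closure(data, TARGET, ("m",), 3)


class TestPreselect:
    def test_grid_size_and_common_size_constraint(self):
        model = planted_recovery_model(seed=16)
        data = sample_dataset(model, 400, seed=17)
        candidates, audit = preselect_candidates(
            data, SearchConfig(target=TARGET, size_min=2, size_max=3)
        )
        assert 1 <= len(candidates) <= 4
        for cand in candidates:
            t2_sizes = {
                len(ps) for nm, ps in cand.parent_sets.items() if nm != TARGET
            }
            assert t2_sizes <= {cand.size_combo[1]}
            assert len(cand.parent_sets[TARGET]) == cand.size_combo[0]

    def test_planted_combo_attains_max_total_ig(self):
        model = planted_recovery_model(seed=18)
        data = sample_dataset(model, 5000, seed=19)
        candidates, _ = preselect_candidates(
            data, SearchConfig(target=TARGET, size_min=2, size_max=3)
        )
        by_ig = max(candidates, key=lambda c: c.total_ig)
        assert by_ig.size_combo == (3, 3)


class TestSelectBest:
    def test_single_candidate_selected_trivially(self):
        model = planted_recovery_model(seed=20)
        data = sample_dataset(model, 300, seed=21)
        cfg = SearchConfig(target=TARGET, size_min=3, size_max=3)
        candidates, _ = preselect_candidates(data, cfg)
        result = select_best_structure(data, candidates[:1], cfg)
        assert result.best_index == 0

    def test_dominant_candidate_wins(self):
        model = planted_recovery_model(seed=22)
        data = sample_dataset(model, 2000, seed=23)
        cfg = SearchConfig(target=TARGET, size_min=2, size_max=3)
        result = run_search(data, cfg)
        combos = [s.combined for s in result.scored]
        assert result.best.combined == max(combos)

    def test_end_to_end_recovery_single_seed(self):
        model = planted_recovery_model(seed=24)
        data = sample_dataset(model, 5000, seed=25)
        result = run_search(data, SearchConfig(target=TARGET, size_min=2, size_max=3))
        assert _sorted_sets(result.best.candidate.parent_sets) == _sorted_sets(
            model.structure.parents
        )

    def test_byte_identical_reruns(self):
        model = planted_recovery_model(seed=26)
        data = sample_dataset(model, 600, seed=27)
        cfg = SearchConfig(target=TARGET, size_min=2, size_max=3)
        assert run_search(data, cfg).to_json() == run_search(data, cfg).to_json()


class TestInteractionProfile:
    def test_two_parent_node_peak_is_the_pair(self):
        model = planted_recovery_model(seed=28)
        data = sample_dataset(model, 1000, seed=29)
        specs = (
            data.spec("t1_02"), data.spec("t1_03"), data.spec(TARGET),
        )
        st = dl.DbnStructure(specs, {TARGET: ("t1_02", "t1_03")}, TARGET)
        profile = strongest_interacting_subsets(data, st)
        assert set(profile.profiles[TARGET]) == {("t1_02",), ("t1_03",), ("t1_02", "t1_03")}

    def test_xor_planted_peak_is_full_pair_log2(self):
        a = np.array([0, 0, 1, 1] * 50)
        b = np.array([0, 1, 0, 1] * 50)
        x = a ^ b
        data = dataset_from(
            {"a": a, "b": b, "x": x}, {"a": 2, "b": 2, "x": 2},
            {"a": Slice.TIME1, "b": Slice.TIME1, "x": Slice.TARGET},
        )
        st = dl.DbnStructure(
            (data.spec("a"), data.spec("b"), data.spec("x")), {"x": ("a", "b")}, "x"
        )
        profile = strongest_interacting_subsets(data, st)
        assert profile.peaks["x"] == ("a", "b")
        assert profile.profiles["x"][("a", "b")] == pytest.approx(np.log(2), abs=1e-12)

    def test_six_parent_fixture_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(30)
        n = 400
        cols = {f"p{i}": rng.integers(0, 2, n) for i in range(6)}
        cols["x"] = (cols["p0"] ^ cols["p1"]) ^ (rng.random(n) < 0.1)
        data = dataset_from(
            cols, {nm: 2 for nm in cols},
            {nm: (Slice.TARGET if nm == "x" else Slice.TIME1) for nm in cols},
        )
        parents = tuple(sorted(f"p{i}" for i in range(6)))
        st = dl.DbnStructure(
            tuple(data.spec(nm) for nm in cols), {"x": parents}, "x"
        )
        profile = strongest_interacting_subsets(data, st)
        # exhaustive oracle over all 57 sub-combinations of size >= 2
        best, best_val = None, -np.inf
        count = 0
        for k in range(2, 7):
            for subset in itertools.combinations(parents, k):
                count += 1
                val = is_direct(cols["x"], [cols[p] for p in subset], 2, [2] * k)
                if val > best_val:
                    best, best_val = subset, val
        assert count == 57
        assert profile.peaks["x"] == best
        assert profile.profiles["x"][best] == pytest.approx(best_val, abs=1e-12)


class TestReduce:
    def _structure_and_profile(self, seed):
        model = planted_recovery_model(seed=seed)
        data = sample_dataset(model, 3000, seed=seed + 1)
        profile = strongest_interacting_subsets(data, model.structure)
        return model.structure, profile, data

    def test_identity_when_peaks_equal_full_parenthoods(self):
        st, profile, _ = self._structure_and_profile(31)
        full = {nm: tuple(sorted(st.parents[nm])) for nm in st.parents if st.parents[nm]}
        forced = type(profile)(profile.profiles, {nm: st.parents[nm] for nm in full})
        reduced = reduce_to_strongest(st, forced)
        assert _sorted_sets(reduced.parents) == _sorted_sets(st.parents)

    def test_partial_peak_keeps_subset_and_drops_orphans(self):
        st, profile, _ = self._structure_and_profile(32)
        forced_peaks = dict(profile.peaks)
        forced_peaks["evaluation"] = ("t1_04",)  # pretend only one arc is strong
        forced = type(profile)(profile.profiles, forced_peaks)
        reduced = reduce_to_strongest(st, forced)
        assert reduced.parents["evaluation"] == ("t1_04",)
        assert "t1_05" not in reduced.node_names  # orphaned, dropped

    def test_target_left_parentless_rejected(self):
        st, profile, _ = self._structure_and_profile(33)
        bad = type(profile)(profile.profiles, {**profile.peaks, TARGET: ()})
        with pytest.raises(ValueError, match="parentless"):
            reduce_to_strongest(st, bad)
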