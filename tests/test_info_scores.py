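"""Entropy, information gain, interaction strength and the likelihood
decomposition that justifies IG as a structure-search surrogate."""

import itertools

import numpy as np
import pytest

from helpers import (
    dataset_from,
    entropy_direct,
    ig_direct,
    is_direct,
    random_flat_fixture,
)

import dbnelicit as dl
from dbnelicit.dbn import DbnStructure
from dbnelicit.info_scores import (
    EmpiricalTable,
    bic_score,
    conditional_entropy,
    decomposition_check,
    empirical_table,
    entropy,
    information_gain,
    interaction_strength,
    log_likelihood,
    n_free_parameters,
)
from dbnelicit.param_learning import FitConfig, mle_fit
from dbnelicit.synthetic import sample_dataset
from dbnelicit.variables import Slice, VariableSpec


class TestEntropy:
    def test_uniform_maximizes(self):
        t = EmpiricalTable(("x",), np.array([10, 10, 10]), 30)
        assert entropy(t) == pytest.approx(np.log(3), abs=1e-12)

    def test_degenerate_is_zero(self):
        t = EmpiricalTable(("x",), np.array([30, 0, 0]), 30)
        assert entropy(t) == 0.0

    def test_two_thirds_one_third(self):
        t = EmpiricalTable(("x",), np.array([20, 10]), 30)
        expected = -(2 / 3) * np.log(2 / 3) - (1 / 3) * np.log(1 / 3)
        assert entropy(t) == pytest.approx(expected, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            entropy(EmpiricalTable(("x",), np.array([0, 0]), 0))


def _product_design(kx, ky, reps=5):
    """Every (x, y) combination exactly `reps` times: exact independence."""
    rows = [(x, y) for x in range(kx) for y in range(ky)] * reps
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    return x, y


class TestConditionalEntropy:
    def test_functional_dependence_is_zero(self):
        y = np.array([0, 1, 2, 0, 1, 2, 2, 1])
        data = dataset_from({"x": y, "y": y}, {"x": 3, "y": 3})
        assert conditional_entropy(data, "x", ("y",)) == pytest.approx(0.0, abs=1e-12)

    def test_independence_leaves_entropy_unchanged(self):
        x, y = _product_design(3, 2)
        data = dataset_from({"x": x, "y": y}, {"x": 3, "y": 2})
        assert conditional_entropy(data, "x", ("y",)) == pytest.approx(
            entropy(empirical_table(data, ["x"])), abs=1e-12
        )

    def test_chain_rule(self):
        rng = np.random.default_rng(0)
        cols = {nm: rng.integers(0, 3, 12) for nm in "xyz"}
        data = dataset_from(cols, {nm: 3 for nm in "xyz"})
        h_joint = entropy(empirical_table(data, ["x", "y", "z"]))
        h_parents = entropy(empirical_table(data, ["y", "z"]))
        assert conditional_entropy(data, "x", ("y", "z")) == pytest.approx(
            h_joint - h_parents, abs=1e-12
        )


class TestInformationGain:
    def test_independent_parent_gives_zero(self):
        x, y = _product_design(3, 3)
        data = dataset_from({"x": x, "y": y}, {"x": 3, "y": 3})
        assert information_gain(data, "x", ("y",)) == pytest.approx(0.0, abs=1e-12)

    def test_copy_of_uniform_parent_gives_log3(self):
        y = np.tile(np.arange(3), 10)
        data = dataset_from({"x": y, "y": y}, {"x": 3, "y": 3})
        assert information_gain(data, "x", ("y",)) == pytest.approx(np.log(3), abs=1e-12)

    def test_mutual_information_identity_two_parents(self):
        rng = np.random.default_rng(3)
        cols = {"x": rng.integers(0, 3, 20), "a": rng.integers(0, 2, 20),
                "b": rng.integers(0, 3, 20)}
        data = dataset_from(cols, {"x": 3, "a": 2, "b": 3})
        oracle = ig_direct(cols["x"], [cols["a"], cols["b"]], 3, [2, 3])
        assert information_gain(data, "x", ("a", "b")) == pytest.approx(oracle, abs=1e-12)

    def test_monotone_under_superset(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            cols = {nm: rng.integers(0, 3, 60) for nm in ("x", "a", "b", "c")}
            data = dataset_from(cols, {nm: 3 for nm in ("x", "a", "b", "c")})
            small = information_gain(data, "x", ("a", "b"))
            big = information_gain(data, "x", ("a", "b", "c"))
            assert big >= small - 1e-12

    def test_bounds(self):
        rng = np.random.default_rng(10)
        for trial in range(10):
            cols = {"x": rng.integers(0, 4, 50), "y": rng.integers(0, 3, 50)}
            data = dataset_from(cols, {"x": 4, "y": 3})
            hx = entropy(empirical_table(data, ["x"]))
            hxy = conditional_entropy(data, "x", ("y",))
            assert -1e-12 <= hxy <= hx + 1e-12 <= np.log(4) + 1e-12


class TestInteractionStrength:
    def test_singleton_is_exactly_zero(self):
        rng = np.random.default_rng(1)
        data = dataset_from(
            {"x": rng.integers(0, 3, 30), "y": rng.integers(0, 3, 30)},
            {"x": 3, "y": 3},
        )
        assert interaction_strength(data, "x", ("y",)) == 0.0

    def test_xor_synergy_is_log2(self):
        a = np.array([0, 0, 1, 1] * 8)
        b = np.array([0, 1, 0, 1] * 8)
        x = a ^ b
        data = dataset_from({"x": x, "a": a, "b": b}, {"x": 2, "a": 2, "b": 2})
        assert interaction_strength(data, "x", ("a", "b")) == pytest.approx(np.log(2), abs=1e-12)

    def test_duplicated_parent_redundancy_is_minus_log_k(self):
        y = np.tile(np.arange(3), 12)
        data = dataset_from({"x": y, "y1": y, "y2": y}, {"x": 3, "y1": 3, "y2": 3})
        assert interaction_strength(data, "x", ("y1", "y2")) == pytest.approx(
            -np.log(3), abs=1e-12
        )
        oracle = is_direct(y, [y, y], 3, [3, 3])
        assert oracle == pytest.approx(-np.log(3), abs=1e-12)

    def test_matches_direct_formula_on_random_fixture(self):
        rng = np.random.default_rng(17)
        cols = {nm: rng.integers(0, 3, 200) for nm in ("x", "a", "b", "c")}
        data = dataset_from(cols, {nm: 3 for nm in ("x", "a", "b", "c")})
        oracle = is_direct(cols["x"], [cols["a"], cols["b"], cols["c"]], 3, [3, 3, 3])
        assert interaction_strength(data, "x", ("a", "b", "c")) == pytest.approx(
            oracle, abs=1e-12
        )


def _flat_structure(names, parents, k=2):
    specs = tuple(
        VariableSpec(nm, Slice.TIME1, tuple(f"l{i}" for i in range(k)), "none")
        for nm in names
    )
    return DbnStructure(specs, parents)


class TestLogLikelihood:
    def test_fair_coin(self):
        st = _flat_structure(["c"], {})
        data = dataset_from({"c": np.array([0, 1])}, {"c": 2})
        params = mle_fit(st, data, FitConfig(pseudocount=0.0))
        assert log_likelihood(st, params, data) == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_single_row_is_log_joint(self):
        model, _ = random_flat_fixture(2)
        data = sample_dataset(model, 1, seed=3)
        from helpers import brute_joint
        assignment = {nm: int(data.col(nm)[0]) for nm in model.structure.node_names}
        expected = np.log(brute_joint(model.structure, model.params, assignment))
        assert log_likelihood(model.structure, model.params, data) == pytest.approx(
            expected, abs=1e-12
        )

    def test_fifty_rows_match_joint_table_lookups(self):
        model, _ = random_flat_fixture(5)
        data = sample_dataset(model, 50, seed=4)
        from helpers import brute_joint
        expected = sum(
            np.log(brute_joint(model.structure, model.params,
                               {nm: int(data.col(nm)[r]) for nm in model.structure.node_names}))
            for r in range(50)
        )
        assert log_likelihood(model.structure, model.params, data) == pytest.approx(
            expected, abs=1e-9
        )


class TestBic:
    def test_parentless_binary_closed_form(self):
        st = _flat_structure(["c"], {})
        data = dataset_from({"c": np.array([0, 0, 1, 1])}, {"c": 2})
        expected = 4 * np.log(0.5) - (np.log(4) / 2) * 1
        assert bic_score(st, data) == pytest.approx(expected, abs=1e-12)

    def test_uninformative_arc_strictly_lowers_bic(self):
        x, y = _product_design(2, 2, reps=8)  # exactly independent
        data = dataset_from({"x": x, "y": y}, {"x": 2, "y": 2})
        st0 = _flat_structure(["x", "y"], {})
        st1 = _flat_structure(["x", "y"], {"x": ("y",)})
        assert n_free_parameters(st1) > n_free_parameters(st0)
        assert bic_score(st1, data) < bic_score(st0, data)


class TestDecomposition:
    def test_empty_arc_structure_equals_minus_n_sum_entropy(self):
        rng = np.random.default_rng(6)
        cols = {nm: rng.integers(0, 3, 40) for nm in "abc"}
        data = dataset_from(cols, {nm: 3 for nm in "abc"})
        st = _flat_structure(list("abc"), {}, k=3)
        params = mle_fit(st, data, FitConfig(pseudocount=0.0))
        h_sum = sum(entropy(empirical_table(data, [nm])) for nm in "abc")
        assert log_likelihood(st, params, data) == pytest.approx(-40 * h_sum, abs=1e-9)
        assert decomposition_check(st, data) < 1e-9 * 40

    def test_random_four_node_fixture(self):
        rng = np.random.default_rng(7)
        cols = {nm: rng.integers(0, 3, 100) for nm in "abcd"}
        data = dataset_from(cols, {nm: 3 for nm in "abcd"})
        st = _flat_structure(list("abcd"), {"b": ("a",), "c": ("a", "b"), "d": ("c",)}, k=3)
        assert decomposition_check(st, data) < 1e-7

    def test_fully_connected_three_nodes(self):
        rng = np.random.default_rng(8)
        cols = {nm: rng.integers(0, 2, 64) for nm in "abc"}
        data = dataset_from(cols, {nm: 2 for nm in "abc"})
        st = _flat_structure(list("abc"), {"b": ("a",), "c": ("a", "b")})
        assert decomposition_check(st, data) < 1e-7


class TestScoreProperties:
    """Distribution-free invariants of the empirical scores."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _data_from(draw_codes):
        x, a, b = draw_codes
        n = min(len(x), len(a), len(b))
        return dataset_from(
            {"x": np.array(x[:n]), "a": np.array(a[:n]), "b": np.array(b[:n])},
            {"x": 3, "a": 2, "b": 3},
        )

    @given(
        st.tuples(
            st.lists(st.integers(0, 2), min_size=8, max_size=40),
            st.lists(st.integers(0, 1), min_size=8, max_size=40),
            st.lists(st.integers(0, 2), min_size=8, max_size=40),
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_entropy_chain_and_ig_bounds(self, draw_codes):
        data = self._data_from(draw_codes)
        hx = entropy(empirical_table(data, ["x"]))
        h_cond = conditional_entropy(data, "x", ("a", "b"))
        ig = information_gain(data, "x", ("a", "b"))
        assert -1e-12 <= h_cond <= hx + 1e-12
        assert hx <= np.log(3) + 1e-12
        assert ig == pytest.approx(hx - h_cond, abs=1e-12)
        assert ig >= information_gain(data, "x", ("a",)) - 1e-12
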