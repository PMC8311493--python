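"""Independent brute-force oracles and fixture builders for the test suite.

Everything here recomputes quantities from first principles (explicit
enumeration, O(n^2) pairwise comparisons, direct formula evaluation) so
the production code paths are checked against genuinely independent
implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

from dbnelicit.dbn import DbnStructure, ParameterSet
from dbnelicit.synthetic import GroundTruthModel
from dbnelicit.variables import CategoricalDataset, Slice, VariableSpec


# ---------------------------------------------------------------------------
# exact-inference oracles
# ---------------------------------------------------------------------------

def all_assignments(structure: DbnStructure):
    names = structure.node_names
    levels = [range(structure.spec(n).n_levels) for n in names]
    for combo in itertools.product(*levels):
        yield dict(zip(names, combo))


def brute_joint(structure: DbnStructure, params: ParameterSet, assignment) -> float:
    prob = 1.0
    for name in structure.node_names:
        idx = tuple(assignment[p] for p in structure.parents[name]) + (assignment[name],)
        prob *= float(params.cpt(name)[idx])
    return prob


def brute_posterior(structure: DbnStructure, params: ParameterSet, evidence) -> np.ndarray:
    """Target posterior by summation over the full joint table."""
    k = structure.spec(structure.target).n_levels
    probs = np.zeros(k)
    for assignment in all_assignments(structure):
        if any(assignment[n] != v for n, v in evidence.items()):
            continue
        probs[assignment[structure.target]] += brute_joint(structure, params, assignment)
    return probs / probs.sum()


# ---------------------------------------------------------------------------
# information-score oracles
# ---------------------------------------------------------------------------

def entropy_direct(counts: np.ndarray) -> float:
    p = np.asarray(counts, dtype=float).ravel()
    p = p[p > 0] / p.sum()
    return float(-(p * np.log(p)).sum())


def joint_counts_direct(columns: list[np.ndarray], shapes: list[int]) -> np.ndarray:
    counts = np.zeros(shapes)
    for row in zip(*columns):
        counts[tuple(int(v) for v in row)] += 1
    return counts


def ig_direct(x: np.ndarray, parents: list[np.ndarray], kx: int, kp: list[int]) -> float:
    """IG via the mutual-information identity H(X) + H(Y) - H(X, Y)."""
    joint = joint_counts_direct([x] + parents, [kx] + kp)
    hx = entropy_direct(joint.sum(axis=tuple(range(1, joint.ndim))))
    hy = entropy_direct(joint.sum(axis=0))
    return hx + hy - entropy_direct(joint)


def is_direct(x: np.ndarray, parents: list[np.ndarray], kx: int, kp: list[int]) -> float:
    joint_ig = ig_direct(x, parents, kx, kp)
    return joint_ig - sum(ig_direct(x, [p], kx, [k]) for p, k in zip(parents, kp))


# ---------------------------------------------------------------------------
# evaluation oracles
# ---------------------------------------------------------------------------

def pairwise_mauc(posteriors: np.ndarray, truths: np.ndarray) -> float:
    """Hand-Till by explicit O(n^2) record comparisons."""
    present = sorted(set(int(t) for t in truths))
    total = 0.0
    pairs = 0
    for i, j in itertools.combinations(present, 2):
        for a, b in ((i, j), (j, i)):
            num = 0.0
            cnt = 0
            for r in np.flatnonzero(truths == a):
                for s in np.flatnonzero(truths == b):
                    cnt += 1
                    if posteriors[r, a] > posteriors[s, a]:
                        num += 1.0
                    elif posteriors[r, a] == posteriors[s, a]:
                        num += 0.5
            total += num / cnt / 2.0
        pairs += 1
    return total / pairs


def brute_roc_points(scores: np.ndarray, positives: np.ndarray):
    """(gamma, fpr, tpr) for every distinct score plus gamma = 0."""
    gammas = sorted(set(float(s) for s in scores), reverse=True)
    if 0.0 not in gammas:
        gammas.append(0.0)
    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    pts = []
    for g in gammas:
        tp = sum(1 for s, p in zip(scores, positives) if p and s >= g)
        fp = sum(1 for s, p in zip(scores, positives) if not p and s >= g)
        pts.append((g, fp / n_neg, tp / n_pos))
    return pts


# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------

def specs_for(levels: dict[str, int], slices: dict[str, Slice] | None = None):
    slices = slices or {}
    out = []
    for name, k in levels.items():
        out.append(
            VariableSpec(name, slices.get(name, Slice.TIME1),
                         tuple(f"l{i}" for i in range(k)), "none")
        )
    return tuple(out)


def dataset_from(columns: dict[str, np.ndarray], levels: dict[str, int],
                 slices: dict[str, Slice] | None = None) -> CategoricalDataset:
    specs = specs_for(levels, slices)
    codes = np.column_stack([np.asarray(columns[s.name], dtype=np.int16) for s in specs])
    return CategoricalDataset(specs, codes)


def random_model(seed: int, n_time1: int = 3, n_time2: int = 2,
                 max_levels: int = 3, target_levels: int = 3) -> GroundTruthModel:
    """A random small three-slice model with Dirichlet CPTs."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_time1):
        k = int(rng.integers(2, max_levels + 1))
        specs.append(VariableSpec(f"t1_{i}", Slice.TIME1,
                                  tuple(f"l{j}" for j in range(k)), "none"))
    specs.append(VariableSpec("msg", Slice.INTERVENTION, ("a", "b", "c", "d"), "none"))
    for i in range(n_time2):
        k = int(rng.integers(2, max_levels + 1))
        specs.append(VariableSpec(f"t2_{i}", Slice.TIME2,
                                  tuple(f"l{j}" for j in range(k)), "none"))
    specs.append(VariableSpec("target", Slice.TARGET,
                              tuple(f"l{j}" for j in range(target_levels)), "none"))
    name_slice = {s.name: s.slice for s in specs}
    parents = {}
    pool_t1 = [s.name for s in specs if s.slice in (Slice.TIME1, Slice.INTERVENTION)]
    pool_t2 = [s.name for s in specs if s.slice == Slice.TIME2]
    for s in specs:
        if s.slice == Slice.TIME2:
            n_par = int(rng.integers(1, 3))
            parents[s.name] = tuple(rng.choice(pool_t1, size=n_par, replace=False))
        elif s.slice == Slice.TARGET:
            cand = pool_t1 + pool_t2
            n_par = int(rng.integers(1, min(3, len(cand)) + 1))
            parents[s.name] = tuple(rng.choice(cand, size=n_par, replace=False))
    structure = DbnStructure(tuple(specs), parents, "target")
    cpts = {}
    for s in specs:
        shape = tuple(structure.spec(p).n_levels for p in parents.get(s.name, ())) + (s.n_levels,)
        table = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1] or (1,))
        cpts[s.name] = table.reshape(shape)
    params = ParameterSet(structure, cpts)
    return GroundTruthModel(structure, params, seed, {})


def random_flat_fixture(seed: int):
    """A random DAG over 3-8 same-slice variables with sampled data
    (n <= 500), for likelihood-decomposition checks."""
    rng = np.random.default_rng(seed)
    n_vars = int(rng.integers(3, 9))
    specs = []
    for i in range(n_vars):
        k = int(rng.integers(2, 5))
        specs.append(VariableSpec(f"v{i}", Slice.TIME1,
                                  tuple(f"l{j}" for j in range(k)), "none"))
    parents = {}
    for i in range(n_vars):
        prev = [f"v{j}" for j in range(i)]
        n_par = int(rng.integers(0, min(2, len(prev)) + 1))
        if n_par:
            parents[f"v{i}"] = tuple(rng.choice(prev, size=n_par, replace=False))
    structure = DbnStructure(tuple(specs), parents, None)
    cpts = {}
    for s in specs:
        shape = tuple(structure.spec(p).n_levels for p in parents.get(s.name, ())) + (s.n_levels,)
        cpts[s.name] = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1] or (1,)).reshape(shape)
    model = GroundTruthModel(structure, ParameterSet(structure, cpts), seed, {})
    n = int(rng.integers(50, 501))
    return model, n
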