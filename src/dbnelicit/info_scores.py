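"""Empirical information-theoretic and likelihood scores.

All scores are computed on empirical frequency tables (natural log
throughout).  For a node X with candidate parents Y_1..Y_m:

* entropy            H(X) = -sum_x p(x) log p(x)
* conditional        H(X|Y) = -sum p(x,y) log[p(x,y)/p(y)]
* information gain   IG(X;Y) = H(X) - H(X|Y)            (>= 0 empirically)
* interaction        IS(X;Y_1..Y_m) = IG(X;Y_1..Y_m) - sum_i IG(X;Y_i)

IS is zero for a single parent, negative for redundant parents and
positive for synergistic ones (an XOR pair reaches log 2).

The module's strongest correctness anchor is the exact likelihood
decomposition on complete data with unsmoothed MLE parameters:
``l(theta, D) = N (sum_i IG(X_i; pi(X_i)) - sum_i H(X_i))``, which is
what justifies using information gain as a cheap likelihood surrogate
during structure pre-selection.

Rows missing any variable of a scored subset are dropped for that score
only (per-subset complete cases).
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np

from .dbn import DbnStructure, ParameterSet
from .variables import MISSING, CategoricalDataset


@dataclasses.dataclass(frozen=True)
class EmpiricalTable:
    """Joint counts over a variable subset, from complete cases only."""

    names: tuple[str, ...]
    counts: np.ndarray
    n_effective: int


def empirical_table(data: CategoricalDataset, names: Sequence[str]) -> EmpiricalTable:
    """Joint count table over *names* from rows complete on all of them."""
    names = tuple(names)
    mask = data.complete_mask(names)
    shape = tuple(data.spec(nm).n_levels for nm in names)
    if not names:
        raise ValueError("empty variable subset")
    cols = [data.col(nm)[mask].astype(np.int64) for nm in names]
    flat = np.ravel_multi_index(cols, shape) if cols else np.zeros(0, dtype=np.int64)
    counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    return EmpiricalTable(names, counts, int(mask.sum()))


def entropy_of_counts(counts: np.ndarray) -> float:
    """Entropy in nats of the distribution proportional to *counts*."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty empirical table")
    p = counts[counts > 0].astype(float) / total
    return float(-(p * np.log(p)).sum())


def entropy(table: "EmpiricalTable | CategoricalDataset", name: "str | None" = None) -> float:
    """H(X) in nats; accepts an :class:`EmpiricalTable` or (data, name)."""
    if isinstance(table, EmpiricalTable):
        return entropy_of_counts(table.counts)
    return entropy_of_counts(empirical_table(table, [name]).counts)


def conditional_entropy(
    data: CategoricalDataset, x: str, parents: Sequence[str]
) -> float:
    """H(X | parents) on the complete cases of {X} + parents."""
    parents = tuple(parents)
    if not parents:
        raise ValueError("parents must be non-empty")
    joint = empirical_table(data, (x,) + parents)
    if joint.n_effective == 0:
        raise ValueError("no complete cases for the scored subset")
    h_joint = entropy_of_counts(joint.counts)
    h_parents = entropy_of_counts(joint.counts.sum(axis=0))
    return h_joint - h_parents


def information_gain(data: CategoricalDataset, x: str, parents: Sequence[str]) -> float:
    """IG(X; parents) = H(X) - H(X|parents), on identical complete cases."""
    parents = tuple(parents)
    if not parents:
        return 0.0
    joint = empirical_table(data, (x,) + parents)
    if joint.n_effective == 0:
        raise ValueError("no complete cases for the scored subset")
    h_joint = entropy_of_counts(joint.counts)
    h_parents = entropy_of_counts(joint.counts.sum(axis=0))
    h_x = entropy_of_counts(joint.counts.reshape(joint.counts.shape[0], -1).sum(axis=1))
    return h_x + h_parents - h_joint


def interaction_strength(data: CategoricalDataset, x: str, parents: Sequence[str]) -> float:
    """IS(X; parents): joint IG minus the sum of singleton IGs.

    Collapses to exactly zero for a single parent; negative values flag
    redundant parents, positive values synergistic ones.
    """
    parents = tuple(parents)
    if not parents:
        raise ValueError("parents must be non-empty")
    if len(parents) == 1:
        return 0.0
    joint_ig = information_gain(data, x, parents)
    return joint_ig - sum(information_gain(data, x, (p,)) for p in parents)


# ---------------------------------------------------------------------------
# likelihood-based scores
# ---------------------------------------------------------------------------

def log_likelihood(
    structure: DbnStructure, params: ParameterSet, data: CategoricalDataset
) -> float:
    """Sum over complete-case rows of the log joint probability.

    Rows missing any structure variable are excluded.  A zero-probability
    row under unsmoothed parameters yields ``-inf`` with a warning.
    """
    names = structure.node_names
    mask = data.complete_mask(names)
    total = 0.0
    with np.errstate(divide="ignore"):
        for name in names:
            cpt = params.cpt(name)
            family = structure.parents[name] + (name,)
            cols = [data.col(nm)[mask].astype(np.int64) for nm in family]
            vals = cpt[tuple(cols)]
            logs = np.log(vals)
            if np.isneginf(logs).any():
                warnings.warn(f"zero-probability row at node {name}; log-likelihood is -inf")
            total += float(logs.sum())
    return total


def n_free_parameters(structure: DbnStructure) -> int:
    """Description length |B| = sum_i (K_i - 1) prod_{j in pi(i)} K_j."""
    total = 0
    for s in structure.specs:
        k = s.n_levels
        m = 1
        for p in structure.parents[s.name]:
            m *= structure.spec(p).n_levels
        total += (k - 1) * m
    return total


def bic_score(structure: DbnStructure, data: CategoricalDataset) -> float:
    """BIC = MLE log-likelihood minus (log N / 2) |B| on complete cases.

    Implemented for completeness; the elicitation pipeline selects by the
    combined mAUC, not BIC.
    """
    from .param_learning import FitConfig, mle_fit

    names = structure.node_names
    sub = data.select_rows(data.complete_mask(names))
    if sub.n == 0:
        raise ValueError("no complete cases")
    params = mle_fit(structure, sub, FitConfig(pseudocount=0.0))
    ll = log_likelihood(structure, params, sub)
    return ll - 0.5 * np.log(sub.n) * n_free_parameters(structure)


def decomposition_check(structure: DbnStructure, data: CategoricalDataset) -> float:
    """Residual of the likelihood decomposition on complete cases.

    Returns ``|l_MLE - N (sum_i IG(X_i; pi(X_i)) - sum_i H(X_i))|`` with
    unsmoothed MLE parameters; analytically zero, numerically < 1e-9 N.
    """
    from .param_learning import FitConfig, mle_fit

    names = structure.node_names
    sub = data.select_rows(data.complete_mask(names))
    if sub.n == 0:
        raise ValueError("no complete cases")
    params = mle_fit(structure, sub, FitConfig(pseudocount=0.0))
    lhs = log_likelihood(structure, params, sub)
    ig_sum = sum(
        information_gain(sub, name, structure.parents[name])
        for name in names
        if structure.parents[name]
    )
    h_sum = sum(entropy(sub, name) for name in names)
    rhs = sub.n * (ig_sum - h_sum)
    return abs(lhs - rhs)


def score_report(
    data: CategoricalDataset, x: str, subsets: Sequence[Sequence[str]]
) -> str:
    """TSV report of IG / IS / effective n for the given parent subsets."""
    lines = ["subset\tsize\tig\tis\tn_effective"]
    for subset in subsets:
        subset = tuple(subset)
        tab = empirical_table(data, (x,) + subset)
        ig = information_gain(data, x, subset)
        is_ = interaction_strength(data, x, subset) if subset else 0.0
        lines.append(
            f"{','.join(subset)}\t{len(subset)}\t{ig:.12g}\t{is_:.12g}\t{tab.n_effective}"
        )
    return "\n".join(lines) + "\n"
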