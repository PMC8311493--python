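"""CPT estimation: closed-form MLE on complete data, EM with missing cells.

With complete records the maximum-likelihood CPTs are frequency ratios
within each node's family (node + parents); an optional pseudocount adds
add-alpha smoothing, which keeps leave-one-out posteriors proper when a
held-out record shows a parent configuration unseen in training.

With missing cells (assumed missing at random) an exact EM is used: the
E-step computes, per record, the posterior over that record's missing
variables given its observed cells and distributes fractional counts to
every family touching a missing variable; the M-step re-normalizes.
Records are grouped by missing pattern so the E-step is vectorized over
all records sharing a pattern.  Initialization is a seeded perturbation
of uniform CPTs, so the whole fit is a pure function of
(structure, data, config).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from collections.abc import Sequence

import numpy as np

from .dbn import DbnStructure, ParameterSet
from .variables import MISSING, CategoricalDataset


@dataclasses.dataclass(frozen=True)
class FitConfig:
    """Estimation hyper-parameters.

    ``pseudocount`` is added to every CPT cell before normalization
    (default 1, add-one); ``em_tolerance`` is the maximum absolute
    parameter change that counts as convergence.
    """

    pseudocount: float = 1.0
    em_tolerance: float = 1e-6
    em_max_iterations: int = 300
    em_seed: int = 0
    em_restarts: int = 1

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.em_tolerance <= 0:
            raise ValueError("em_tolerance must be > 0")
        if self.em_max_iterations < 1 or self.em_restarts < 1:
            raise ValueError("em_max_iterations and em_restarts must be >= 1")


def _family(structure: DbnStructure, name: str) -> tuple[str, ...]:
    return structure.parents[name] + (name,)


def _family_shape(structure: DbnStructure, name: str) -> tuple[int, ...]:
    return tuple(structure.spec(v).n_levels for v in _family(structure, name))


def _normalize_counts(counts: np.ndarray, pseudocount: float, node: str) -> np.ndarray:
    k = counts.shape[-1]
    smoothed = counts + pseudocount
    row_tot = smoothed.sum(axis=-1, keepdims=True)
    zero = row_tot[..., 0] == 0
    if zero.any():
        warnings.warn(f"{node}: unseen parent configuration(s) default to uniform")
        smoothed = smoothed + np.where(zero, 1.0, 0.0)[..., None]
        row_tot = smoothed.sum(axis=-1, keepdims=True)
    return smoothed / row_tot


def family_counts(
    structure: DbnStructure, data: CategoricalDataset, name: str
) -> np.ndarray:
    """Observed joint counts for one node's family (family-complete rows)."""
    fam = _family(structure, name)
    mask = data.complete_mask(fam)
    shape = _family_shape(structure, name)
    cols = [data.col(v)[mask].astype(np.int64) for v in fam]
    flat = np.ravel_multi_index(cols, shape)
    return np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape).astype(float)


def mle_fit(
    structure: DbnStructure, data: CategoricalDataset, config: FitConfig = FitConfig()
) -> ParameterSet:
    """Closed-form (smoothed) maximum-likelihood CPTs.

    ``p(x|u) = (count(x,u) + a) / (count(u) + a K)``; rows missing any
    family member are excluded for that family only.  With ``a = 0`` an
    unseen parent configuration defaults to a uniform row with a warning.
    """
    cpts = {
        name: _normalize_counts(
            family_counts(structure, data, name), config.pseudocount, name
        )
        for name in structure.node_names
    }
    return ParameterSet(structure, cpts, converged=True, n_iterations=0)


# ---------------------------------------------------------------------------
# EM with missing data
# ---------------------------------------------------------------------------

class _EmWorkspace:
    """Precomputed index machinery for a (structure, data) pair."""

    def __init__(self, structure: DbnStructure, data: CategoricalDataset):
        self.structure = structure
        self.names = list(structure.node_names)
        self.pos = {nm: j for j, nm in enumerate(self.names)}
        self.cols = np.column_stack([data.col(nm) for nm in self.names]).astype(np.int64)
        self.n = data.n
        self.shapes = {nm: _family_shape(structure, nm) for nm in self.names}
        self.strides = {
            nm: np.array(
                [int(np.prod(self.shapes[nm][j + 1:])) for j in range(len(self.shapes[nm]))],
                dtype=np.int64,
            )
            for nm in self.names
        }
        for j, nm in enumerate(self.names):
            if not (self.cols[:, j] != MISSING).any():
                raise ValueError(f"{nm}: no observed values at all")

        missing = self.cols == MISSING
        self.complete_rows = np.flatnonzero(~missing.any(axis=1))
        # base hard counts: a family collects a unit count from every row
        # where the whole family is observed
        self.base_counts = {}
        for nm in self.names:
            fam = _family(structure, nm)
            fam_idx = [self.pos[v] for v in fam]
            mask = ~missing[:, fam_idx].any(axis=1)
            flat = (self.cols[np.ix_(mask.nonzero()[0], fam_idx)] * self.strides[nm]).sum(axis=1)
            size = int(np.prod(self.shapes[nm]))
            self.base_counts[nm] = np.bincount(flat, minlength=size).astype(float)

        # group incomplete rows by their missing pattern
        self.patterns: list[dict] = []
        incomplete = np.flatnonzero(missing.any(axis=1))
        keys: dict[tuple[int, ...], list[int]] = {}
        for r in incomplete:
            keys.setdefault(tuple(np.flatnonzero(missing[r])), []).append(int(r))
        for key in sorted(keys):
            rows = np.asarray(keys[key], dtype=np.int64)
            miss_names = [self.names[j] for j in key]
            relevant = [
                nm for nm in self.names
                if set(_family(structure, nm)) & set(miss_names)
            ]
            constant = [nm for nm in self.names if nm not in relevant]
            fam_index = {}
            for nm in relevant:
                fam = _family(structure, nm)
                base = np.zeros(len(rows), dtype=np.int64)
                miss_stride = []
                for j, v in enumerate(fam):
                    if v in miss_names:
                        miss_stride.append((miss_names.index(v), int(self.strides[nm][j])))
                    else:
                        base += self.cols[rows, self.pos[v]] * self.strides[nm][j]
                fam_index[nm] = (base, miss_stride)
            const_index = {}
            for nm in constant:
                fam = _family(structure, nm)
                fam_idx = [self.pos[v] for v in fam]
                const_index[nm] = (self.cols[np.ix_(rows, fam_idx)] * self.strides[nm]).sum(axis=1)
            configs = list(
                itertools.product(*[range(structure.spec(nm).n_levels) for nm in miss_names])
            )
            self.patterns.append(
                dict(rows=rows, miss=miss_names, relevant=relevant, constant=constant,
                     fam_index=fam_index, const_index=const_index, configs=configs)
            )

    # -- likelihood and E-step -------------------------------------------
    def observed_loglik(self, flat_cpts: dict[str, np.ndarray]) -> float:
        total = 0.0
        with np.errstate(divide="ignore"):
            for nm in self.names:
                fam = _family(self.structure, nm)
                fam_idx = [self.pos[v] for v in fam]
                flat = (self.cols[np.ix_(self.complete_rows, fam_idx)] * self.strides[nm]).sum(axis=1)
                total += float(np.log(flat_cpts[nm][flat]).sum())
            for pat in self.patterns:
                w = self._pattern_weights(pat, flat_cpts)
                tot = w.sum(axis=0)
                const = np.zeros(len(pat["rows"]))
                for nm in pat["constant"]:
                    const += np.log(flat_cpts[nm][pat["const_index"][nm]])
                total += float((np.log(np.maximum(tot, 1e-300)) + const).sum())
        return total

    def _pattern_weights(self, pat: dict, flat_cpts: dict[str, np.ndarray]) -> np.ndarray:
        w = np.empty((len(pat["configs"]), len(pat["rows"])))
        for c, cfg in enumerate(pat["configs"]):
            wc = np.ones(len(pat["rows"]))
            for nm in pat["relevant"]:
                base, miss_stride = pat["fam_index"][nm]
                idx = base
                for mpos, stride in miss_stride:
                    idx = idx + cfg[mpos] * stride
                wc = wc * flat_cpts[nm][idx]
            w[c] = wc
        return w

    def expected_counts(self, flat_cpts: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        counts = {nm: self.base_counts[nm].copy() for nm in self.names}
        for pat in self.patterns:
            w = self._pattern_weights(pat, flat_cpts)
            tot = w.sum(axis=0)
            bad = tot <= 0
            if bad.any():
                # zero-probability record under current parameters: spread
                # responsibility uniformly to keep the iteration defined
                w[:, bad] = 1.0
                tot = w.sum(axis=0)
            resp = w / tot
            for c, cfg in enumerate(pat["configs"]):
                for nm in pat["relevant"]:
                    base, miss_stride = pat["fam_index"][nm]
                    idx = base
                    for mpos, stride in miss_stride:
                        idx = idx + cfg[mpos] * stride
                    np.add.at(counts[nm], idx, resp[c])
        return counts


def _initial_cpts(
    structure: DbnStructure, seed: int, magnitude: float = 0.01
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(seed)
    cpts = {}
    for nm in structure.node_names:
        shape = _family_shape(structure, nm)
        table = np.full(shape, 1.0, dtype=float)
        table += magnitude * rng.random(shape)
        cpts[nm] = table / table.sum(axis=-1, keepdims=True)
    return cpts


def em_fit(
    structure: DbnStructure, data: CategoricalDataset, config: FitConfig = FitConfig()
) -> ParameterSet:
    """EM estimate of the CPTs; exact E-step, deterministic given the config.

    On complete data the first M-step already reproduces the (smoothed)
    MLE exactly, because the expected counts are the observed counts.
    The best of ``em_restarts`` seeded runs (by observed-data
    log-likelihood) is returned, carrying a convergence flag, the
    iteration count and the per-iteration log-likelihood trace.
    """
    ws = _EmWorkspace(structure, data)
    best: ParameterSet | None = None
    best_ll = -np.inf
    for r in range(config.em_restarts):
        cpts = _initial_cpts(structure, (config.em_seed + r) % (2**31 - 1))
        flat = {nm: cpts[nm].ravel() for nm in ws.names}
        trace = []
        converged = False
        iterations = 0
        for it in range(1, config.em_max_iterations + 1):
            iterations = it
            trace.append(ws.observed_loglik(flat))
            counts = ws.expected_counts(flat)
            new_flat = {}
            delta = 0.0
            for nm in ws.names:
                shaped = counts[nm].reshape(ws.shapes[nm])
                new = _normalize_counts(shaped, config.pseudocount, nm).ravel()
                delta = max(delta, float(np.abs(new - flat[nm]).max()))
                new_flat[nm] = new
            flat = new_flat
            if delta < config.em_tolerance:
                converged = True
                break
        final_ll = ws.observed_loglik(flat)
        if final_ll > best_ll:
            best_ll = final_ll
            best = ParameterSet(
                structure,
                {nm: flat[nm].reshape(ws.shapes[nm]) for nm in ws.names},
                converged=converged,
                n_iterations=iterations,
                loglik_trace=tuple(trace) + (final_ll,),
            )
    if best is not None and not best.converged:
        warnings.warn("EM did not converge within em_max_iterations")
    return best


def fit_parameters(
    structure: DbnStructure, data: CategoricalDataset, config: FitConfig = FitConfig()
) -> ParameterSet:
    """MLE when the structure's variables are fully observed, EM otherwise."""
    if data.complete_mask(structure.node_names).all():
        return mle_fit(structure, data, config)
    return em_fit(structure, data, config)
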