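"""Predictor evaluation: accuracy, one-vs-rest ROC, Hand-Till multiclass
AUC, in-sample and leave-one-out protocols, and the combined score.

The predictor under evaluation is always the same conditional: the
posterior of the intention-change target given a participant's Time-1
observations and assigned message frame, with all Time-2 mediators
marginalized.

* *In-sample*: parameters are fitted once on the whole dataset; every
  record is then scored individually from its partial observations.
* *Leave-one-out*: parameters are refitted N times, each excluding one
  record, and the held-out record is scored; metrics pool the N held-out
  posteriors.  On complete data with (smoothed) MLE fitting the N refits
  are obtained exactly by decrementing the full-data family counts by
  the held-out record's contribution, which makes the protocol linear in
  N instead of quadratic.  With missing data the literal per-record EM
  refit is performed instead.

The final structure-selection score is the arithmetic mean of the
in-sample and leave-one-out multiclass AUCs.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
from collections.abc import Sequence

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from . import dbn
from .dbn import DbnStructure, ParameterSet
from .param_learning import FitConfig, family_counts, fit_parameters
from .variables import MISSING, CategoricalDataset, Slice

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# elementary metrics
# ---------------------------------------------------------------------------

def accuracy(predictions: Sequence[int], truths: Sequence[int]) -> float:
    """Fraction of exact matches; ``accuracy * N`` is always an integer."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape or predictions.size == 0:
        raise ValueError("predictions and truths must be aligned and non-empty")
    return float((predictions == truths).sum()) / predictions.size


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """One-vs-rest ROC for a single class: (gamma, fpr, tpr) triples for a
    sweep of the acceptance threshold gamma, from no acceptances to all."""

    label: str
    points: tuple[tuple[float, float, float], ...]

    @property
    def auc(self) -> float:
        fpr = np.array([p[1] for p in self.points])
        tpr = np.array([p[2] for p in self.points])
        return float(np.trapezoid(tpr, fpr))


def roc_curve(scores: np.ndarray, positives: np.ndarray, label: str = "") -> RocCurve:
    """Sweep ``accept iff score >= gamma`` over all distinct scores plus 0.

    ``positives`` is the boolean truth for the class in question; both at
    least one positive and one negative record are required.
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    n_pos = int(positives.sum())
    n_neg = int((~positives).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"class {label!r} needs positive and negative records")
    gammas = np.unique(scores)[::-1]
    points = [(float(np.nextafter(gammas[0], np.inf)), 0.0, 0.0)]
    for g in gammas:
        acc = scores >= g
        points.append(
            (float(g), float((acc & ~positives).sum()) / n_neg, float((acc & positives).sum()) / n_pos)
        )
    if gammas[-1] > 0.0:
        points.append((0.0, 1.0, 1.0))
    return RocCurve(label, tuple(points))


def mauc(posteriors: np.ndarray, truths: Sequence[int]) -> float:
    """Hand-Till multiclass AUC.

    For every unordered pair of classes present in ``truths``,
    ``A(i|j)`` is the rank-based probability (ties credited 1/2) that a
    random class-i record receives a higher class-i score than a random
    class-j record; the pair measure is ``(A(i|j) + A(j|i)) / 2`` and the
    result averages all pairs.  Classes absent from ``truths`` are
    skipped with the class count adjusted (and logged).
    """
    posteriors = np.asarray(posteriors, dtype=float)
    truths = np.asarray(truths)
    present = np.unique(truths)
    if present.size < 2:
        raise ValueError("mauc undefined with a single observed class")
    if present.size < posteriors.shape[1]:
        log.info("mauc: %d of %d classes absent; pairs skipped",
                 posteriors.shape[1] - present.size, posteriors.shape[1])

    def a_cond(i: int, j: int) -> float:
        sel = (truths == i) | (truths == j)
        s = posteriors[sel, i]
        is_i = truths[sel] == i
        ranks = rankdata(s)
        n_i = int(is_i.sum())
        n_j = int((~is_i).sum())
        return (float(ranks[is_i].sum()) - n_i * (n_i + 1) / 2.0) / (n_i * n_j)

    pairs = list(itertools.combinations(present.tolist(), 2))
    total = sum((a_cond(i, j) + a_cond(j, i)) / 2.0 for i, j in pairs)
    return float(total / len(pairs))


def combine(mauc_in: float, mauc_out: float) -> float:
    """The selection score: arithmetic mean of the two mAUC estimates."""
    for v in (mauc_in, mauc_out):
        if not (0.0 <= v <= 1.0):
            raise ValueError("mAUC values must lie in [0, 1]")
    return (mauc_in + mauc_out) / 2.0


# ---------------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvalReport:
    """Metrics of one evaluation protocol run (or a merged pair)."""

    accuracy: float
    roc_curves: dict[str, RocCurve]
    mauc_in: "float | None" = None
    mauc_out: "float | None" = None
    posteriors: "np.ndarray | None" = None
    truths: "np.ndarray | None" = None
    fallback_count: int = 0

    @property
    def combined(self) -> "float | None":
        if self.mauc_in is None or self.mauc_out is None:
            return None
        return combine(self.mauc_in, self.mauc_out)

    def to_json(self) -> str:
        doc = {
            "accuracy": self.accuracy,
            "mauc_in": self.mauc_in,
            "mauc_out": self.mauc_out,
            "combined": self.combined,
            "fallback_count": self.fallback_count,
            "roc": {
                label: [list(p) for p in curve.points]
                for label, curve in sorted(self.roc_curves.items())
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# posterior tables
# ---------------------------------------------------------------------------

def _evidence_nodes(structure: DbnStructure) -> list[str]:
    return [
        s.name for s in structure.specs
        if s.slice in (Slice.TIME1, Slice.INTERVENTION)
    ]


def _latent_mediators(structure: DbnStructure) -> list[str]:
    """Time-2 ancestors of the target: the only latent nodes whose factors
    survive barren-node removal under Time-1 + intervention evidence."""
    anc = nx.ancestors(structure.graph(), structure.target)
    return sorted(n for n in anc if structure.spec(n).slice == Slice.TIME2)


def _posterior_rows_generic(
    structure: DbnStructure,
    params: ParameterSet,
    data: CategoricalDataset,
    rows: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Per-row target posteriors via the generic exact-inference engine."""
    ev_nodes = _evidence_nodes(structure)
    k = structure.spec(structure.target).n_levels
    out = np.empty((len(rows), k))
    fallbacks = 0
    for i, r in enumerate(rows):
        evidence = {
            nm: int(data.col(nm)[r]) for nm in ev_nodes if data.col(nm)[r] != MISSING
        }
        post = dbn.posterior_target(structure, params, evidence)
        out[i] = post.probabilities
        fallbacks += int(post.fallback)
    return out, fallbacks


def _posterior_table_fast(
    structure: DbnStructure,
    data: CategoricalDataset,
    rows: np.ndarray,
    pseudocount: float,
    loo: bool,
) -> tuple[np.ndarray, int]:
    """Vectorized posterior table on complete data.

    Factor values are taken from full-data family counts; in
    leave-one-out mode each record's own count contribution is subtracted
    before normalization, which reproduces the single-record-deleted MLE
    refit exactly.
    """
    target = structure.target
    latents = _latent_mediators(structure)
    rel = latents + [target]
    rel_set = set(rel)
    k_t = structure.spec(target).n_levels
    n_rows = len(rows)

    factor_tables: dict[str, np.ndarray] = {}
    combo_strides: dict[str, dict[str, int]] = {}
    for nm in rel:
        fam = structure.parents[nm] + (nm,)
        shape = tuple(structure.spec(v).n_levels for v in fam)
        strides = [int(np.prod(shape[j + 1:])) for j in range(len(shape))]
        cnt = family_counts(structure, data, nm)
        cnt_flat = cnt.ravel()
        pcnt_flat = cnt.sum(axis=-1).ravel()
        pshape = shape[:-1]
        pstrides = [int(np.prod(pshape[j + 1:])) for j in range(len(pshape))]
        k = shape[-1]

        free = [v for v in fam if v in rel_set]
        free_shape = tuple(structure.spec(v).n_levels for v in free)
        fstrides = [int(np.prod(free_shape[j + 1:])) for j in range(len(free_shape))]
        combo_strides[nm] = dict(zip(free, fstrides))

        base = np.zeros(n_rows, dtype=np.int64)
        pbase = np.zeros(n_rows, dtype=np.int64)
        for j, v in enumerate(fam):
            if v in rel_set:
                continue
            col = data.col(v)[rows].astype(np.int64)
            base += col * strides[j]
            if j < len(fam) - 1:
                pbase += col * pstrides[j]

        table = np.empty((int(np.prod(free_shape)), n_rows))
        for combo in itertools.product(*[range(s) for s in free_shape]):
            assign = dict(zip(free, combo))
            idx = base.copy()
            pidx = pbase.copy()
            for j, v in enumerate(fam):
                if v in rel_set:
                    idx += assign[v] * strides[j]
                    if j < len(fam) - 1:
                        pidx += assign[v] * pstrides[j]
            num = cnt_flat[idx] + pseudocount
            den = pcnt_flat[pidx] + pseudocount * k
            if loo:
                d_par = np.ones(n_rows, dtype=bool)
                for j, v in enumerate(fam[:-1]):
                    if v in rel_set:
                        d_par &= data.col(v)[rows] == assign[v]
                d_fam = d_par & (data.col(nm)[rows] == assign[nm])
                num = num - d_fam
                den = den - d_par
            row = int(sum(assign[v] * combo_strides[nm][v] for v in free))
            # unseen parent configuration in the (possibly decremented)
            # training counts: the CPT row defaults to uniform
            table[row] = np.where(den > 0, num / np.maximum(den, 1.0), 1.0 / k)
        factor_tables[nm] = table

    score = np.zeros((n_rows, k_t))
    latent_levels = [range(structure.spec(v).n_levels) for v in latents]
    for lc in itertools.product(*latent_levels):
        assign = dict(zip(latents, lc))
        for v in range(k_t):
            assign[target] = v
            term = np.ones(n_rows)
            for nm in rel:
                row = int(
                    sum(assign[u] * s for u, s in combo_strides[nm].items())
                )
                term = term * factor_tables[nm][row]
            score[:, v] += term
    totals = score.sum(axis=1)
    fallback = totals <= 0
    if fallback.any():
        log.warning("%d record(s) hit zero-probability evidence; uniform fallback", fallback.sum())
        score[fallback] = 1.0
        totals[fallback] = k_t
    return score / totals[:, None], int(fallback.sum())


def _report_from_posteriors(
    structure: DbnStructure,
    posteriors: np.ndarray,
    truths: np.ndarray,
    fallbacks: int,
) -> EvalReport:
    preds = np.argmax(posteriors, axis=1)  # ties resolve to the lowest index
    acc = accuracy(preds, truths)
    levels = structure.spec(structure.target).levels
    curves = {}
    for c, label in enumerate(levels):
        pos = truths == c
        if pos.any() and (~pos).any():
            curves[label] = roc_curve(posteriors[:, c], pos, label)
    return EvalReport(acc, curves, mauc_in=None, mauc_out=None,
                      posteriors=posteriors, truths=truths, fallback_count=fallbacks)


def _evaluated_rows(structure: DbnStructure, data: CategoricalDataset) -> np.ndarray:
    rows = np.flatnonzero(data.col(structure.target) != MISSING)
    if rows.size == 0:
        raise ValueError("no rows with an observed target")
    return rows


def evaluate_in_sample(
    structure: DbnStructure, data: CategoricalDataset, config: FitConfig = FitConfig()
) -> EvalReport:
    """Fit once on everything, then score each record from its Time-1 and
    intervention cells only."""
    rows = _evaluated_rows(structure, data)
    if data.complete_mask(structure.node_names).all():
        post, fb = _posterior_table_fast(structure, data, rows, config.pseudocount, loo=False)
    else:
        params = fit_parameters(structure, data, config)
        post, fb = _posterior_rows_generic(structure, params, data, rows)
    report = _report_from_posteriors(structure, post, data.col(structure.target)[rows], fb)
    report.mauc_in = mauc(post, data.col(structure.target)[rows])
    return report


def evaluate_loo(
    structure: DbnStructure, data: CategoricalDataset, config: FitConfig = FitConfig()
) -> EvalReport:
    """Leave-one-out protocol: N single-record-deleted fits, each scored on
    its held-out record; metrics pool the N posteriors."""
    if data.n < 2:
        raise ValueError("leave-one-out needs at least two records")
    rows = _evaluated_rows(structure, data)
    if data.complete_mask(structure.node_names).all():
        post, fb = _posterior_table_fast(structure, data, rows, config.pseudocount, loo=True)
    else:
        k = structure.spec(structure.target).n_levels
        post = np.empty((len(rows), k))
        fb = 0
        for i, r in enumerate(rows):
            keep = np.ones(data.n, dtype=bool)
            keep[r] = False
            params = fit_parameters(structure, data.select_rows(keep), config)
            p, f = _posterior_rows_generic(structure, params, data, np.array([r]))
            post[i] = p[0]
            fb += f
    report = _report_from_posteriors(structure, post, data.col(structure.target)[rows], fb)
    report.mauc_out = mauc(post, data.col(structure.target)[rows])
    return report


def evaluate_combined(
    structure: DbnStructure, data: CategoricalDataset, config: FitConfig = FitConfig()
) -> EvalReport:
    """Run both protocols and merge into a single report (accuracy and ROC
    curves are the in-sample ones; the combined score averages the mAUCs)."""
    rin = evaluate_in_sample(structure, data, config)
    rout = evaluate_loo(structure, data, config)
    rin.mauc_out = rout.mauc_out
    rin.fallback_count += rout.fallback_count
    return rin
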