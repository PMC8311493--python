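"""Seeded generators of ground-truth models and study-shaped data.

Every experiment in this package runs against planted ground truth: a
three-slice network with known parenthoods and CPTs, from which either
integer-coded records (for learning experiments) or a continuous
questionnaire-style table (for end-to-end pipeline runs) are sampled.
Each generator is a pure function of its configuration and seed.

Dependence strength is a single scalar knob per node: each child's CPT
is a mixture ``(1 - s) * uniform + s * peak(u)`` where the peak level is
a seeded random function of the parent configuration ``u``.  ``s = 0``
makes the child independent of its parents, ``s = 1`` a deterministic
function of them.

The continuous emitter writes each categorical level into a disjoint
interval of the 1-7 index scale (age gets years, demographics and the
message frame stay categorical) and encodes the target as the difference
of the two intention columns.  Its reference ("latent") categorical
dataset is the quantile binning of the noiseless values, so the
noiseless round trip through the study-data module is exact by
construction; measurement noise is added on top of that reference.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .dbn import DbnStructure, ParameterSet, validate_structure
from .study_data import (
    ID_COLUMN,
    INTENTION_T1,
    INTENTION_T2,
    DiscretizationMap,
    RawStudyTable,
    default_study_schema,
    derive_intention_change,
    discretize,
    fit_discretization,
)
from .variables import (
    MISSING,
    CategoricalDataset,
    Slice,
    VariableSpec,
    message_spec,
    quantile3,
    target_spec,
)


@dataclasses.dataclass
class GroundTruthModel:
    """A planted structure + CPTs, with the seed that generated them."""

    structure: DbnStructure
    params: ParameterSet
    seed: int
    strengths: dict[str, float]


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence(seed).generate_state(k + 1)[-1] % (2**31 - 1))


def make_planted_model(
    specs: Sequence[VariableSpec],
    parents: Mapping[str, Sequence[str]],
    strength: "float | Mapping[str, float]" = 0.9,
    seed: int = 0,
) -> GroundTruthModel:
    """Construct a ground-truth model with the given planted parenthoods.

    ``strength`` may be one scalar for all children or a per-node map;
    nodes without parents get uniform distributions.
    """
    structure = DbnStructure(
        tuple(specs),
        {nm: tuple(ps) for nm, ps in parents.items()},
        next((s.name for s in specs if s.slice == Slice.TARGET), None),
    )
    report = validate_structure(structure)
    if not report.ok:
        raise ValueError(f"planted arcs invalid: {report.messages}")
    rng = np.random.default_rng(_child_seed(seed, 0))
    strengths: dict[str, float] = {}
    cpts: dict[str, np.ndarray] = {}
    for s in sorted(structure.specs, key=lambda v: v.name):
        k = s.n_levels
        ps = structure.parents[s.name]
        if not ps:
            cpts[s.name] = np.full((k,), 1.0 / k)
            strengths[s.name] = 0.0
            continue
        w = float(strength[s.name] if isinstance(strength, Mapping) else strength)
        if not (0.0 <= w <= 1.0):
            raise ValueError("strength must lie in [0, 1]")
        pshape = tuple(structure.spec(p).n_levels for p in ps)
        n_cfg = int(np.prod(pshape))
        peaks = rng.integers(k, size=n_cfg)
        table = np.full((n_cfg, k), (1.0 - w) / k)
        table[np.arange(n_cfg), peaks] += w
        cpts[s.name] = table.reshape(pshape + (k,))
        strengths[s.name] = w
    return GroundTruthModel(structure, ParameterSet(structure, cpts), seed, strengths)


def sample_dataset(model: GroundTruthModel, n: int, seed: int) -> CategoricalDataset:
    """Ancestral sampling of *n* integer-coded records (bit-reproducible)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(_child_seed(seed, 1))
    structure = model.structure
    order = structure.topological_order()
    cols: dict[str, np.ndarray] = {}
    for name in order:
        cpt = model.params.cpt(name)
        k = structure.spec(name).n_levels
        ps = structure.parents[name]
        rows = cpt.reshape(-1, k)
        if ps:
            shape = tuple(structure.spec(p).n_levels for p in ps)
            flat = np.ravel_multi_index([cols[p].astype(np.int64) for p in ps], shape)
        else:
            flat = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(rows, axis=1)[flat]
        u = rng.random(n)
        cols[name] = (u[:, None] > cum).sum(axis=1).astype(np.int16)
    codes = np.column_stack([cols[s.name] for s in structure.specs])
    return CategoricalDataset(structure.specs, codes)


def mask_missing(dataset: CategoricalDataset, rate: float, seed: int) -> CategoricalDataset:
    """MCAR-mask exactly ``floor(rate * cells)`` non-target cells.

    ``cells`` counts all non-target positions.  Masking that would leave
    a variable with no observed value is rejected.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    eligible_cols = [j for j, s in enumerate(dataset.specs) if s.slice != Slice.TARGET]
    n_cells = dataset.n * len(eligible_cols)
    k = math.floor(rate * n_cells)
    out = dataset.copy()
    if k == 0:
        return out
    rng = np.random.default_rng(_child_seed(seed, 2))
    flat_eligible = np.array(
        [r * dataset.codes.shape[1] + c for c in eligible_cols for r in range(dataset.n)
         if dataset.codes[r, c] != MISSING],
        dtype=np.int64,
    )
    if flat_eligible.size < k:
        raise ValueError("not enough observed cells to mask at this rate")
    chosen = rng.choice(flat_eligible, size=k, replace=False)
    out.codes.ravel()[chosen] = MISSING
    for j, s in enumerate(out.specs):
        if not (out.codes[:, j] != MISSING).any():
            raise ValueError(f"rate would mask variable {s.name} entirely")
    return out


# ---------------------------------------------------------------------------
# study-shaped configurations
# ---------------------------------------------------------------------------

def planted_recovery_model(seed: int = 0, strength: float = 0.9) -> GroundTruthModel:
    """A 17-variable study-shaped model for structure-recovery experiments.

    Ten Time-1 indexes, the four-frame message, five Time-2 variables of
    which two ("threat", "evaluation") mediate the target, and the
    five-level target with three parents (the two mediators plus one
    Time-1 index).  Mediators have three parents each, so a search over
    sizes [2, 3] can recover every planted parenthood exactly.
    """
    t1 = [INTENTION_T1] + [f"t1_{i:02d}" for i in range(2, 11)]
    specs = [quantile3(nm, Slice.TIME1) for nm in t1]
    specs.append(message_spec())
    specs.extend(quantile3(nm, Slice.TIME2) for nm in
                 ["threat", "evaluation", "tone", "trust", "processing"])
    specs.append(target_spec())
    parents = {
        "threat": ("message", "t1_02", "t1_03"),
        "evaluation": ("t1_04", "t1_05", "t1_06"),
        "intention_change": ("evaluation", "threat", INTENTION_T1),
    }
    return make_planted_model(specs, parents, strength, seed)


def parameter_recovery_model(seed: int = 0, strength: float = 0.9) -> GroundTruthModel:
    """A compact six-variable model for parameter-recovery experiments.

    Family tables are small (at most 12 parent configurations), so at a
    few thousand records every CPT cell rests on hundreds of
    observations and estimation error is dominated by the estimator, not
    by sampling noise.
    """
    specs = [quantile3(nm, Slice.TIME1) for nm in ("t1_a", "t1_b", "t1_c")]
    specs.append(message_spec())
    specs.append(quantile3("mediator", Slice.TIME2))
    specs.append(target_spec())
    parents = {
        "mediator": ("message", "t1_a"),
        "intention_change": ("mediator", "t1_b"),
    }
    return make_planted_model(specs, parents, strength, seed)


def study_model(seed: int = 0, strength: float = 0.65) -> GroundTruthModel:
    """Ground truth over the full study roster (for pipeline demos).

    Mediation chains run from baseline dispositions and the message frame
    through the Time-2 message perceptions into intention change.
    """
    specs = default_study_schema()
    parents = {
        "threat": ("message", "prevention", "anticipated_negative_emotions"),
        "tone": ("message", "promotion"),
        "distress": ("threat", "anticipated_negative_emotions"),
        "trust": ("tone", "subjective_norm"),
        "systematic_processing": ("trust", "perceived_behavioral_control"),
        "evaluation": ("threat", "tone", "attitude"),
        "intention_change": ("evaluation", "threat", INTENTION_T1),
    }
    return make_planted_model(specs, parents, strength, seed)


# ---------------------------------------------------------------------------
# continuous emission
# ---------------------------------------------------------------------------

#: level base intervals on the 1-7 scale (tertiles) and the change scale
_BIN_LO = 1.0
_BIN_WIDTH = 2.0
_CHANGE_LO = -1.5
_CHANGE_WIDTH = 0.6
DEFAULT_NOISE = 0.25


@dataclasses.dataclass
class ContinuousStudy:
    """A continuous study table plus its generating reference."""

    table: RawStudyTable
    latent: CategoricalDataset
    dmap: DiscretizationMap
    model: GroundTruthModel


def sample_continuous_study(
    model: GroundTruthModel,
    n: int,
    noise: float = DEFAULT_NOISE,
    seed: int = 0,
) -> ContinuousStudy:
    """Emit a questionnaire-style CSV-shaped table from planted ground truth.

    Tertile variables write level ``L`` into the interval
    ``[1 + 2L + 0.15, 1 + 2L + 1.85]``; the target level becomes an
    intention difference in ``[-1.5 + 0.6L, -1.5 + 0.6(L+1))`` encoded
    via ``intention_t2 = intention_t1 + change``; age uses decades.
    Gaussian noise with standard deviation ``noise`` is added to every
    continuous column after the reference discretization is fixed, and
    values are clipped back into range.
    """
    latent_codes = sample_dataset(model, n, seed)
    rng = np.random.default_rng(_child_seed(seed, 3))
    structure = model.structure
    frame: dict[str, np.ndarray] = {}
    frame[ID_COLUMN] = np.array([f"P{i + 1:04d}" for i in range(n)], dtype=object)

    target = structure.target
    target_codes = latent_codes.col(target).astype(int)
    change = (
        _CHANGE_LO + _CHANGE_WIDTH * target_codes + 0.05 * _CHANGE_WIDTH
        + 0.9 * _CHANGE_WIDTH * rng.random(n)
    )

    for s in structure.specs:
        lv = latent_codes.col(s.name).astype(int)
        if s.slice == Slice.TARGET:
            continue
        if s.name == INTENTION_T1:
            lo = np.maximum(_BIN_LO + _BIN_WIDTH * lv + 0.05, 1.0 - change)
            hi = np.minimum(_BIN_LO + _BIN_WIDTH * (lv + 1) - 0.05, 7.0 - change)
            if (hi <= lo).any():
                raise RuntimeError("intention bins incompatible with change range")
            t1 = lo + (hi - lo) * rng.random(n)
            frame[INTENTION_T1] = t1
            frame[INTENTION_T2] = t1 + change
        elif s.discretization.startswith("quantile"):
            if s.name == "age":
                frame[s.name] = 20.0 + 10.0 * lv + 0.5 + 9.0 * rng.random(n)
            else:
                frame[s.name] = (
                    _BIN_LO + _BIN_WIDTH * lv + 0.15 + 0.85 * _BIN_WIDTH * rng.random(n)
                )
        else:
            labels = np.asarray(s.levels, dtype=object)
            frame[s.name] = labels[lv]

    clean = RawStudyTable(pd.DataFrame(frame), structure.specs)
    clean = derive_intention_change(clean)
    dmap = fit_discretization(clean, structure.specs)
    latent = discretize(clean, dmap, structure.specs)

    noisy = clean.frame.copy()
    if noise > 0:
        for s in structure.specs:
            if s.slice == Slice.TARGET or not s.discretization.startswith("quantile"):
                continue
            if s.name == INTENTION_T1:
                continue
            col = noisy[s.name].to_numpy(dtype=float) + rng.normal(0.0, noise, n)
            bounds = (18.0, 80.0) if s.name == "age" else (1.0, 7.0)
            noisy[s.name] = np.clip(col, *bounds)
        for col in (INTENTION_T1, INTENTION_T2):
            vals = noisy[col].to_numpy(dtype=float) + rng.normal(0.0, noise, n)
            noisy[col] = np.clip(vals, 1.0, 7.0)
    noisy = noisy.drop(columns=["intention_change"])
    return ContinuousStudy(RawStudyTable(noisy, structure.specs), latent, dmap, model)
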