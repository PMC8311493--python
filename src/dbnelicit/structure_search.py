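"""Deterministic structure elicitation.

The search balances explanatory structure against predictive capability
in four fully deterministic steps:

1. for every parent-set size k in a configured range, find the subset of
   non-target variables with maximal information gain for the target;
2. expand every Time-2 variable appearing in a selected parenthood with
   its own IG-maximal parent set of a common size, avoiding cycles, until
   every Time-2 node in the structure is rooted (directly or indirectly)
   in Time-1 / intervention nodes;
3. this yields one candidate structure per (target size, common Time-2
   size) grid cell, scored by total information gain;
4. every candidate is then evaluated by the combined in-sample /
   leave-one-out multiclass AUC, and the argmax is selected.

All ties break lexicographically (variable-name tuples, then grid
order), so identical inputs always give byte-identical results.
Redundancy of the equal-size parenthoods is profiled afterwards with the
interaction strength, whose per-node peak identifies the strongest
interacting sub-parenthood (the basis of the reduced structure).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from collections.abc import Mapping, Sequence

import numpy as np

from .dbn import DbnStructure, validate_structure
from .evaluation import evaluate_combined
from .info_scores import information_gain, interaction_strength
from .param_learning import FitConfig
from .variables import CategoricalDataset, Slice, VariableSpec


@dataclasses.dataclass(frozen=True)
class SearchConfig:
    """Bounds and policies of the deterministic search."""

    target: str
    size_min: int = 2
    size_max: int = 8
    fit: FitConfig = dataclasses.field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if not (1 <= self.size_min <= self.size_max):
            raise ValueError("need 1 <= size_min <= size_max")


@dataclasses.dataclass
class CandidateStructure:
    """One pre-selected structure: a (target size, Time-2 size) grid cell."""

    structure: DbnStructure
    size_combo: tuple[int, int]
    total_ig: float
    parent_sets: dict[str, tuple[str, ...]]


@dataclasses.dataclass
class ScoredCandidate:
    candidate: CandidateStructure
    mauc_in: float
    mauc_out: float
    combined: float
    accuracy: float


@dataclasses.dataclass
class SearchResult:
    """All evaluated candidates, the selected best and the audit log."""

    scored: list[ScoredCandidate]
    best_index: int
    audit: list[str]

    @property
    def best(self) -> ScoredCandidate:
        return self.scored[self.best_index]

    def score_table(self) -> str:
        lines = ["target_size\ttime2_size\ttotal_ig\tmauc_in\tmauc_out\tcombined\taccuracy\tselected"]
        for i, s in enumerate(self.scored):
            lines.append(
                f"{s.candidate.size_combo[0]}\t{s.candidate.size_combo[1]}\t"
                f"{s.candidate.total_ig:.12g}\t{s.mauc_in:.12g}\t{s.mauc_out:.12g}\t"
                f"{s.combined:.12g}\t{s.accuracy:.12g}\t{int(i == self.best_index)}"
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        doc = {
            "best_index": self.best_index,
            "candidates": [
                {
                    "size_combo": list(s.candidate.size_combo),
                    "total_ig": s.candidate.total_ig,
                    "parent_sets": {k: list(v) for k, v in sorted(s.candidate.parent_sets.items())},
                    "mauc_in": s.mauc_in,
                    "mauc_out": s.mauc_out,
                    "combined": s.combined,
                    "accuracy": s.accuracy,
                }
                for s in self.scored
            ],
            "audit": self.audit,
        }
        return json.dumps(doc, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# step 1: target parenthoods
# ---------------------------------------------------------------------------

def _target_pool(data: CategoricalDataset, target: str) -> list[str]:
    return sorted(nm for nm in data.names if nm != target)


def best_parent_sets_for_target(
    data: CategoricalDataset, config: SearchConfig
) -> dict[int, tuple[str, ...]]:
    """For each size k in range, the IG-maximal parent subset of the target
    among all other variables; ties break to the lexicographically first."""
    pool = _target_pool(data, config.target)
    if len(pool) < config.size_min:
        raise ValueError("candidate pool smaller than size_min")
    out: dict[int, tuple[str, ...]] = {}
    for k in range(config.size_min, min(config.size_max, len(pool)) + 1):
        best: tuple[str, ...] | None = None
        best_ig = -np.inf
        for subset in itertools.combinations(pool, k):
            ig = information_gain(data, config.target, subset)
            if ig > best_ig:
                best, best_ig = subset, ig
        out[k] = best
    return out


# ---------------------------------------------------------------------------
# step 2: Time-2 closure
# ---------------------------------------------------------------------------

class InfeasibleCombo(RuntimeError):
    """No cycle-free parenthood of the required size exists for some node."""


def _descendants(children: Mapping[str, set[str]], start: str) -> set[str]:
    seen: set[str] = set()
    stack = [start]
    while stack:
        u = stack.pop()
        for v in children.get(u, ()):  # deterministic not required: result is a set
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return seen

def expand_time2_closure(
    data: CategoricalDataset,
    target: str,
    target_parents: Sequence[str],
    common_size: int,
) -> dict[str, tuple[str, ...]]:
    """Expand every reachable Time-2 node with an IG-maximal parenthood of
    ``common_size``, avoiding cycles.

    Worklist order is deterministic: the target's Time-2 parents in
    lexicographic order, then newly referenced Time-2 nodes in discovery
    order.  Candidate parents of a Time-2 node are Time-1 variables, the
    intervention, or other Time-2 non-target variables; arcs that would
    close a directed cycle are excluded before subset enumeration.
    """
    is_t2 = {nm: data.spec(nm).slice == Slice.TIME2 for nm in data.names}
    expanded: dict[str, tuple[str, ...]] = {}
    children: dict[str, set[str]] = {}
    worklist = [nm for nm in sorted(target_parents) if is_t2[nm]]
    queued = set(worklist)
    while worklist:
        node = worklist.pop(0)
        forbidden = _descendants(children, node)
        pool = [
            nm for nm in sorted(data.names)
            if nm not in (node, target) and nm not in forbidden
            and data.spec(nm).slice != Slice.TARGET
        ]
        if len(pool) < common_size:
            raise InfeasibleCombo(f"{node}: no acyclic parenthood of size {common_size}")
        best: tuple[str, ...] | None = None
        best_ig = -np.inf
        for subset in itertools.combinations(pool, common_size):
            ig = information_gain(data, node, subset)
            if ig > best_ig:
                best, best_ig = subset, ig
        expanded[node] = best
        for p in best:
            children.setdefault(p, set()).add(node)
            if is_t2[p] and p not in queued:
                worklist.append(p)
                queued.add(p)
    return expanded


# ---------------------------------------------------------------------------
# steps 3-4: pre-selection grid and final evaluation
# ---------------------------------------------------------------------------

def _build_structure(
    data: CategoricalDataset,
    target: str,
    parent_sets: Mapping[str, tuple[str, ...]],
) -> DbnStructure:
    nodes: set[str] = {target}
    for child, ps in parent_sets.items():
        nodes.add(child)
        nodes.update(ps)
    specs = tuple(data.spec(nm) for nm in sorted(nodes))
    structure = DbnStructure(specs, dict(parent_sets), target)
    report = validate_structure(structure)
    if not report.ok:
        raise RuntimeError(f"search produced an invalid structure: {report.messages}")
    return structure


def preselect_candidates(
    data: CategoricalDataset, config: SearchConfig
) -> tuple[list[CandidateStructure], list[str]]:
    """One IG-maximal candidate per feasible (target size, Time-2 size)
    grid cell; infeasible cells are skipped and logged."""
    audit: list[str] = []
    best_sets = best_parent_sets_for_target(data, config)
    candidates: list[CandidateStructure] = []
    sizes = sorted(best_sets)
    for ts in sizes:
        tp = best_sets[ts]
        audit.append(f"step1 size={ts}: target parents {tp}")
        for cs in range(config.size_min, config.size_max + 1):
            try:
                expanded = expand_time2_closure(data, config.target, tp, cs)
            except InfeasibleCombo as exc:
                audit.append(f"combo ({ts},{cs}) infeasible: {exc}")
                continue
            parent_sets = {config.target: tp, **expanded}
            structure = _build_structure(data, config.target, parent_sets)
            total_ig = sum(
                information_gain(data, child, ps) for child, ps in parent_sets.items()
            )
            audit.append(
                f"combo ({ts},{cs}): expanded {sorted(expanded)} total_ig={total_ig:.6f}"
            )
            candidates.append(
                CandidateStructure(structure, (ts, cs), float(total_ig), parent_sets)
            )
    if not candidates:
        audit.append("all size combinations infeasible")
    return candidates, audit


def select_best_structure(
    data: CategoricalDataset,
    candidates: Sequence[CandidateStructure],
    config: SearchConfig,
) -> SearchResult:
    """Evaluate every candidate with the combined in-sample / leave-one-out
    mAUC and select the argmax (grid order breaks exact ties)."""
    if not candidates:
        raise ValueError("no candidate structures to evaluate")
    audit: list[str] = []
    scored: list[ScoredCandidate] = []
    for cand in candidates:
        try:
            report = evaluate_combined(cand.structure, data, config.fit)
        except Exception as exc:  # noqa: BLE001 - candidate excluded, logged
            audit.append(f"combo {cand.size_combo} evaluation failed: {exc}")
            continue
        scored.append(
            ScoredCandidate(cand, report.mauc_in, report.mauc_out, report.combined, report.accuracy)
        )
        audit.append(
            f"combo {cand.size_combo}: mauc_in={report.mauc_in:.6f} "
            f"mauc_out={report.mauc_out:.6f} combined={report.combined:.6f}"
        )
    if not scored:
        raise RuntimeError("every candidate failed evaluation")
    best_index = 0
    for i, s in enumerate(scored):
        if s.combined > scored[best_index].combined:
            best_index = i
    audit.append(f"selected combo {scored[best_index].candidate.size_combo}")
    return SearchResult(scored, best_index, audit)


def run_search(data: CategoricalDataset, config: SearchConfig) -> SearchResult:
    """Steps 1-4 end to end."""
    candidates, audit = preselect_candidates(data, config)
    result = select_best_structure(data, candidates, config)
    result.audit = audit + result.audit
    return result


# ---------------------------------------------------------------------------
# interaction-strength profiling and the reduced structure
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class InteractionProfile:
    """Per-node interaction strengths over parent sub-combinations."""

    profiles: dict[str, dict[tuple[str, ...], float]]
    peaks: dict[str, tuple[str, ...]]

    def table(self) -> str:
        lines = ["node\tsubset\tsize\tis\tpeak"]
        for node in sorted(self.profiles):
            for subset, val in self.profiles[node].items():
                lines.append(
                    f"{node}\t{','.join(subset)}\t{len(subset)}\t{val:.12g}\t"
                    f"{int(subset == self.peaks[node])}"
                )
        return "\n".join(lines) + "\n"


def strongest_interacting_subsets(
    data: CategoricalDataset, structure: DbnStructure
) -> InteractionProfile:
    """IS over every parent sub-combination (singletons score 0) for each
    node with parents; the per-node argmax is the strongest interacting
    sub-parenthood."""
    profiles: dict[str, dict[tuple[str, ...], float]] = {}
    peaks: dict[str, tuple[str, ...]] = {}
    for node in sorted(structure.parents):
        parents = tuple(sorted(structure.parents[node]))
        if not parents:
            continue
        prof: dict[tuple[str, ...], float] = {}
        for k in range(1, len(parents) + 1):
            for subset in itertools.combinations(parents, k):
                prof[subset] = (
                    0.0 if k == 1 else interaction_strength(data, node, subset)
                )
        # deterministic argmax: strict improvement wins, first subset on ties
        best = None
        best_val = -np.inf
        for subset, val in prof.items():
            if val > best_val:
                best, best_val = subset, val
        profiles[node] = prof
        peaks[node] = best
    return InteractionProfile(profiles, peaks)


def reduce_to_strongest(
    structure: DbnStructure, profile: InteractionProfile
) -> DbnStructure:
    """Keep only arcs inside each node's strongest interacting subset and
    drop nodes left without arcs (the 'thick arrow' subgraph)."""
    new_parents = {
        node: tuple(p for p in structure.parents[node] if p in profile.peaks.get(node, ()))
        for node in structure.node_names
    }
    if structure.target is not None and not new_parents.get(structure.target):
        raise ValueError("reduction left the target parentless")
    connected = {n for n, ps in new_parents.items() if ps}
    for ps in new_parents.values():
        connected.update(ps)
    specs = tuple(s for s in structure.specs if s.name in connected)
    reduced = DbnStructure(
        specs, {n: ps for n, ps in new_parents.items() if n in connected}, structure.target
    )
    report = validate_structure(reduced)
    if not report.ok:
        raise RuntimeError(f"reduced structure invalid: {report.messages}")
    return reduced
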