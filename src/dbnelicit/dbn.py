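"""Three-slice discrete Bayesian network: structure, CPTs, exact inference.

The joint distribution factorizes over parenthoods,
``p(X_1..X_n) = prod_i p(X_i | pi(X_i))``.  Structures are constrained by
the timeline: every arc must point from an earlier (or equal) slice to a
later one, the intervention node has no parents (frames were assigned by
design, not caused by the questionnaire), and the target has no children.

Inference of the target posterior given partial evidence is exact: barren
nodes (unobserved non-target nodes without observed descendants) are
pruned, then the remaining free variables -- typically the latent Time-2
mediators -- are summed out by enumeration.  Networks here are tiny, so
enumeration after pruning is both fast and easy to audit.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import xml.etree.ElementTree as ET
from collections.abc import Mapping, Sequence

import networkx as nx
import numpy as np

from .variables import Slice, VariableSpec

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DbnStructure:
    """An acyclic parenthood map over a roster of variables.

    ``parents`` gives, for every node, the ordered tuple of its parents;
    ``target`` names the predicted node (may be ``None`` for fragments).
    """

    specs: tuple[VariableSpec, ...]
    parents: Mapping[str, tuple[str, ...]]
    target: "str | None" = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        names = {s.name for s in self.specs}
        par = {}
        for s in self.specs:
            par[s.name] = tuple(self.parents.get(s.name, ()))
        for child, ps in par.items():
            for p in ps:
                if p not in names:
                    raise ValueError(f"unknown parent {p!r} of {child!r}")
        object.__setattr__(self, "parents", par)
        if self.target is not None and self.target not in names:
            raise ValueError(f"unknown target {self.target!r}")

    # -- graph views -----------------------------------------------------
    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for child, ps in self.parents.items():
            g.add_edges_from((p, child) for p in ps)
        return g

    def children(self, name: str) -> tuple[str, ...]:
        return tuple(c for c in self.node_names if name in self.parents[c])

    def topological_order(self) -> tuple[str, ...]:
        """Deterministic topological order (ties broken by name)."""
        return tuple(nx.lexicographical_topological_sort(self.graph()))

    def arcs(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (p, c) for c in sorted(self.parents) for p in self.parents[c]
        )

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "nodes": [
                {
                    "name": s.name,
                    "slice": s.slice.name,
                    "levels": list(s.levels),
                    "discretization": s.discretization,
                }
                for s in self.specs
            ],
            "parents": {k: list(v) for k, v in sorted(self.parents.items())},
            "target": self.target,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DbnStructure":
        doc = json.loads(text)
        specs = tuple(
            VariableSpec(d["name"], Slice.parse(d["slice"]), tuple(d["levels"]), d["discretization"])
            for d in doc["nodes"]
        )
        return cls(specs, {k: tuple(v) for k, v in doc["parents"].items()}, doc.get("target"))


@dataclasses.dataclass
class ParameterSet:
    """One conditional probability table per node.

    ``cpts[name]`` has shape ``(*parent_levels, child_levels)``; slices
    along the last axis are proper distributions.
    """

    structure: DbnStructure
    cpts: dict[str, np.ndarray]
    converged: bool = True
    n_iterations: int = 0
    loglik_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in self.structure.node_names:
            cpt = np.asarray(self.cpts[name], dtype=float)
            shape = tuple(
                self.structure.spec(p).n_levels for p in self.structure.parents[name]
            ) + (self.structure.spec(name).n_levels,)
            if cpt.shape != shape:
                raise ValueError(f"{name}: CPT shape {cpt.shape} != expected {shape}")
            if (cpt < -1e-12).any() or (cpt > 1 + 1e-12).any():
                raise ValueError(f"{name}: CPT entries outside [0, 1]")
            rows = cpt.reshape(-1, shape[-1]).sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-9):
                raise ValueError(f"{name}: CPT rows do not sum to 1")
            self.cpts[name] = cpt

    def cpt(self, name: str) -> np.ndarray:
        return self.cpts[name]

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "structure": json.loads(self.structure.to_json()),
            "cpts": {
                name: {
                    "parents": list(self.structure.parents[name]),
                    "shape": list(self.cpts[name].shape),
                    # row-major over parent configurations, child level fastest
                    "table": [float(x) for x in self.cpts[name].ravel()],
                }
                for name in sorted(self.cpts)
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        doc = json.loads(text)
        structure = DbnStructure.from_json(json.dumps(doc["structure"]))
        cpts = {
            name: np.asarray(d["table"], dtype=float).reshape(d["shape"])
            for name, d in doc["cpts"].items()
        }
        return cls(structure, cpts)

    def to_xmlbif(self) -> str:
        """Serialize in the interchange XMLBIF dialect (child level fastest)."""
        root = ET.Element("BIF", VERSION="0.3")
        net = ET.SubElement(root, "NETWORK")
        ET.SubElement(net, "NAME").text = "dbnelicit"
        for s in self.structure.specs:
            var = ET.SubElement(net, "VARIABLE", TYPE="nature")
            ET.SubElement(var, "NAME").text = s.name
            for lv in s.levels:
                ET.SubElement(var, "OUTCOME").text = lv
            ET.SubElement(var, "PROPERTY").text = f"slice = {s.slice.name}"
        for s in self.structure.specs:
            dfn = ET.SubElement(net, "DEFINITION")
            ET.SubElement(dfn, "FOR").text = s.name
            for p in self.structure.parents[s.name]:
                ET.SubElement(dfn, "GIVEN").text = p
            ET.SubElement(dfn, "TABLE").text = " ".join(
                format(x, ".17g") for x in self.cpts[s.name].ravel()
            )
        ET.indent(root)
        return ET.tostring(root, encoding="unicode", xml_declaration=True)

    @classmethod
    def from_xmlbif(cls, text: str, slices: Mapping[str, Slice] | None = None) -> "ParameterSet":
        root = ET.fromstring(text)
        net = root.find("NETWORK")
        specs = {}
        for var in net.findall("VARIABLE"):
            name = var.findtext("NAME")
            levels = tuple(o.text for o in var.findall("OUTCOME"))
            slc = Slice.TIME1
            prop = var.findtext("PROPERTY") or ""
            if prop.startswith("slice"):
                slc = Slice.parse(prop.split("=", 1)[1])
            if slices and name in slices:
                slc = slices[name]
            specs[name] = VariableSpec(name, slc, levels, "none")
        parents = {}
        tables = {}
        for dfn in net.findall("DEFINITION"):
            name = dfn.findtext("FOR")
            ps = tuple(g.text for g in dfn.findall("GIVEN"))
            parents[name] = ps
            shape = tuple(specs[p].n_levels for p in ps) + (specs[name].n_levels,)
            tables[name] = np.fromstring(dfn.findtext("TABLE"), sep=" ").reshape(shape)
        target = next((n for n, s in specs.items() if s.slice == Slice.TARGET), None)
        structure = DbnStructure(tuple(specs.values()), parents, target)
        return cls(structure, tables)


# ---------------------------------------------------------------------------
# structural validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class StructureReport:
    """Outcome of the structural checks; ``ok`` iff all constraints hold."""

    acyclic: bool
    time_oriented: bool
    target_childless: bool
    intervention_parentless: bool
    messages: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return (
            self.acyclic
            and self.time_oriented
            and self.target_childless
            and self.intervention_parentless
        )


def validate_structure(structure: DbnStructure) -> StructureReport:
    """Check acyclicity, time orientation and the target/intervention roles."""
    msgs: list[str] = []
    g = structure.graph()
    acyclic = nx.is_directed_acyclic_graph(g)
    if not acyclic:
        cyc = nx.find_cycle(g)
        msgs.append("cycle: " + " -> ".join(u for u, _ in cyc))

    time_ok = True
    for child in sorted(structure.parents):
        cs = structure.spec(child).slice
        child_slice = Slice.TIME2 if cs == Slice.TARGET else cs
        for p in structure.parents[child]:
            ps = structure.spec(p).slice
            p_slice = Slice.TIME2 if ps == Slice.TARGET else ps
            if p_slice > child_slice:
                time_ok = False
                msgs.append(f"time-orientation violation: {p} -> {child}")

    target_childless = True
    for s in structure.specs:
        if s.slice == Slice.TARGET and structure.children(s.name):
            target_childless = False
            msgs.append(f"target {s.name} has children")

    intervention_parentless = True
    for s in structure.specs:
        if s.slice == Slice.INTERVENTION and structure.parents[s.name]:
            intervention_parentless = False
            msgs.append(f"intervention {s.name} has parents")

    return StructureReport(acyclic, time_ok, target_childless, intervention_parentless, tuple(msgs))


# ---------------------------------------------------------------------------
# exact inference
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PosteriorDistribution:
    """Posterior over the target levels; ``fallback`` marks zero-probability
    evidence resolved to a uniform distribution."""

    levels: tuple[str, ...]
    probabilities: np.ndarray
    fallback: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("posterior does not sum to 1")
        object.__setattr__(self, "probabilities", p)

    def argmax_level(self) -> int:
        """Index of the most probable level; ties go to the lowest index."""
        p = self.probabilities
        best = int(np.argmax(p))
        if np.sum(np.isclose(p, p[best], rtol=0, atol=1e-12)) > 1:
            log.info("posterior tie broken toward lowest level index")
        return best


def joint_probability(
    structure: DbnStructure, params: ParameterSet, assignment: Mapping[str, int]
) -> float:
    """Probability of one full configuration, as the product of CPT entries."""
    prob = 1.0
    for name in structure.node_names:
        if name not in assignment:
            raise ValueError(f"assignment misses node {name!r}")
        idx = tuple(assignment[p] for p in structure.parents[name]) + (assignment[name],)
        prob *= float(params.cpt(name)[idx])
    return prob


def _prune_barren(structure: DbnStructure, keep: set[str]) -> list[str]:
    """Drop unobserved nodes with no retained descendants (their factors sum
    to one); returns the active node list."""
    active = set(structure.node_names)
    changed = True
    while changed:
        changed = False
        for name in sorted(active):
            if name in keep:
                continue
            if not any(c in active for c in structure.children(name)):
                active.discard(name)
                changed = True
    return sorted(active)


def posterior_target(
    structure: DbnStructure, params: ParameterSet, evidence: Mapping[str, int]
) -> PosteriorDistribution:
    """Exact posterior of the target given partial evidence.

    Unobserved non-target nodes (e.g. all Time-2 mediators when predicting
    from baseline data) are marginalized.  Evidence on the target itself is
    a contract error.  If the evidence has probability zero under the
    model, a uniform posterior is returned with ``fallback=True``.
    """
    target = structure.target
    if target is None:
        raise ValueError("structure has no target node")
    if target in evidence:
        raise ValueError("evidence must not assign the target node")
    for name, val in evidence.items():
        spec = structure.spec(name)
        if not (0 <= int(val) < spec.n_levels):
            raise ValueError(f"evidence value {val} out of range for {name}")

    active = _prune_barren(structure, set(evidence) | {target})
    free = [n for n in active if n not in evidence and n != target]
    k_t = structure.spec(target).n_levels
    probs = np.zeros(k_t)
    free_levels = [range(structure.spec(n).n_levels) for n in free]
    for combo in itertools.product(*free_levels):
        assign = dict(evidence)
        assign.update(zip(free, combo))
        base = 1.0
        # factors not involving the target can be shared across target levels
        for name in active:
            if name == target or target in structure.parents[name]:
                continue
            idx = tuple(assign[p] for p in structure.parents[name]) + (assign[name],)
            base *= float(params.cpt(name)[idx])
        if base == 0.0:
            continue
        for v in range(k_t):
            assign[target] = v
            term = base
            for name in active:
                if name != target and target not in structure.parents[name]:
                    continue
                idx = tuple(assign[p] for p in structure.parents[name]) + (assign[name],)
                term *= float(params.cpt(name)[idx])
            probs[v] += term
        del assign[target]
    total = probs.sum()
    if total <= 0.0:
        log.warning("zero-probability evidence; falling back to a uniform posterior")
        return PosteriorDistribution(structure.spec(target).levels, np.full(k_t, 1.0 / k_t), True)
    return PosteriorDistribution(structure.spec(target).levels, probs / total, False)


def predict(
    structure: DbnStructure, params: ParameterSet, evidence: Mapping[str, int]
) -> int:
    """Most probable target level given the evidence (lowest index on ties)."""
    return posterior_target(structure, params, evidence).argmax_level()
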