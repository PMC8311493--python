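"""Raw study tables, target derivation and quantile discretization.

Entry point of the pipeline: a CSV of per-participant continuous
questionnaire indexes (plus demographics and the assigned message frame)
is parsed, the intention-change target is derived as the Time-2 minus
Time-1 intention index, and every continuous column is cut into ordered
categories at empirical quantiles -- tertiles for ordinary indexes,
quintiles for the target.

Conventions fixed here (the underlying questionnaire tooling does not
pin them down):

* quantile estimator: linear interpolation of order statistics
  (``numpy.quantile`` default, the classic "type 7");
* a value exactly equal to a breakpoint falls in the *lower* bin;
* coincident breakpoints (heavy Likert ties) collapse the affected bins
  into one, with a warning; downstream code sees fewer effective levels.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .variables import (
    MISSING,
    CategoricalDataset,
    Slice,
    VariableSpec,
    message_spec,
    quantile3,
    target_spec,
)

ID_COLUMN = "participant_id"
INTENTION_T1 = "intention_t1"
INTENTION_T2 = "intention_t2"
INTENTION_CHANGE = "intention_change"


class SchemaError(ValueError):
    """The CSV does not match the declared variable roster."""


@dataclasses.dataclass
class RawStudyTable:
    """Continuous per-participant study table plus its variable roster."""

    frame: pd.DataFrame
    specs: tuple[VariableSpec, ...]

    def __post_init__(self) -> None:
        self.specs = tuple(self.specs)

    @property
    def n(self) -> int:
        return len(self.frame)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)


# ---------------------------------------------------------------------------
# schema handling
# ---------------------------------------------------------------------------

def load_schema(path: "str | Path") -> tuple[VariableSpec, ...]:
    """Read a YAML/JSON variable-metadata config into a roster of specs.

    Each entry declares ``name``, ``slice`` and ``discretization``;
    ``levels`` is required for native categoricals and defaulted for
    quantile schemes.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return schema_from_mapping(doc)


def schema_from_mapping(doc: dict) -> tuple[VariableSpec, ...]:
    specs = []
    for entry in doc["variables"]:
        name = entry["name"]
        slc = Slice.parse(entry["slice"])
        disc = entry.get("discretization", "native-categorical")
        levels = entry.get("levels")
        if levels is None:
            if disc == "quantile-3":
                levels = quantile3(name, slc).levels
            elif disc == "quantile-5":
                levels = target_spec(name).levels
            else:
                raise SchemaError(f"{name}: native-categorical variables must declare levels")
        specs.append(VariableSpec(name, slc, tuple(levels), disc))
    return tuple(specs)


def default_study_schema() -> tuple[VariableSpec, ...]:
    """The study-shaped roster: ten Time-1 indexes, demographics, the
    four-frame message, six Time-2 message-perception indexes and the
    five-level intention-change target."""
    t1 = [
        "prevention", "promotion", "past_behavior", "past_outdoor_behavior",
        "attitude", "perceived_behavioral_control", "subjective_norm",
        "anticipated_positive_emotions", "anticipated_negative_emotions",
        INTENTION_T1,
    ]
    t2 = ["threat", "distress", "tone", "trust", "systematic_processing", "evaluation"]
    specs = [quantile3(nm, Slice.TIME1) for nm in t1]
    specs.append(quantile3("age", Slice.TIME1))
    specs.append(VariableSpec("sex", Slice.TIME1, ("female", "male", "other"), "native-categorical"))
    specs.append(VariableSpec(
        "education", Slice.TIME1,
        ("secondary", "bachelor", "postgraduate"), "native-categorical"))
    specs.append(message_spec())
    specs.extend(quantile3(nm, Slice.TIME2) for nm in t2)
    specs.append(target_spec())
    return tuple(specs)


# ---------------------------------------------------------------------------
# loading and target derivation
# ---------------------------------------------------------------------------

def _continuous_names(specs: Sequence[VariableSpec]) -> list[str]:
    return [s.name for s in specs if s.discretization.startswith("quantile")]


def load_raw_table(path: "str | Path", specs: Sequence[VariableSpec]) -> RawStudyTable:
    """Parse a study CSV against the declared roster.

    Numeric cells are parsed with a locale-independent decimal point;
    unparseable cells become missing.  The intention-change target is not
    expected as a CSV column -- its operands ``intention_t1`` and
    ``intention_t2`` are.
    """
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    specs = tuple(specs)
    required = []
    for s in specs:
        if s.name == INTENTION_CHANGE or s.slice == Slice.TARGET:
            required.extend([INTENTION_T1, INTENTION_T2])
        else:
            required.append(s.name)
    for col in required:
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    if ID_COLUMN in frame.columns and frame[ID_COLUMN].duplicated().any():
        dup = frame[ID_COLUMN][frame[ID_COLUMN].duplicated()].iloc[0]
        raise ValueError(f"duplicate {ID_COLUMN}: {dup!r}")

    numeric_cols = set(_continuous_names(specs)) - {INTENTION_CHANGE}
    numeric_cols |= {INTENTION_T1, INTENTION_T2} & set(frame.columns)
    out = frame.copy()
    for col in numeric_cols:
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    return RawStudyTable(out, specs)


def derive_intention_change(table: RawStudyTable) -> RawStudyTable:
    """Add ``intention_change`` = Time-2 minus Time-1 intention index.

    Missing in either operand propagates to the derived column.
    """
    frame = table.frame
    for col in (INTENTION_T1, INTENTION_T2):
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column: {col}")
    out = frame.copy()
    out[INTENTION_CHANGE] = pd.to_numeric(out[INTENTION_T2], errors="coerce") - pd.to_numeric(
        out[INTENTION_T1], errors="coerce"
    )
    return RawStudyTable(out, table.specs)


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

class DegenerateVariableError(ValueError):
    """A continuous variable has a single distinct observed value."""


@dataclasses.dataclass
class DiscretizationMap:
    """Fitted quantile breakpoints plus the effective (post-collapse) levels.

    ``breakpoints[name]`` holds strictly increasing cut points; a value
    ``v`` maps to the number of breakpoints strictly below it, with
    ``v == breakpoint`` assigned to the lower bin.  ``effective_levels``
    records the surviving labels after any tie collapse.
    """

    breakpoints: dict[str, np.ndarray]
    effective_levels: dict[str, tuple[str, ...]]

    def to_json(self) -> str:
        doc = {
            name: {
                "breakpoints": [float(b) for b in bp],
                "levels": list(self.effective_levels[name]),
            }
            for name, bp in sorted(self.breakpoints.items())
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationMap":
        doc = json.loads(text)
        return cls(
            {k: np.asarray(v["breakpoints"], dtype=float) for k, v in doc.items()},
            {k: tuple(v["levels"]) for k, v in doc.items()},
        )


def _collapse_ties(name: str, breaks: np.ndarray, levels: tuple[str, ...]):
    """Merge bins whose breakpoints coincide; warn when it happens."""
    keep = np.concatenate([[True], np.diff(breaks) > 0])
    if not keep.all():
        warnings.warn(
            f"{name}: coincident quantile breakpoints; collapsing "
            f"{len(breaks) - keep.sum()} bin(s)",
            stacklevel=3,
        )
    breaks = breaks[keep]
    # one label per surviving bin: keep the first len(breaks)+1 labels
    return breaks, tuple(levels[: len(breaks) + 1])


def fit_discretization(table: RawStudyTable, specs: Sequence[VariableSpec] | None = None) -> DiscretizationMap:
    """Fit per-variable quantile breakpoints on the non-missing values.

    Tertile schemes cut at the empirical 1/3 and 2/3 quantiles; quintile
    schemes at 0.2, 0.4, 0.6, 0.8.  Estimator: linear interpolation of
    order statistics.
    """
    specs = tuple(specs) if specs is not None else table.specs
    breakpoints: dict[str, np.ndarray] = {}
    levels: dict[str, tuple[str, ...]] = {}
    for s in specs:
        if not s.discretization.startswith("quantile"):
            continue
        vals = pd.to_numeric(table.frame[s.name], errors="coerce").to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise DegenerateVariableError(f"{s.name}: no observed values")
        if np.unique(vals).size < 2:
            raise DegenerateVariableError(f"{s.name}: single distinct value")
        k = s.n_levels
        probs = np.arange(1, k) / k
        breaks = np.quantile(vals, probs, method="linear")
        breaks, eff = _collapse_ties(s.name, breaks, s.levels)
        breakpoints[s.name] = breaks
        levels[s.name] = eff
    return DiscretizationMap(breakpoints, levels)


def bin_values(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    """Assign each value to its bin; exact breakpoint hits go to the lower bin."""
    values = np.asarray(values, dtype=float)
    out = np.searchsorted(breaks, values, side="left").astype(np.int16)
    out[np.isnan(values)] = MISSING
    return out


def discretize(
    table: RawStudyTable,
    dmap: DiscretizationMap,
    specs: Sequence[VariableSpec] | None = None,
) -> CategoricalDataset:
    """Map the raw table onto integer level codes.

    Continuous columns are cut at the fitted breakpoints (outer bins
    unbounded); native categoricals are passed through by label; missing
    stays missing.  Variables whose breakpoints collapsed come out with
    the reduced level set recorded in the map.
    """
    specs = tuple(specs) if specs is not None else table.specs
    out_specs: list[VariableSpec] = []
    cols: list[np.ndarray] = []
    n = table.n
    for s in specs:
        if s.discretization.startswith("quantile"):
            eff = dmap.effective_levels[s.name]
            spec = s if eff == s.levels else VariableSpec(s.name, s.slice, eff, "native-categorical")
            vals = pd.to_numeric(table.frame[s.name], errors="coerce").to_numpy(dtype=float)
            cols.append(bin_values(vals, dmap.breakpoints[s.name]))
            out_specs.append(spec)
        else:
            lut = {lv: i for i, lv in enumerate(s.levels)}
            col = np.full(n, MISSING, dtype=np.int16)
            for i, v in enumerate(table.frame[s.name]):
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                code = lut.get(str(v))
                if code is None:
                    warnings.warn(f"{s.name}: unknown label {v!r} treated as missing", stacklevel=2)
                else:
                    col[i] = code
            cols.append(col)
            out_specs.append(s)
    codes = np.column_stack(cols) if cols else np.empty((n, 0), dtype=np.int16)
    return CategoricalDataset(tuple(out_specs), codes)


def prepare_dataset(
    table: RawStudyTable, specs: Sequence[VariableSpec] | None = None
) -> tuple[CategoricalDataset, DiscretizationMap]:
    """Derive the target, fit quantiles and discretize, in one call."""
    table = derive_intention_change(table)
    specs = tuple(specs) if specs is not None else table.specs
    dmap = fit_discretization(table, specs)
    return discretize(table, dmap, specs), dmap
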