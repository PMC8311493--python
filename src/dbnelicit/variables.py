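"""Categorical variable metadata and discretized datasets.

The questionnaire study is modelled over three instants: a baseline
questionnaire (``TIME1``), a framed persuasive message (``INTERVENTION``)
and a post-message questionnaire (``TIME2``).  The prediction target --
the change in behavioural intention between the two questionnaires -- is
treated as a fourth pseudo-slice ``TARGET`` that sorts after ``TIME2``.

Every variable entering the network is categorical.  Continuous
questionnaire indexes (multi-item scale means on a 1--7 Likert range)
are discretized by empirical quantiles: tertiles for ordinary indexes
(``low``/``medium``/``high``) and quintiles for the intention-change
target (``high-negative`` ... ``high-positive``).  The message frame is
natively categorical with four levels (gain, non-loss, non-gain, loss).
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing cell in the integer-coded data matrix
MISSING: int = -1

Q3_LEVELS = ("low", "medium", "high")
Q5_LEVELS = ("high-negative", "low-negative", "neutral", "low-positive", "high-positive")
MESSAGE_LEVELS = ("gain", "non-loss", "non-gain", "loss")

DISCRETIZATIONS = ("quantile-3", "quantile-5", "native-categorical", "none")


class Slice(enum.IntEnum):
    """Time instant of a variable; arcs must never point backwards in time."""

    TIME1 = 0
    INTERVENTION = 1
    TIME2 = 2
    TARGET = 3

    @classmethod
    def parse(cls, text: "str | Slice") -> "Slice":
        if isinstance(text, Slice):
            return text
        return cls[str(text).strip().upper()]


@dataclasses.dataclass(frozen=True)
class VariableSpec:
    """A named categorical variable with a time slice and ordered levels.

    Parameters
    ----------
    name:
        Column name in the raw study table (and node name in the network).
    slice:
        Time instant the variable belongs to.
    levels:
        Ordered category labels; the order is meaningful for ordinal scales.
    discretization:
        How raw values map onto the levels: ``quantile-3``/``quantile-5``
        for continuous indexes, ``native-categorical`` for labels passed
        through as-is, ``none`` for variables that are already coded.
    """

    name: str
    slice: Slice
    levels: tuple[str, ...]
    discretization: str = "none"

    def __post_init__(self) -> None:
        object.__setattr__(self, "slice", Slice.parse(self.slice))
        object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        if self.discretization not in DISCRETIZATIONS:
            raise ValueError(f"unknown discretization {self.discretization!r}")
        if self.discretization == "quantile-3" and len(self.levels) != 3:
            raise ValueError(f"{self.name}: quantile-3 requires exactly 3 levels")
        if self.discretization == "quantile-5" and len(self.levels) != 5:
            raise ValueError(f"{self.name}: quantile-5 requires exactly 5 levels")
        if self.slice == Slice.INTERVENTION and self.discretization.startswith("quantile"):
            raise ValueError(f"{self.name}: the intervention variable is natively categorical")
        if len(self.levels) < 2:
            raise ValueError(f"{self.name}: a categorical variable needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"{self.name}: duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_index(self, label: str) -> int:
        try:
            return self.levels.index(str(label))
        except ValueError:
            raise KeyError(f"{label!r} is not a level of {self.name}") from None


def quantile3(name: str, slice_: "str | Slice") -> VariableSpec:
    """Convenience constructor for a tertile-discretized index."""
    return VariableSpec(name, Slice.parse(slice_), Q3_LEVELS, "quantile-3")


def target_spec(name: str = "intention_change") -> VariableSpec:
    """The five-level intention-change target."""
    return VariableSpec(name, Slice.TARGET, Q5_LEVELS, "quantile-5")


def message_spec(name: str = "message") -> VariableSpec:
    """The four-frame message-intervention variable."""
    return VariableSpec(name, Slice.INTERVENTION, MESSAGE_LEVELS, "native-categorical")


@dataclasses.dataclass
class CategoricalDataset:
    """Integer-coded participant records over a roster of variables.

    ``codes`` is an ``(n, p)`` integer matrix; cell values are level
    indexes into the matching :class:`VariableSpec` or :data:`MISSING`.
    """

    specs: tuple[VariableSpec, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.specs = tuple(self.specs)
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.specs):
            raise ValueError("codes shape does not match the variable roster")
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        self._index = {s.name: j for j, s in enumerate(self.specs)}
        for j, s in enumerate(self.specs):
            col = self.codes[:, j]
            bad = (col != MISSING) & ((col < 0) | (col >= s.n_levels))
            if bad.any():
                raise ValueError(f"{s.name}: out-of-range level code")

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return int(self.codes.shape[0])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.specs)

    def spec(self, name: str) -> VariableSpec:
        return self.specs[self._index[name]]

    def column_index(self, name: str) -> int:
        return self._index[name]

    def col(self, name: str) -> np.ndarray:
        return self.codes[:, self._index[name]]

    def complete_mask(self, names: Iterable[str]) -> np.ndarray:
        """Boolean mask of rows with no missing value among *names*."""
        mask = np.ones(self.n, dtype=bool)
        for nm in names:
            mask &= self.col(nm) != MISSING
        return mask

    def select_rows(self, mask: np.ndarray) -> "CategoricalDataset":
        return CategoricalDataset(self.specs, self.codes[np.asarray(mask)])

    def copy(self) -> "CategoricalDataset":
        return CategoricalDataset(self.specs, self.codes.copy())

    # -- interchange -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Labelled view of the records (missing cells become NaN)."""
        out = {}
        for j, s in enumerate(self.specs):
            col = self.codes[:, j]
            labels = np.asarray(s.levels, dtype=object)
            vals = np.where(col == MISSING, None, labels[np.clip(col, 0, None)])
            out[s.name] = vals
        return pd.DataFrame(out)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, specs: Sequence[VariableSpec]) -> "CategoricalDataset":
        specs = tuple(specs)
        codes = np.full((len(frame), len(specs)), MISSING, dtype=np.int16)
        for j, s in enumerate(specs):
            lut = {lv: i for i, lv in enumerate(s.levels)}
            for i, v in enumerate(frame[s.name]):
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    continue
                codes[i, j] = lut[str(v)]
        return cls(specs, codes)
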