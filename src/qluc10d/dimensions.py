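"""Descriptive system for the QLU-C10D health-state classifier.

The QLU-C10D describes a health state on 10 health-related quality-of-life
dimensions (four functioning scales, pain, and five cancer-relevant
symptoms), each with 4 ordinal levels (1 = no problems .. 4 = very much).
Together with a survival duration attribute this yields the alternatives
of the valuation choice experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

#: Canonical dimension order used everywhere (design columns, CSV layout,
#: coefficient vectors, state code strings).  Note the state-code
#: convention places fatigue before pain: e.g. "2111121111" is a little
#: impairment in physical functioning and pain.
DIMENSIONS: Tuple[str, ...] = (
    "physical",
    "role",
    "social",
    "emotional",
    "fatigue",
    "pain",
    "sleep",
    "appetite",
    "nausea",
    "bowel",
)

N_LEVELS = 4
DURATION_LEVELS: Tuple[int, ...] = (1, 2, 5, 10)


@dataclass(frozen=True)
class AttributeSpec:
    """Attribute space of the choice experiment.

    The default is the QLU-C10D instrument: 10 four-level dimensions plus
    a duration attribute taking 1, 2, 5 or 10 life-years.  Smaller spaces
    are used for exhaustively enumerable test instances.

    ``physical_split`` records that physical functioning is presented to
    respondents as two walk items (long walk / short walk) but is designed
    and scored as a single 4-level dimension; it is presentation metadata
    only and does not affect design or estimation.
    """

    dimensions: Tuple[str, ...] = DIMENSIONS
    n_levels: int = N_LEVELS
    duration_levels: Tuple[int, ...] = DURATION_LEVELS
    physical_split: bool = True

    def __post_init__(self) -> None:
        if len(self.dimensions) < 1:
            raise ValueError("at least one dimension required")
        if len(set(self.dimensions)) != len(self.dimensions):
            raise ValueError("dimension names must be unique")
        if self.n_levels < 2:
            raise ValueError("dimensions need at least 2 levels")
        d = self.duration_levels
        if any(t <= 0 for t in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("duration levels must be positive and strictly increasing")

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def n_states(self) -> int:
        """Number of distinct health states (4^10 = 1,048,576 by default)."""
        return self.n_levels ** self.n_dimensions

    @property
    def n_params(self) -> int:
        """Parameters of the duration-interaction choice model: one linear
        duration term plus (levels-1) dummies per dimension."""
        return 1 + self.n_dimensions * (self.n_levels - 1)


@dataclass(frozen=True)
class HealthState:
    """One QLU-C10D health state: a level in [1, 4] on each dimension.

    The canonical string code concatenates the levels in dimension order,
    e.g. ``"2111121111"`` = a little trouble with physical functioning and
    a little pain, no problems elsewhere.
    """

    levels: Tuple[int, ...]
    spec: AttributeSpec = field(default_factory=AttributeSpec, compare=False)

    def __post_init__(self) -> None:
        lv = tuple(int(x) for x in self.levels)
        object.__setattr__(self, "levels", lv)
        if len(lv) != self.spec.n_dimensions:
            raise ValueError(
                f"expected {self.spec.n_dimensions} levels, got {len(lv)}"
            )
        if any(not 1 <= x <= self.spec.n_levels for x in lv):
            raise ValueError(f"levels must lie in [1, {self.spec.n_levels}]: {lv}")

    @classmethod
    def from_code(cls, code: str, spec: AttributeSpec | None = None) -> "HealthState":
        spec = spec or AttributeSpec()
        if len(code) != spec.n_dimensions or not code.isdigit():
            raise ValueError(f"code must be {spec.n_dimensions} digits: {code!r}")
        return cls(tuple(int(c) for c in code), spec)

    @property
    def code(self) -> str:
        return "".join(str(x) for x in self.levels)

    def level(self, dimension: str) -> int:
        return self.levels[self.spec.dimensions.index(dimension)]


FULL_HEALTH = HealthState.from_code("1" * 10)
WORST_STATE = HealthState.from_code("4" * 10)


def differing_dimensions(
    state_a: Sequence[int] | HealthState, state_b: Sequence[int] | HealthState
) -> frozenset[int]:
    """Indices of the dimensions on which two states differ.

    The choice-set construction constrains this set's size (default 4) so
    respondents only have to scan a few highlighted rows per task.
    """
    a = state_a.levels if isinstance(state_a, HealthState) else tuple(state_a)
    b = state_b.levels if isinstance(state_b, HealthState) else tuple(state_b)
    if len(a) != len(b):
        raise ValueError("states have different dimensionality")
    return frozenset(i for i, (x, y) in enumerate(zip(a, b)) if x != y)
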