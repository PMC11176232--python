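"""Anchored preference weights, monotonicity repair, and utility scoring.

A fitted choice model gives a duration coefficient alpha (utility of one
life-year in full health) and level coefficients beta.  The preference
weight (utility decrement) of a dimension-level is the ratio beta/alpha,
dimensionless and anchored so full health scores 1 and being dead scores 0
by construction; states worse than dead score below 0.  Ratio standard
errors use the delta method on the fit's (clustered) covariance:

    Var(b/a) ~ Var(b)/a^2 + b^2 Var(a)/a^4 - 2 b Cov(a,b)/a^3

Within a dimension, worse levels must carry weakly larger decrements; an
estimated violation is repaired by pooling the offending adjacent levels
into one coefficient and re-estimating until the fit is monotone
("Model 2" in the conventional terminology of these valuation studies).

The module also maps questionnaire responses (13 QLQ-C30 items, 1-4
Likert) onto the 10-dimension health state and scores them against a
value set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .dimensions import DIMENSIONS, AttributeSpec, HealthState
from .model import ChoiceData, FittedChoiceModel, ModelSpec, fit as _fit


class AnchoringError(ValueError):
    """Duration coefficient is non-positive; utilities cannot be anchored."""


@dataclass(frozen=True)
class PreferenceWeight:
    """Utility decrement of one dimension-level, with delta-method CI."""

    dimension: str
    level: int
    decrement: float
    se: float
    ci_low: float
    ci_high: float


def decrements(
    fit: FittedChoiceModel, se_source: str = "clustered", z: float = 1.96
) -> List[PreferenceWeight]:
    """Delta-method preference weights beta/alpha from a fitted model.

    Level 1 of every dimension has decrement exactly 0.  With a merged
    model spec, all levels of a pooled block share the block's ratio.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    alpha = fit.alpha
    if alpha <= 0:
        raise AnchoringError(
            f"duration coefficient must be positive, got {alpha:.4g}; "
            "life-years must carry positive utility"
        )
    vcov = fit.vcov_clustered if se_source == "clustered" else fit.vcov_model
    var_a = float(vcov.loc["duration", "duration"])
    mspec = fit.model_spec
    out: List[PreferenceWeight] = []
    for dim in mspec.spec.dimensions:
        out.append(PreferenceWeight(dim, 1, 0.0, 0.0, 0.0, 0.0))
        for block in mspec.partition(dim):
            if 1 in block:
                for lv in sorted(block):
                    if lv > 1:
                        out.append(PreferenceWeight(dim, lv, 0.0, 0.0, 0.0, 0.0))
                continue
            name = f"{dim}_{''.join(map(str, block))}"
            b = float(fit.params[name])
            var_b = float(vcov.loc[name, name])
            cov_ab = float(vcov.loc["duration", name])
            d = b / alpha
            var_d = (
                var_b / alpha**2
                + b**2 * var_a / alpha**4
                - 2.0 * b * cov_ab / alpha**3
            )
            se = float(np.sqrt(max(var_d, 0.0)))
            for lv in block:
                out.append(PreferenceWeight(dim, lv, d, se, d - z * se, d + z * se))
    out.sort(key=lambda w: (mspec.spec.dimensions.index(w.dimension), w.level))
    return out


# -- monotonicity ------------------------------------------------------


@dataclass(frozen=True)
class MonotonicityViolation:
    """Adjacent level pair whose worse level has the less negative
    coefficient (strictly), within one dimension."""

    dimension: str
    level_low: int
    level_high: int
    coef_low: float
    coef_high: float


def check_monotonicity(
    source: FittedChoiceModel | Mapping[Tuple[str, int], float],
    spec: AttributeSpec | None = None,
) -> List[MonotonicityViolation]:
    """Find strict within-dimension monotonicity violations.

    Accepts either a fitted model or a plain coefficient mapping
    ``(dimension, level) -> coefficient``.  The level-1 reference enters
    with coefficient 0, so a positive level-2 coefficient is a violation
    too.  Exact ties are not violations.
    """
    if isinstance(source, FittedChoiceModel):
        mspec = source.model_spec
        blocks_by_dim = {}
        for dim in mspec.spec.dimensions:
            seq: List[Tuple[Tuple[int, ...], float]] = [((1,), 0.0)]
            for block in mspec.partition(dim):
                if 1 in block:
                    seq[0] = (tuple(sorted(set(block) | {1})), 0.0)
                    continue
                name = f"{dim}_{''.join(map(str, block))}"
                seq.append((block, float(source.params[name])))
            blocks_by_dim[dim] = seq
    else:
        spec = spec or AttributeSpec()
        blocks_by_dim = {
            dim: [((1,), 0.0)]
            + [((lv,), float(source[(dim, lv)]))
               for lv in range(2, spec.n_levels + 1)
               if (dim, lv) in source]
            for dim in spec.dimensions
            if any((dim, lv) in source for lv in range(2, spec.n_levels + 1))
        }
    violations = []
    for dim, seq in blocks_by_dim.items():
        for (lo_block, c_lo), (hi_block, c_hi) in zip(seq, seq[1:]):
            if c_hi > c_lo:  # strictly less negative than the better level
                violations.append(
                    MonotonicityViolation(
                        dim, max(lo_block), min(hi_block), c_lo, c_hi
                    )
                )
    return violations


def merge_and_refit(
    data: ChoiceData,
    spec: ModelSpec | None = None,
    fit: FittedChoiceModel | None = None,
    weights: Mapping | pd.Series | None = None,
    max_rounds: int = 20,
) -> Tuple[ModelSpec, FittedChoiceModel]:
    """Impose monotonicity by iterative pooling.

    Each round pools every dimension's first violating adjacent level pair
    into one block and re-estimates; rounds repeat until the fit is
    monotone.  Terminates because every merge strictly reduces the
    parameter count.  With no violations the input spec/fit are returned
    unchanged (the trivial partition is its own fixed point).
    """
    spec = spec or ModelSpec()
    if fit is None:
        fit = _fit(data, spec, weights=weights)
    for _ in range(max_rounds):
        violations = check_monotonicity(fit)
        if not violations:
            return fit.model_spec, fit
        mspec = fit.model_spec
        merged_dims = set()
        for v in violations:
            if v.dimension in merged_dims:
                continue  # one merge per dimension per round
            lo = next(
                b for b in ([(1,)] + list(mspec.partition(v.dimension)))
                if v.level_low in b
            )
            hi = next(
                b for b in mspec.partition(v.dimension) if v.level_high in b
            )
            mspec = mspec.merged(v.dimension, tuple(lo), tuple(hi))
            merged_dims.add(v.dimension)
        fit = _fit(data, mspec, weights=weights)
    raise RuntimeError("monotonicity repair did not terminate")  # pragma: no cover


# -- value set ---------------------------------------------------------


@dataclass
class ValueSet:
    """Country value set: a decrement for all 10 x 4 dimension-levels.

    ``utility(state) = 1 + sum_d decrement(d, level_d)``; decrements are
    non-positive for monotone sets, level 1 is always 0, full health is
    exactly 1, and values below 0 (worse than dead) are permitted.
    """

    weights: Dict[Tuple[str, int], PreferenceWeight]
    spec: AttributeSpec = field(default_factory=AttributeSpec)
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dim in self.spec.dimensions:
            for lv in range(1, self.spec.n_levels + 1):
                if (dim, lv) not in self.weights:
                    raise ValueError(f"missing weight for ({dim}, {lv})")
        for dim in self.spec.dimensions:
            w1 = self.weights[(dim, 1)]
            if w1.decrement != 0.0:
                raise ValueError(f"level-1 decrement must be 0 in {dim!r}")

    @classmethod
    def from_fit(
        cls, fit: FittedChoiceModel, se_source: str = "clustered", **provenance
    ) -> "ValueSet":
        ws = decrements(fit, se_source=se_source)
        return cls(
            {(w.dimension, w.level): w for w in ws},
            fit.model_spec.spec,
            {"model": fit.model_spec.column_names(), **provenance},
        )

    @classmethod
    def from_coefficients(
        cls,
        coefs: Mapping[Tuple[str, int], float],
        alpha: float,
        spec: AttributeSpec | None = None,
        **provenance,
    ) -> "ValueSet":
        """Value set from plain coefficients (e.g. a published table).
        No covariance is available, so SEs/CIs are NaN."""
        spec = spec or AttributeSpec()
        if alpha <= 0:
            raise AnchoringError("duration coefficient must be positive")
        weights = {}
        for dim in spec.dimensions:
            weights[(dim, 1)] = PreferenceWeight(dim, 1, 0.0, 0.0, 0.0, 0.0)
            for lv in range(2, spec.n_levels + 1):
                d = float(coefs[(dim, lv)]) / alpha
                weights[(dim, lv)] = PreferenceWeight(
                    dim, lv, d, float("nan"), float("nan"), float("nan")
                )
        return cls(weights, spec, dict(provenance))

    def decrement(self, dimension: str, level: int) -> float:
        return self.weights[(dimension, int(level))].decrement

    def utility(self, state: HealthState | str | Sequence[int]) -> float:
        if isinstance(state, str):
            state = HealthState.from_code(state, self.spec)
        elif not isinstance(state, HealthState):
            state = HealthState(tuple(state), self.spec)
        return 1.0 + sum(
            self.decrement(dim, lv)
            for dim, lv in zip(self.spec.dimensions, state.levels)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "dimension": w.dimension,
                "level": w.level,
                "decrement": w.decrement,
                "se": w.se,
                "ci_low": w.ci_low,
                "ci_high": w.ci_high,
            }
            for w in sorted(
                self.weights.values(),
                key=lambda w: (self.spec.dimensions.index(w.dimension), w.level),
            )
        ]
        return pd.DataFrame(rows)


def utility(state, valueset: ValueSet) -> float:
    """Utility of a health state under a value set (1 = full health,
    0 = dead; negative values are worse than dead)."""
    return valueset.utility(state)


def export_valueset(valueset: ValueSet, path: str | Path) -> None:
    """Write the 40-row value-set CSV and a provenance sidecar."""
    path = Path(path)
    valueset.to_frame().to_csv(path, index=False)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(valueset.provenance, indent=2, default=str)
    )


def read_valueset(path: str | Path, spec: AttributeSpec | None = None) -> ValueSet:
    path = Path(path)
    df = pd.read_csv(path)
    spec = spec or AttributeSpec(dimensions=tuple(dict.fromkeys(df["dimension"])))
    weights = {
        (r.dimension, int(r.level)): PreferenceWeight(
            r.dimension, int(r.level), float(r.decrement), float(r.se),
            float(r.ci_low), float(r.ci_high)
        )
        for r in df.itertuples()
    }
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    provenance = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ValueSet(weights, spec, provenance)


def reference_valueset() -> ValueSet:
    """The published Japanese value set reconstructed from the printed
    unweighted Model 1 coefficients (accurate to ~2 decimals because the
    published ratios used unrounded coefficients)."""
    from . import reference

    return ValueSet.from_coefficients(
        {k: v[0] for k, v in reference.UNWEIGHTED_M1.items()},
        reference.UNWEIGHTED_M1_DURATION[0],
        source="published unweighted Model 1 coefficients",
    )


# -- questionnaire scoring --------------------------------------------


@dataclass(frozen=True)
class QLQC30Mapping:
    """Item-to-dimension derivation for the 13 scoring items.

    ``items`` maps each dimension to the questionnaire item ids feeding
    it; ``rule`` is the combination rule for multi-item dimensions
    ("worst": the highest = worst response carries).  The exact published
    derivation table ships with the instrument's supplementary material,
    so the default here is a synthetic stand-in with the right shape
    (13 distinct items, walk items feeding physical functioning) and must
    be replaced by the official table for production scoring.
    """

    items: Mapping[str, Tuple[str, ...]]
    rule: str = "worst"

    def __post_init__(self) -> None:
        if self.rule not in ("worst",):
            raise ValueError(f"unknown combination rule {self.rule!r}")
        all_items = [i for its in self.items.values() for i in its]
        if len(set(all_items)) != len(all_items):
            raise ValueError("an item may feed only one dimension")
        for dim, its in self.items.items():
            if not its:
                raise ValueError(f"dimension {dim!r} maps from no items")

    @classmethod
    def default(cls) -> "QLQC30Mapping":
        return cls(
            items={
                "physical": ("q02", "q03"),  # long walk / short walk
                "role": ("q06", "q07"),
                "social": ("q26",),
                "emotional": ("q24",),
                "pain": ("q09", "q19"),
                "fatigue": ("q18",),
                "sleep": ("q11",),
                "appetite": ("q13",),
                "nausea": ("q14",),
                "bowel": ("q17",),
            }
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QLQC30Mapping":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            items={d: tuple(v) for d, v in raw["items"].items()},
            rule=raw.get("rule", "worst"),
        )

    @property
    def all_items(self) -> Tuple[str, ...]:
        return tuple(i for its in self.items.values() for i in its)


def derive_state(
    responses: Mapping[str, float], mapping: QLQC30Mapping, spec: AttributeSpec
) -> Tuple[int, ...] | None:
    """Dimension levels from one record's item responses; None when any
    needed item is missing."""
    levels = []
    for dim in spec.dimensions:
        vals = [responses.get(i) for i in mapping.items[dim]]
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            return None
        levels.append(int(max(vals)))  # "worst" rule
    return tuple(levels)


def score_qlqc30(
    records: pd.DataFrame,
    valueset: ValueSet,
    mapping: QLQC30Mapping | None = None,
    id_column: str = "record_id",
) -> pd.DataFrame:
    """Score questionnaire records against a value set.

    ``records`` has one row per record with the 13 item columns (values in
    [1, 4] or missing).  Returns record_id, the derived state code (or NA)
    and the utility; records with any missing needed item get a missing
    utility (the default policy) and are counted in ``.attrs['n_missing']``.
    """
    mapping = mapping or QLQC30Mapping.default()
    missing_cols = [i for i in mapping.all_items if i not in records.columns]
    if missing_cols:
        raise ValueError(f"missing item columns: {missing_cols}")
    for col in mapping.all_items:
        vals = records[col]
        bad = vals.dropna()[(vals.dropna() < 1) | (vals.dropna() > valueset.spec.n_levels)]
        if len(bad):
            raise ValueError(
                f"responses out of [1,{valueset.spec.n_levels}] in {col!r} "
                f"at rows {list(bad.index[:5])}"
            )
    out_rows = []
    n_missing = 0
    for _, row in records.iterrows():
        state = derive_state(row.to_dict(), mapping, valueset.spec)
        if state is None:
            n_missing += 1
            out_rows.append(
                {id_column: row.get(id_column), "state": pd.NA, "utility": np.nan}
            )
        else:
            code = "".join(map(str, state))
            out_rows.append(
                {id_column: row.get(id_column), "state": code,
                 "utility": valueset.utility(code)}
            )
    out = pd.DataFrame(out_rows)
    out.attrs["n_missing"] = n_missing
    return out
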