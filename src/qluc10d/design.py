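"""Constrained choice-experiment design: construction, D-error, allocation.

The valuation task asks respondents to choose between two health states,
each paired with a survival duration.  The designed experiment fixes which
pairs exist (default 960), subject to an overlap constraint — the two
states in a pair differ on exactly ``overlap`` quality-of-life dimensions
(default 4) so the task stays cognitively manageable.  Design quality is
measured by the D-error of the paired conditional logit information matrix
evaluated at prior coefficients; the search is a seeded random-restart
hill climb over pair replacements.

Each respondent then receives a randomized presentation: 16 of the design's
sets, a random A/B slot assignment per set, and a personal random dimension
order with duration always shown last.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .dimensions import AttributeSpec, differing_dimensions


class DegenerateDesignError(ValueError):
    """Raised when a design's information matrix is singular at the priors."""


@dataclass(frozen=True)
class ChoicePair:
    """One choice set: two (health state, duration) alternatives."""

    state_a: Tuple[int, ...]
    state_b: Tuple[int, ...]
    duration_a: float
    duration_b: float

    @property
    def differing_dims(self) -> frozenset[int]:
        return differing_dimensions(self.state_a, self.state_b)


@dataclass
class DCEDesign:
    """A designed experiment: choice pairs plus efficiency metadata."""

    pairs: List[ChoicePair]
    spec: AttributeSpec
    overlap: int
    seed: int | None = None
    priors: np.ndarray | None = None
    d_error: float | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    # -- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, p in enumerate(self.pairs):
            for alt, state, dur in (("A", p.state_a, p.duration_a),
                                    ("B", p.state_b, p.duration_b)):
                row = {"set_id": s, "alt": alt}
                row.update(dict(zip(self.spec.dimensions, state)))
                row["duration_years"] = dur
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        """Write the design CSV and a sidecar ``<path>.meta.json``."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "seed": self.seed,
            "overlap": self.overlap,
            "d_error": self.d_error,
            "priors": None if self.priors is None else list(map(float, self.priors)),
            "dimensions": list(self.spec.dimensions),
            "n_levels": self.spec.n_levels,
            "duration_levels": list(self.spec.duration_levels),
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "DCEDesign":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        dims = tuple(meta.get("dimensions") or
                     [c for c in df.columns if c not in ("set_id", "alt", "duration_years")])
        spec = AttributeSpec(
            dimensions=dims,
            n_levels=int(meta.get("n_levels", 4)),
            duration_levels=tuple(meta.get("duration_levels", (1, 2, 5, 10))),
        )
        pairs = []
        for set_id, grp in df.groupby("set_id", sort=True):
            grp = grp.set_index("alt")
            a, b = grp.loc["A"], grp.loc["B"]
            pairs.append(
                ChoicePair(
                    tuple(int(a[d]) for d in dims),
                    tuple(int(b[d]) for d in dims),
                    float(a["duration_years"]),
                    float(b["duration_years"]),
                )
            )
        overlap = meta.get("overlap")
        if overlap is None:
            overlap = len(pairs[0].differing_dims) if pairs else 0
        priors = meta.get("priors")
        return cls(
            pairs,
            spec,
            int(overlap),
            seed=meta.get("seed"),
            priors=None if priors is None else np.asarray(priors, float),
            d_error=meta.get("d_error"),
        )


# -- covariates and information ---------------------------------------


def alternative_covariates(
    state: Sequence[int], duration: float, spec: AttributeSpec
) -> np.ndarray:
    """Model covariates of one alternative: duration, then duration-scaled
    level dummies (levels 2..n per dimension; level 1 is the reference)."""
    x = np.zeros(spec.n_params)
    x[0] = duration
    for d, lv in enumerate(state):
        if lv > 1:
            x[1 + d * (spec.n_levels - 1) + (lv - 2)] = duration
    return x


def parameter_names(spec: AttributeSpec) -> List[str]:
    return ["duration"] + [
        f"{dim}_{lv}" for dim in spec.dimensions for lv in range(2, spec.n_levels + 1)
    ]


def _pair_diffs(pairs: Sequence[ChoicePair], spec: AttributeSpec) -> np.ndarray:
    return np.array(
        [
            alternative_covariates(p.state_a, p.duration_a, spec)
            - alternative_covariates(p.state_b, p.duration_b, spec)
            for p in pairs
        ]
    )


def fisher_information(
    pairs: Sequence[ChoicePair], priors: np.ndarray, spec: AttributeSpec
) -> np.ndarray:
    """Per-set information matrix of the paired conditional logit at the
    priors: mean over sets of p_A p_B (x_A - x_B)(x_A - x_B)'."""
    diffs = _pair_diffs(pairs, spec)
    eta = diffs @ np.asarray(priors, float)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    return (diffs * w[:, None]).T @ diffs / len(pairs)


def _is_singular(info: np.ndarray, rtol: float = 1e-12) -> bool:
    """Rank-deficiency test; slogdet alone can report a spuriously finite
    determinant for near-singular matrices."""
    s = np.linalg.eigvalsh(info)
    return s[-1] <= 0 or s[0] <= s[-1] * rtol


def _name_collinear(info: np.ndarray, spec: AttributeSpec) -> List[str]:
    names = parameter_names(spec)
    _, s, vt = np.linalg.svd(info)
    null = vt[s < s.max() * 1e-10] if s.max() > 0 else vt
    bad: set[str] = set()
    for v in null:
        bad.update(names[i] for i in np.nonzero(np.abs(v) > 1e-6)[0])
    return sorted(bad) or names


def d_error(design_or_info, priors=None, spec=None) -> float:
    """D-error = det(information)^(-1/K); smaller is better.

    Accepts either a :class:`DCEDesign` (with ``priors``) or a precomputed
    information matrix.  Raises :class:`DegenerateDesignError` naming the
    collinear parameters when the information matrix is singular.
    """
    if isinstance(design_or_info, DCEDesign):
        design = design_or_info
        priors = design.priors if priors is None else priors
        if priors is None:
            raise ValueError("priors required to evaluate the design")
        spec = design.spec
        info = fisher_information(design.pairs, priors, spec)
    else:
        info = np.asarray(design_or_info, float)
        if spec is None:
            raise ValueError("spec required with a raw information matrix")
    k = info.shape[0]
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet) or _is_singular(info):
        raise DegenerateDesignError(
            "singular information matrix; collinear parameters: "
            + ", ".join(_name_collinear(info, spec))
        )
    return float(np.exp(-logdet / k))


def relative_efficiency(design: DCEDesign, reference: DCEDesign,
                        priors: np.ndarray | None = None) -> float:
    """Efficiency of ``design`` relative to ``reference`` as a percentage
    (100 means equally efficient; the reference is usually the best known)."""
    priors = priors if priors is not None else design.priors
    return 100.0 * d_error(reference, priors) / d_error(design, priors)


# -- design search -----------------------------------------------------


def _random_pair(rng: np.random.Generator, spec: AttributeSpec, overlap: int) -> ChoicePair:
    n_dims, n_lv = spec.n_dimensions, spec.n_levels
    a = rng.integers(1, n_lv + 1, size=n_dims)
    b = a.copy()
    which = rng.choice(n_dims, size=overlap, replace=False)
    for d in which:
        shift = rng.integers(1, n_lv)  # cyclic shift guarantees a change
        b[d] = 1 + (a[d] - 1 + shift) % n_lv
    durs = rng.choice(spec.duration_levels, size=2)
    return ChoicePair(tuple(map(int, a)), tuple(map(int, b)),
                      float(durs[0]), float(durs[1]))


def generate_design(
    spec: AttributeSpec | None = None,
    n_sets: int = 960,
    overlap: int = 4,
    priors: np.ndarray | None = None,
    n_iter: int = 300,
    seed: int | None = None,
    n_restarts: int = 20,
) -> DCEDesign:
    """Search for a D-efficient constrained design.

    Starts from a random design whose every pair satisfies the overlap
    constraint exactly, then hill-climbs: propose replacing one random pair
    with a fresh random pair, accept when the D-error decreases.  The
    returned design's D-error is never worse than the initial candidate's,
    and the whole run is reproducible from ``seed``.

    ``priors`` is the coefficient vector at which the conditional-logit
    information is evaluated (default: the published Japanese unweighted
    Model 1 coefficients when the spec is the full instrument, zeros
    otherwise).
    """
    spec = spec or AttributeSpec()
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not 1 <= overlap <= spec.n_dimensions:
        raise ValueError(
            f"overlap must lie in [1, {spec.n_dimensions}], got {overlap}"
        )
    if priors is None:
        if spec.n_params == 31 and spec.n_levels == 4:
            from .reference import coefficient_vector

            priors = coefficient_vector().to_numpy()
        else:
            priors = np.zeros(spec.n_params)
    priors = np.asarray(priors, float)
    if priors.shape != (spec.n_params,):
        raise ValueError(f"priors must have length {spec.n_params}")

    rng = np.random.default_rng(seed)

    def contrib(pair: ChoicePair) -> np.ndarray:
        dx = alternative_covariates(pair.state_a, pair.duration_a, spec) - \
            alternative_covariates(pair.state_b, pair.duration_b, spec)
        eta = float(dx @ priors)
        p = 1.0 / (1.0 + np.exp(-eta))
        return p * (1.0 - p) * np.outer(dx, dx)

    def try_d_error(info_sum: np.ndarray) -> float:
        info = info_sum / n_sets
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0 or not np.isfinite(logdet) or _is_singular(info):
            return np.inf
        return float(np.exp(-logdet / spec.n_params))

    # random restarts until a non-degenerate starting design is found
    pairs = None
    for _ in range(n_restarts):
        cand = [_random_pair(rng, spec, overlap) for _ in range(n_sets)]
        contribs = [contrib(p) for p in cand]
        info_sum = np.sum(contribs, axis=0)
        err = try_d_error(info_sum)
        if np.isfinite(err):
            pairs, best_err = cand, err
            break
    if pairs is None:
        # structurally degenerate (e.g. fewer sets than parameters):
        # return the constrained design; evaluating its d_error raises.
        return DCEDesign(cand, spec, overlap, seed=seed, priors=priors,
                         d_error=float("inf"))

    for _ in range(n_iter):
        i = int(rng.integers(n_sets))
        new_pair = _random_pair(rng, spec, overlap)
        new_contrib = contrib(new_pair)
        new_info = info_sum - contribs[i] + new_contrib
        new_err = try_d_error(new_info)
        if new_err < best_err:
            pairs[i], contribs[i] = new_pair, new_contrib
            info_sum, best_err = new_info, new_err

    return DCEDesign(pairs, spec, overlap, seed=seed, priors=priors,
                     d_error=best_err)


# -- per-respondent randomized presentation ----------------------------


@dataclass(frozen=True)
class PresentationPlan:
    """Randomization of the survey for one respondent: which design sets
    they answer, the A/B slot assignment per set, and their personal
    dimension display order (duration is always shown last)."""

    respondent_id: int
    assigned_pairs: Tuple[int, ...]
    ab_swap: Tuple[bool, ...]
    dimension_order: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.assigned_pairs) != len(self.ab_swap):
            raise ValueError("ab_swap must match assigned_pairs in length")


def allocate(
    design: DCEDesign,
    n_respondents: int,
    per_respondent: int = 16,
    seed: int | None = None,
) -> List[PresentationPlan]:
    """Randomize the design over respondents.

    Each respondent gets ``per_respondent`` distinct sets sampled uniformly
    without replacement (independently across respondents), a fair-coin A/B
    swap per set, and a uniform random dimension order.
    """
    n_sets = len(design)
    if per_respondent > n_sets:
        raise ValueError(
            f"per_respondent ({per_respondent}) exceeds design size ({n_sets})"
        )
    rng = np.random.default_rng(seed)
    plans = []
    for rid in range(n_respondents):
        assigned = rng.choice(n_sets, size=per_respondent, replace=False)
        swaps = rng.random(per_respondent) < 0.5
        order = rng.permutation(design.spec.n_dimensions)
        plans.append(
            PresentationPlan(
                respondent_id=rid,
                assigned_pairs=tuple(int(s) for s in assigned),
                ab_swap=tuple(bool(s) for s in swaps),
                dimension_order=tuple(int(d) for d in order),
            )
        )
    return plans
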