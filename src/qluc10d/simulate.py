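"""Synthetic valuation cohorts: demographics, Gumbel choices, QC artifacts.

The study population cannot be redistributed, so every downstream stage is
exercised on simulated respondents instead.  Choice behavior follows the
same random-utility model the estimator assumes: systematic utility
V_j = alpha*t_j + sum beta_dl x_jdl t_j plus an independent Gumbel error
per alternative, which makes P(choose A) the logistic function of
V_A - V_B.  Defaults reproduce the study conditions: 2,435 respondents,
16 pairs each from a 960-set design, published Japanese coefficients as
the data-generating truth, unit Gumbel scale.

Demographics are drawn independently per variable from the valuation
sample's category shares, so they deliberately misrepresent the general
population on income, education, health status and psychological distress
— the pattern the raking weights exist to correct.

Two data-quality artifacts can be layered on: "straightliners" (a seeded
subset whose answers are overwritten with a constant slot) and survey
completion times (truncated log-normal), optionally coupled to a larger
noise scale for faster respondents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .dimensions import DIMENSIONS, AttributeSpec
from .design import DCEDesign, PresentationPlan, alternative_covariates
from .model import ChoiceData
from . import reference

DemographicMargins = Mapping[str, Mapping[str, float]]


def validate_margins(margins: DemographicMargins, tol: float = 1e-9) -> None:
    for var, cats in margins.items():
        if not cats:
            raise ValueError(f"variable {var!r} has no categories")
        total = sum(cats.values())
        if abs(total - 1.0) > tol:
            raise ValueError(
                f"proportions for {var!r} sum to {total!r}, not 1"
            )
        if any(p < 0 for p in cats.values()):
            raise ValueError(f"negative proportion in {var!r}")


@dataclass
class TrueModel:
    """Data-generating parameters of the random-utility model."""

    alpha: float
    beta: Dict[Tuple[str, int], float]
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if any(l == 1 for (_, l) in self.beta):
            raise ValueError("level 1 is the reference; no beta for level 1")

    @classmethod
    def from_reference(cls, weighted: bool = False, noise_scale: float = 1.0) -> "TrueModel":
        """Published Japanese Model 1 coefficients as the truth."""
        coefs = reference.WEIGHTED_M1 if weighted else reference.UNWEIGHTED_M1
        dur = (
            reference.WEIGHTED_M1_DURATION if weighted
            else reference.UNWEIGHTED_M1_DURATION
        )
        return cls(dur[0], {k: v[0] for k, v in coefs.items()}, noise_scale)

    def theta(self, spec: AttributeSpec) -> np.ndarray:
        """Coefficients in canonical parameter order (duration first)."""
        out = [self.alpha]
        for dim in spec.dimensions:
            for lv in range(2, spec.n_levels + 1):
                out.append(self.beta.get((dim, lv), 0.0))
        return np.asarray(out, float)


@dataclass
class SyntheticCohort:
    """Bundle of everything the simulator produced for one cohort."""

    demographics: pd.DataFrame
    plans: List[PresentationPlan]
    choices: ChoiceData
    completion_times: pd.Series | None = None
    straightliner_ids: Tuple[int, ...] = ()


def simulate_demographics(
    n: int,
    panel_margins: DemographicMargins | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw respondent categories independently per variable.

    Defaults to the valuation sample's composition, which differs from the
    population margins on the variables later used for raking.
    """
    margins = panel_margins if panel_margins is not None else reference.SAMPLE_MARGINS
    validate_margins(margins)
    rng = np.random.default_rng(seed)
    out = {"respondent_id": np.arange(n)}
    for var, cats in margins.items():
        names = list(cats)
        out[var] = rng.choice(names, size=n, p=[cats[c] for c in names])
    return pd.DataFrame(out)


def demographics_to_long(demographics: pd.DataFrame) -> pd.DataFrame:
    """Long export format: respondent_id, variable, category."""
    return demographics.melt(
        id_vars="respondent_id", var_name="variable", value_name="category"
    ).sort_values(["respondent_id", "variable"], kind="stable", ignore_index=True)


def simulate_choices(
    plans: Sequence[PresentationPlan],
    design: DCEDesign,
    truth: TrueModel | None = None,
    seed: int | None = None,
    noise_scales: Mapping[int, float] | pd.Series | None = None,
) -> ChoiceData:
    """Simulate every presented choice set under the random-utility model.

    Each plan's A/B swap is applied before simulation, so the exported data
    record the alternatives as presented.  ``noise_scales`` optionally sets
    a per-respondent Gumbel scale (overriding ``truth.noise_scale``), used
    to emulate lower-quality responding.
    """
    truth = truth if truth is not None else TrueModel.from_reference()
    spec = design.spec
    theta = truth.theta(spec)

    LA = np.array([p.state_a for p in design.pairs])
    LB = np.array([p.state_b for p in design.pairs])
    TA = np.array([p.duration_a for p in design.pairs])
    TB = np.array([p.duration_b for p in design.pairs])
    XA = np.array(
        [alternative_covariates(p.state_a, p.duration_a, spec) for p in design.pairs]
    )
    XB = np.array(
        [alternative_covariates(p.state_b, p.duration_b, spec) for p in design.pairs]
    )
    VA_all, VB_all = XA @ theta, XB @ theta

    rid = np.concatenate([[p.respondent_id] * len(p.assigned_pairs) for p in plans])
    idx = np.concatenate([p.assigned_pairs for p in plans]).astype(int)
    swap = np.concatenate([p.ab_swap for p in plans]).astype(bool)

    # presented slot A holds the design's B alternative where swapped
    VA = np.where(swap, VB_all[idx], VA_all[idx])
    VB = np.where(swap, VA_all[idx], VB_all[idx])
    lvA = np.where(swap[:, None], LB[idx], LA[idx])
    lvB = np.where(swap[:, None], LA[idx], LB[idx])
    tA = np.where(swap, TB[idx], TA[idx])
    tB = np.where(swap, TA[idx], TB[idx])

    if noise_scales is not None:
        smap = pd.Series(noise_scales, dtype=float)
        scale = smap.reindex(rid).to_numpy()
        if np.isnan(scale).any():
            raise ValueError("noise_scales missing for some respondents")
    else:
        scale = np.full(len(rid), truth.noise_scale)

    rng = np.random.default_rng(seed)
    eps = rng.gumbel(0.0, 1.0, size=(len(rid), 2)) * scale[:, None]
    choose_a = VA + eps[:, 0] > VB + eps[:, 1]

    n = len(rid)
    df = pd.DataFrame(
        {
            "respondent_id": np.repeat(rid, 2),
            "set_id": np.repeat(idx, 2),
            "alt": np.tile(["A", "B"], n),
            "chosen": np.where(
                np.tile([True, False], n),
                np.repeat(choose_a, 2),
                ~np.repeat(choose_a, 2),
            ).astype(int),
            "duration_years": np.stack([tA, tB], axis=1).ravel(),
        }
    )
    levels = np.stack([lvA, lvB], axis=1).reshape(-1, spec.n_dimensions)
    for d, name in enumerate(spec.dimensions):
        df[name] = levels[:, d]
    return ChoiceData(df, spec)


def inject_straightliners(
    data: ChoiceData, rate: float, seed: int | None = None
) -> Tuple[ChoiceData, Tuple[int, ...]]:
    """Overwrite a seeded random floor(rate * n) subset of respondents with
    constant-slot answers (all A or all B, fair coin per respondent)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    ids = np.unique(data.df["respondent_id"].to_numpy())
    n_inject = int(np.floor(rate * len(ids)))
    if n_inject == 0:
        return data, ()
    rng = np.random.default_rng(seed)
    picked = np.sort(rng.choice(ids, size=n_inject, replace=False))
    slots = np.where(rng.random(n_inject) < 0.5, "A", "B")
    df = data.df.copy()
    for rid, slot in zip(picked, slots):
        mask = df["respondent_id"] == rid
        df.loc[mask, "chosen"] = (df.loc[mask, "alt"] == slot).astype(int)
    return ChoiceData(df, data.spec), tuple(int(r) for r in picked)


def simulate_completion_times(
    respondent_ids: Sequence[int] | int,
    seed: int | None = None,
    median: float = reference.COMPLETION_TIME_MEDIAN,
    sigma: float = 0.45,
    bounds: Tuple[float, float] = (
        reference.COMPLETION_TIME_MIN,
        reference.COMPLETION_TIME_MAX,
    ),
) -> pd.Series:
    """Survey completion times in minutes: log-normal centred on the study
    median, truncated to the study range by rejection sampling."""
    if isinstance(respondent_ids, (int, np.integer)):
        respondent_ids = np.arange(int(respondent_ids))
    ids = np.asarray(respondent_ids)
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    out = np.empty(len(ids))
    remaining = np.arange(len(ids))
    while len(remaining):
        draw = np.exp(rng.normal(np.log(median), sigma, size=len(remaining)))
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return pd.Series(out, index=ids, name="completion_minutes").rename_axis(
        "respondent_id"
    )


def noise_scales_from_times(
    times: pd.Series, gamma: float = 1.0, base: float = 1.0
) -> pd.Series:
    """Couple shorter completion times to noisier choices:
    scale_i = base * (median_time / time_i)^gamma."""
    med = float(times.median())
    return base * (med / times) ** gamma


def simulate_cohort(
    design: DCEDesign,
    n_respondents: int = reference.STUDY_N_COMPLETERS,
    per_respondent: int = reference.STUDY_SETS_PER_RESPONDENT,
    truth: TrueModel | None = None,
    panel_margins: DemographicMargins | None = None,
    straightliner_rate: float = 0.0,
    time_noise_gamma: float | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """One-call cohort: demographics, plans, times, choices, straightliners.

    All stage seeds are spawned deterministically from ``seed``.
    """
    from .design import allocate

    ss = np.random.SeedSequence(seed)
    s_demo, s_alloc, s_time, s_choice, s_straight = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    ]
    demographics = simulate_demographics(n_respondents, panel_margins, s_demo)
    plans = allocate(design, n_respondents, per_respondent, s_alloc)
    times = simulate_completion_times(n_respondents, s_time)
    noise = (
        noise_scales_from_times(times, gamma=time_noise_gamma)
        if time_noise_gamma
        else None
    )
    choices = simulate_choices(plans, design, truth, s_choice, noise_scales=noise)
    straightliners: Tuple[int, ...] = ()
    if straightliner_rate > 0:
        choices, straightliners = inject_straightliners(
            choices, straightliner_rate, s_straight
        )
    return SyntheticCohort(demographics, plans, choices, times, straightliners)
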