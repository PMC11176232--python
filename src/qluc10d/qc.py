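"""Data-quality diagnostics for valuation choice data.

Three checks mirror standard practice for these surveys: flagging
straightliners (respondents who pick the same slot on every task),
a sensitivity refit with straightliners excluded (reporting the largest
and mean coefficient shift), and a completion-time decile analysis
(model fit and coefficient significance per speed decile, where fast,
low-quality responding shows up as few significant coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .model import ChoiceData, FittedChoiceModel, ModelSpec, fit as _fit


def flag_straightliners(data: ChoiceData) -> Tuple[int, ...]:
    """Respondents whose chosen slot (A or B) is constant across all of
    their completed sets."""
    df = data.df
    chosen_alt = df.loc[df["chosen"] == 1].groupby("respondent_id")["alt"].agg(
        ["nunique"]
    )
    flagged = chosen_alt.index[chosen_alt["nunique"] == 1]
    return tuple(sorted(flagged))


@dataclass
class SensitivityResult:
    """Coefficient shift from excluding a respondent subset (full - excluded)."""

    max_abs_diff: float
    mean_diff: float
    differences: pd.Series
    n_excluded: int


def sensitivity_refit(
    data: ChoiceData,
    exclude_ids: Sequence[int],
    spec: ModelSpec | None = None,
    weights: Mapping | pd.Series | None = None,
    fit_full: FittedChoiceModel | None = None,
) -> SensitivityResult:
    """Refit with ``exclude_ids`` dropped and compare coefficients.

    An empty exclusion returns exact zeros.  Excluding nearly everyone can
    leave degenerate choices; estimation errors propagate to the caller.
    """
    spec = spec or ModelSpec()
    if fit_full is None:
        fit_full = _fit(data, spec, weights=weights)
    exclude = set(exclude_ids)
    if not exclude:
        zeros = pd.Series(0.0, index=fit_full.params.index)
        return SensitivityResult(0.0, 0.0, zeros, 0)
    keep = ~data.df["respondent_id"].isin(exclude)
    sub = ChoiceData(data.df.loc[keep].reset_index(drop=True), data.spec)
    if weights is not None:
        weights = pd.Series(weights, dtype=float)
        weights = weights[~weights.index.isin(exclude)]
    fit_sub = _fit(sub, spec, weights=weights)
    diff = fit_full.params - fit_sub.params
    return SensitivityResult(
        float(diff.abs().max()), float(diff.mean()), diff, len(exclude)
    )


def assign_time_deciles(times: pd.Series, n_deciles: int = 10) -> pd.Series:
    """Decile index (1 = fastest) per respondent.

    Respondents are ranked by completion time with ties broken by
    respondent id, then split into groups whose sizes differ by at most
    one — a deterministic partition.
    """
    order = times.rename("time").rename_axis("respondent_id").reset_index()
    order = order.sort_values(["time", "respondent_id"],
                              kind="stable", ignore_index=True)
    groups = np.array_split(np.arange(len(order)), n_deciles)
    decile = np.empty(len(order), int)
    for d, idx in enumerate(groups, start=1):
        decile[idx] = d
    return pd.Series(decile, index=order["respondent_id"], name="decile")


def time_decile_analysis(
    data: ChoiceData,
    completion_times: pd.Series,
    spec: ModelSpec | None = None,
    n_deciles: int = 10,
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Fit the choice model within each completion-time decile.

    Returns one row per decile: n respondents, pseudo-R2, and the count of
    coefficients significant at the 5% level (clustered SEs).  A decile
    whose fit fails is reported with NaNs and the error message rather
    than aborting the whole analysis.
    """
    spec = spec or ModelSpec()
    resp = data.df["respondent_id"].unique()
    missing = set(resp) - set(completion_times.index)
    if missing:
        raise ValueError(f"completion times missing for {len(missing)} respondents")
    deciles = assign_time_deciles(completion_times.loc[resp], n_deciles)
    z_crit = stats.norm.ppf(1.0 - alpha_level / 2.0)
    rows = []
    for d in range(1, n_deciles + 1):
        ids = deciles.index[deciles == d]
        sub_df = data.df[data.df["respondent_id"].isin(ids)]
        row = {"decile": d, "n_respondents": len(ids)}
        try:
            f = _fit(ChoiceData(sub_df.reset_index(drop=True), data.spec), spec)
            z = (f.params / f.se("clustered")).abs()
            row.update(
                pseudo_r2=f.pseudo_r2,
                n_significant=int((z > z_crit).sum()),
                n_coefficients=len(f.params),
                error="",
            )
        except Exception as exc:  # per-decile failures are not fatal
            row.update(pseudo_r2=np.nan, n_significant=np.nan,
                       n_coefficients=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class QCReport:
    """Aggregate data-quality report."""

    straightliner_ids: Tuple[int, ...]
    sensitivity: SensitivityResult | None
    decile_table: pd.DataFrame | None

    @property
    def n_straightliners(self) -> int:
        return len(self.straightliner_ids)


def qc_report(
    data: ChoiceData,
    completion_times: pd.Series | None = None,
    spec: ModelSpec | None = None,
    weights: Mapping | pd.Series | None = None,
) -> QCReport:
    """Run all diagnostics that the supplied inputs allow."""
    spec = spec or ModelSpec()
    ids = flag_straightliners(data)
    sens = sensitivity_refit(data, ids, spec, weights=weights)
    deciles = (
        time_decile_analysis(data, completion_times, spec)
        if completion_times is not None
        else None
    )
    return QCReport(ids, sens, deciles)
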