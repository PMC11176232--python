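"""Raking (iterative proportional fitting) weights and variance inflation.

Quota sampling matches an online panel to the population on sex and age
but leaves other measured characteristics (income, education, health
status, psychological distress) misrepresented.  Raking repairs this:
weights are scaled cyclically, one variable at a time, by the ratio of
the target category share to the current weighted share, until every
margin matches.  The price of weighting is variance: the module also
quantifies the percentage increase in coefficient standard errors between
an unweighted and a weighted fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import FittedChoiceModel


class RakingError(RuntimeError):
    """Raking cannot proceed (empty sample cell for a positive target)."""


@dataclass
class RakingResult:
    """Converged raking weights (normalized to mean 1) and diagnostics."""

    weights: pd.Series
    iterations: int
    converged: bool
    max_margin_error: float

    def margin_error(
        self, sample: pd.DataFrame, targets: Mapping[str, Mapping[str, float]]
    ) -> float:
        return _max_margin_error(sample, self.weights, targets)


def _weighted_shares(cats: pd.Series, w: np.ndarray) -> pd.Series:
    return pd.Series(w).groupby(cats.to_numpy()).sum() / w.sum()


def _max_margin_error(
    sample: pd.DataFrame, weights: pd.Series, targets: Mapping[str, Mapping[str, float]]
) -> float:
    w = weights.reindex(sample["respondent_id"]).to_numpy()
    err = 0.0
    for var, target in targets.items():
        shares = _weighted_shares(sample[var], w)
        for cat, t in target.items():
            err = max(err, abs(float(shares.get(cat, 0.0)) - t))
    return err


def rake(
    sample: pd.DataFrame,
    target_margins: Mapping[str, Mapping[str, float]],
    tol: float = 1e-6,
    max_iter: int = 100,
    cap: float | None = None,
) -> RakingResult:
    """Iterative proportional fitting of respondent weights to margins.

    ``sample`` has a ``respondent_id`` column plus one categorical column
    per raking variable; ``target_margins`` maps each variable to its
    category -> target proportion table (summing to 1).  Weights start at
    1 and are scaled per variable until the worst absolute margin error is
    below ``tol``.  An optional ``cap`` trims weights to [1/cap, cap]
    after each cycle (off by default).  Returned weights are indexed by
    respondent and normalized to mean 1.
    """
    from .simulate import validate_margins

    validate_margins(target_margins, tol=1e-9)
    missing_vars = [v for v in target_margins if v not in sample.columns]
    if missing_vars:
        raise ValueError(f"sample lacks raking variables: {missing_vars}")
    for var in target_margins:
        if sample[var].isna().any():
            raise ValueError(f"missing category assignments in {var!r}")
        observed = set(sample[var].unique())
        for cat, t in target_margins[var].items():
            if t > 0 and cat not in observed:
                raise RakingError(
                    f"no sample members in {var!r}={cat!r} but target is {t:g}"
                )

    ids = sample["respondent_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("one row per respondent required")
    w = np.ones(len(sample), float)
    cats = {var: sample[var].to_numpy() for var in target_margins}

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for var, target in target_margins.items():
            shares = _weighted_shares(pd.Series(cats[var]), w)
            factor = np.ones(len(w))
            for cat, t in target.items():
                cur = float(shares.get(cat, 0.0))
                if cur > 0:
                    factor[cats[var] == cat] = t / cur
            w = w * factor
        if cap is not None:
            w = np.clip(w, 1.0 / cap, cap)
        w = w / w.mean()
        err = max(
            abs(float(_weighted_shares(pd.Series(cats[var]), w).get(cat, 0.0)) - t)
            for var, target in target_margins.items()
            for cat, t in target.items()
        )
        if err < tol:
            converged = True
            break

    weights = pd.Series(w / w.mean(), index=pd.Index(ids, name="respondent_id"),
                        name="weight")
    return RakingResult(weights, it, converged, err)


def write_weights(result: RakingResult, path) -> None:
    result.weights.reset_index().to_csv(path, index=False)


def read_weights(path) -> pd.Series:
    df = pd.read_csv(path)
    return df.set_index("respondent_id")["weight"]


# -- variance inflation ------------------------------------------------


@dataclass
class VarianceInflation:
    """Per-coefficient percentage increase of weighted over unweighted SEs."""

    per_coefficient: pd.Series  # percent, same index as the coefficients
    summary: Dict[str, float]   # min / median / mean / max

    def rounded(self) -> pd.Series:
        return self.per_coefficient.round().astype(int)


def variance_inflation(
    unweighted_fit: FittedChoiceModel | pd.Series,
    weighted_fit: FittedChoiceModel | pd.Series,
    se_source: str = "clustered",
) -> VarianceInflation:
    """(weighted SE - unweighted SE) / unweighted SE, as percent.

    Accepts fitted models (must share the same model layout) or plain SE
    Series.  Reported per coefficient plus min/median/mean/max summaries.
    """
    def se_of(x):
        return x.se(se_source) if isinstance(x, FittedChoiceModel) else pd.Series(x, dtype=float)

    if isinstance(unweighted_fit, FittedChoiceModel) and isinstance(
        weighted_fit, FittedChoiceModel
    ):
        if list(unweighted_fit.params.index) != list(weighted_fit.params.index):
            raise ValueError("fits have different model specifications")
    se_u, se_w = se_of(unweighted_fit), se_of(weighted_fit)
    if list(se_u.index) != list(se_w.index):
        raise ValueError("coefficient sets differ between fits")
    pct = (se_w - se_u) / se_u * 100.0
    summary = {
        "min": float(pct.min()),
        "median": float(pct.median()),
        "mean": float(pct.mean()),
        "max": float(pct.max()),
    }
    return VarianceInflation(pct.rename("inflation_pct"), summary)
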