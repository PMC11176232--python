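"""QALY-anchored paired conditional logit with clustered sandwich variances.

The utility of alternative j for respondent i in choice set s is

    U_isj = alpha * TIME_isj + sum_dl beta_dl * x_isj,dl * TIME_isj + eps_isj

with Gumbel errors, so the probability of choosing A over B is the logistic
function of the difference in systematic utilities.  Every covariate is an
interaction with survival duration, which forces utility to zero at zero
life-years — the anchoring required by the QALY framework (dead = 0).

The model has 31 parameters in its unrestricted form: a linear duration
term and 30 duration-scaled level dummies (levels 2-4 of 10 dimensions,
level 1 the reference).  A merge specification can pool adjacent levels of
a dimension into one coefficient; that is how monotonicity violations are
repaired downstream.

Estimation is Newton-Raphson on the (optionally respondent-weighted)
paired-logit log-likelihood with analytic gradient and Hessian; the
likelihood is concave so this converges quickly.  Standard errors come
from either the model-based inverse information or a respondent-clustered
sandwich estimator, the latter accounting for each respondent answering
up to 16 sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dimensions import DIMENSIONS, AttributeSpec

META_COLUMNS = ("respondent_id", "set_id", "alt", "chosen", "duration_years")


class NonConvergenceError(RuntimeError):
    """Optimizer failed to converge (e.g. complete separation)."""


class CollinearityError(ValueError):
    """Singular Hessian / information matrix; names the offending columns."""


# -- data --------------------------------------------------------------


@dataclass
class ChoiceData:
    """Long-format paired choice data.

    One row per alternative: ``respondent_id, set_id, alt (A/B), chosen,
    duration_years`` plus one level column per dimension in canonical
    order.  Every (respondent, set) has exactly two rows, exactly one of
    them chosen.
    """

    df: pd.DataFrame
    spec: AttributeSpec = field(default_factory=AttributeSpec)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in META_COLUMNS if c not in df.columns]
        missing += [d for d in self.spec.dimensions if d not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        for d in self.spec.dimensions:
            lv = df[d].to_numpy()
            if ((lv < 1) | (lv > self.spec.n_levels)).any():
                raise ValueError(f"levels out of [1,{self.spec.n_levels}] in {d!r}")
        if (df["duration_years"] <= 0).any():
            raise ValueError("durations must be positive")
        counts = df.groupby(["respondent_id", "set_id"], sort=False).agg(
            n=("alt", "size"), chosen=("chosen", "sum")
        )
        if (counts["n"] != 2).any() or (counts["chosen"] != 1).any():
            bad = counts[(counts["n"] != 2) | (counts["chosen"] != 1)]
            raise ValueError(
                f"{len(bad)} (respondent, set) groups are not complete "
                "pairs with exactly one chosen alternative"
            )

    @classmethod
    def from_csv(cls, path: str | Path, spec: AttributeSpec | None = None) -> "ChoiceData":
        return cls(pd.read_csv(path), spec or AttributeSpec())

    def to_csv(self, path: str | Path) -> None:
        cols = list(META_COLUMNS[:2]) + ["alt", "chosen", "duration_years"] + list(
            self.spec.dimensions
        )
        self.df[cols].to_csv(path, index=False)

    @property
    def n_respondents(self) -> int:
        return self.df["respondent_id"].nunique()

    @property
    def n_sets(self) -> int:
        return len(self.df) // 2


# -- model specification ----------------------------------------------

LevelBlock = Tuple[int, ...]


@dataclass(frozen=True)
class ModelSpec:
    """Dummy-variable layout of the choice model.

    ``merges`` maps a dimension name to its ordered partition of levels
    2..4 into contiguous blocks sharing one coefficient, e.g.
    ``{"sleep": ((2, 3), (4,))}``.  A block containing level 1 is absorbed
    into the reference (coefficient 0).  Without merges the model has
    1 + 10*3 = 31 parameters.
    """

    spec: AttributeSpec = field(default_factory=AttributeSpec)
    merges: Mapping[str, Tuple[LevelBlock, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        levels = tuple(range(2, self.spec.n_levels + 1))
        for dim, partition in self.merges.items():
            if dim not in self.spec.dimensions:
                raise ValueError(f"unknown dimension {dim!r}")
            flat = [l for block in partition for l in block]
            covered = [l for l in flat if l >= 2]
            if sorted(covered) != list(levels):
                raise ValueError(f"partition for {dim!r} must cover levels {levels}")
            for block in partition:
                b = sorted(block)
                if b != list(range(b[0], b[-1] + 1)):
                    raise ValueError(f"blocks must be contiguous: {block}")

    def partition(self, dim: str) -> Tuple[LevelBlock, ...]:
        default = tuple((l,) for l in range(2, self.spec.n_levels + 1))
        return tuple(tuple(sorted(b)) for b in self.merges.get(dim, default))

    def columns(self) -> List[Tuple[str, LevelBlock]]:
        """Estimated interaction columns as (dimension, level block),
        excluding blocks absorbed into the level-1 reference."""
        cols = []
        for dim in self.spec.dimensions:
            for block in self.partition(dim):
                if 1 not in block:
                    cols.append((dim, block))
        return cols

    def column_names(self) -> List[str]:
        return ["duration"] + [
            f"{dim}_{''.join(map(str, block))}" for dim, block in self.columns()
        ]

    @property
    def n_params(self) -> int:
        return 1 + len(self.columns())

    def merged(self, dim: str, lo_block: LevelBlock, hi_block: LevelBlock) -> "ModelSpec":
        """Return a spec with the two adjacent level blocks of ``dim``
        pooled into one.  ``lo_block`` may be the implicit level-1
        reference ``(1,)``, in which case ``hi_block`` is absorbed into
        the reference (decrement 0)."""
        lo = tuple(sorted(lo_block))
        hi = tuple(sorted(hi_block))
        blocks = list(self.partition(dim))
        if 1 in lo and lo not in blocks:
            blocks = [lo] + blocks  # materialize the reference block
        try:
            i, j = blocks.index(lo), blocks.index(hi)
        except ValueError:
            raise ValueError(f"{lo}/{hi} are not blocks of {dim!r}") from None
        if j != i + 1:
            raise ValueError(f"blocks {lo} and {hi} are not adjacent in {dim!r}")
        new_blocks = blocks[:i] + [tuple(sorted(set(lo) | set(hi)))] + blocks[j + 1:]
        merges = dict(self.merges)
        merges[dim] = tuple(new_blocks)
        return replace(self, merges=merges)


def build_design_matrix(
    data: ChoiceData | pd.DataFrame, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Covariate matrix, one row per alternative.

    The first column is duration in years; each remaining column is
    duration times the indicator that the dimension's level falls in the
    column's level block.  At full health every interaction column is 0,
    so systematic utility is alpha * t exactly.
    """
    spec = spec or ModelSpec()
    df = data.df if isinstance(data, ChoiceData) else data
    unknown_check = isinstance(data, pd.DataFrame)
    for d in spec.spec.dimensions:
        if d not in df.columns:
            raise ValueError(f"missing dimension column {d!r}")
        if unknown_check:
            lv = df[d].to_numpy()
            if ((lv < 1) | (lv > spec.spec.n_levels)).any():
                raise ValueError(f"levels out of range in {d!r}")
    t = df["duration_years"].to_numpy(float)
    out = {"duration": t}
    for dim, block in spec.columns():
        ind = df[dim].isin(block).to_numpy()
        out[f"{dim}_{''.join(map(str, block))}"] = t * ind
    return pd.DataFrame(out, index=df.index)


# -- fitted model ------------------------------------------------------


@dataclass
class FittedChoiceModel:
    """Estimates and inference artifacts of a paired conditional logit."""

    params: pd.Series
    vcov_model: pd.DataFrame
    vcov_clustered: pd.DataFrame
    loglik: float
    n_respondents: int
    n_sets: int
    n_rows: int
    converged: bool
    n_iter: int
    gradient_norm: float
    model_spec: ModelSpec
    # per-set internals retained for sandwich recomputation and refits
    _xd: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)
    _w: np.ndarray | None = field(default=None, repr=False)
    _cluster: np.ndarray | None = field(default=None, repr=False)

    @property
    def alpha(self) -> float:
        """Utility of one life-year in full health."""
        return float(self.params["duration"])

    @property
    def beta(self) -> pd.Series:
        return self.params.drop("duration")

    def se(self, source: str = "clustered") -> pd.Series:
        v = self.vcov_clustered if source == "clustered" else self.vcov_model
        # the sandwich is PSD; rounding can leave tiny negative diagonals
        diag = np.clip(np.diag(v), 0.0, None)
        return pd.Series(np.sqrt(diag), index=self.params.index, name="se")

    # fit statistics ---------------------------------------------------

    @property
    def loglik_null(self) -> float:
        """Log-likelihood of coin-flip choices over the (weighted) sets."""
        w_total = float(self._w.sum()) if self._w is not None else self.n_sets
        return w_total * np.log(0.5)

    @property
    def pseudo_r2(self) -> float:
        return 1.0 - self.loglik / self.loglik_null

    @property
    def k(self) -> int:
        return len(self.params)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def bic(self) -> float:
        # sample size = number of alternative rows (2 per choice set)
        return self.k * np.log(self.n_rows) - 2.0 * self.loglik


def fit_statistics(fit: FittedChoiceModel) -> Dict[str, float]:
    if not fit.converged:
        raise NonConvergenceError("fit did not converge")
    return {"pseudo_r2": fit.pseudo_r2, "aic": fit.aic, "bic": fit.bic,
            "loglik": fit.loglik, "k": fit.k, "n_rows": fit.n_rows}


# -- estimation --------------------------------------------------------


def _pairwise_arrays(
    data: ChoiceData, spec: ModelSpec, weights: Mapping | pd.Series | None
):
    """Difference covariates per set: Xd = X_A - X_B, y = 1{A chosen},
    per-set weight and respondent id."""
    df = data.df.sort_values(["respondent_id", "set_id", "alt"], kind="stable")
    Xfull = build_design_matrix(df, spec).to_numpy()
    alt = df["alt"].to_numpy()
    if not (np.all(alt[0::2] == "A") and np.all(alt[1::2] == "B")):
        raise ValueError("each (respondent, set) must have one A and one B row")
    xd = Xfull[0::2] - Xfull[1::2]
    y = df["chosen"].to_numpy(float)[0::2]
    resp = df["respondent_id"].to_numpy()[0::2]
    if weights is None:
        w = np.ones(len(y))
    else:
        wmap = pd.Series(weights, dtype=float)
        if (wmap <= 0).any():
            raise ValueError("weights must be positive")
        w = wmap.reindex(resp).to_numpy()
        if np.isnan(w).any():
            raise ValueError("weights missing for some respondents")
    return xd, y, w, resp


def fit(
    data: ChoiceData | pd.DataFrame,
    spec: ModelSpec | None = None,
    weights: Mapping | pd.Series | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FittedChoiceModel:
    """Maximize the (weighted) paired-logit log-likelihood by Newton-Raphson.

    ``weights`` are per-respondent pseudo-likelihood multipliers (e.g.
    raking weights); each respondent's log-likelihood contribution and
    score are scaled by their weight.  Standard errors are always computed
    with the respondent-clustered sandwich alongside the model-based ones.
    """
    spec = spec or ModelSpec()
    if isinstance(data, pd.DataFrame):
        data = ChoiceData(data, spec.spec)
    xd, y, w, resp = _pairwise_arrays(data, spec, weights)
    names = spec.column_names()
    k = len(names)

    theta = np.zeros(k)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = xd @ theta
        # numerically safe logistic pieces
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
        grad = xd.T @ (w * (y - p))
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol:
            converged = True
            break
        wt = w * p * (1.0 - p)
        H = (xd * wt[:, None]).T @ xd
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise CollinearityError(
                "singular Hessian; collinear columns: "
                + ", ".join(_collinear_names(H, names))
            ) from None
        # step-halving keeps every iteration an ascent step
        scale = 1.0
        for _ in range(50):
            cand = theta + scale * step
            eta_c = xd @ cand
            ll_c = float(np.sum(w * (y * eta_c - np.logaddexp(0.0, eta_c))))
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        theta = theta + scale * step
        if np.max(np.abs(theta)) > 1e3:
            raise NonConvergenceError(
                "estimates diverging; choices may be completely separated"
            )
        ll_prev = ll

    eta = xd @ theta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
    grad = xd.T @ (w * (y - p))
    gnorm = float(np.max(np.abs(grad)))
    if not converged:
        raise NonConvergenceError(
            f"no convergence in {max_iter} iterations (|grad|={gnorm:.2e}); "
            "possible complete separation"
        )
    # perfectly predicted choices mean the MLE is at infinity; the gradient
    # vanishes there, so convergence alone does not catch separation
    p_chosen = np.where(y > 0.5, p, 1.0 - p)
    if p_chosen.min() > 1.0 - 1e-6:
        raise NonConvergenceError(
            "complete separation: every choice is perfectly predicted"
        )

    wt = w * p * (1.0 - p)
    A = (xd * wt[:, None]).T @ xd  # observed information
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        raise CollinearityError(
            "singular information; collinear columns: "
            + ", ".join(_collinear_names(A, names))
        ) from None

    params = pd.Series(theta, index=names, name="coef")
    fitted = FittedChoiceModel(
        params=params,
        vcov_model=pd.DataFrame(A_inv, index=names, columns=names),
        vcov_clustered=pd.DataFrame(np.nan, index=names, columns=names),
        loglik=ll,
        n_respondents=len(np.unique(resp)),
        n_sets=len(y),
        n_rows=2 * len(y),
        converged=converged,
        n_iter=it,
        gradient_norm=gnorm,
        model_spec=spec,
        _xd=xd,
        _y=y,
        _w=w,
        _cluster=resp,
    )
    fitted.vcov_clustered = clustered_vcov(fitted)
    return fitted


def _collinear_names(mat: np.ndarray, names: Sequence[str]) -> List[str]:
    _, s, vt = np.linalg.svd(mat)
    null = vt[s < s.max() * 1e-10] if s.max() > 0 else vt
    bad: set[str] = set()
    for v in null:
        bad.update(names[i] for i in np.nonzero(np.abs(v) > 1e-6)[0])
    return sorted(bad) or list(names)


def clustered_vcov(
    fit: FittedChoiceModel, cluster: Sequence | None = None
) -> pd.DataFrame:
    """Respondent-clustered sandwich covariance A^-1 B A^-1.

    A is the observed information at the optimum; B sums the outer products
    of respondent-level scores (each respondent's per-set scores summed),
    scaled by the finite-cluster correction G/(G-1).
    """
    if fit._xd is None:
        raise ValueError("fit does not retain per-set internals")
    cluster = np.asarray(cluster if cluster is not None else fit._cluster)
    if len(np.unique(cluster)) < 2:
        raise ValueError("clustered variance requires at least 2 clusters")
    xd, y, w = fit._xd, fit._y, fit._w
    theta = fit.params.to_numpy()
    eta = xd @ theta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    scores = xd * (w * (y - p))[:, None]  # per-set score rows
    g = pd.DataFrame(scores).groupby(pd.Series(cluster)).sum().to_numpy()
    G = g.shape[0]
    B = g.T @ g * (G / (G - 1.0))
    wt = w * p * (1.0 - p)
    A = (xd * wt[:, None]).T @ xd
    A_inv = np.linalg.inv(A)
    V = A_inv @ B @ A_inv
    names = fit.params.index
    return pd.DataFrame(V, index=names, columns=names)


# -- reporting ---------------------------------------------------------

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p_value: float) -> str:
    """Two-sided significance stars: *** 0.1%, ** 1%, * 5%."""
    for cut, stars in _STAR_LEVELS:
        if p_value < cut:
            return stars
    return ""


def coefficient_table(
    fit: FittedChoiceModel, se_source: str = "clustered"
) -> pd.DataFrame:
    """Wald z-tests per coefficient with conventional significance stars."""
    if not fit.converged:
        raise NonConvergenceError("fit did not converge")
    se = fit.se(se_source)
    z = fit.params / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "se": se,
            "z": z,
            "p": pvals,
            "stars": [significance_stars(p) for p in pvals],
        }
    )
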