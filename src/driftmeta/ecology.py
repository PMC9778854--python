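"""Ecological covariates and the diversity-association regression stage.

Covers pond geometry (pyramid volume), the NN2 isolation measure (mean
haversine distance to the two nearest occupied neighbor ponds), survey-based
subpopulation age, PCA of habitat covariates, and a type-II multiple
regression of genomic diversity on age, habitat PCs, isolation and
infection status.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import UndefinedStatisticError
from .geo import haversine

__all__ = [
    "pond_volume",
    "nn2_isolation",
    "nn2_table",
    "age_from_survey",
    "detection_miss_probability",
    "covariate_pca",
    "PcaResult",
    "diversity_regression",
    "RegressionResult",
    "AGE_CLASS_BOUNDS",
]

# age-class boundaries (years): newly founded <= 2 < intermediate <= 15 < old
AGE_CLASS_BOUNDS = (2.0, 15.0)


def pond_volume(surface_area, depth):
    """Pond volume (m^3) as a pyramid: surface_area * depth / 3."""
    surface_area = np.asarray(surface_area, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(surface_area < 0) or np.any(depth < 0):
        raise ValueError("surface area and depth must be >= 0")
    v = surface_area * depth / 3.0
    return float(v) if v.ndim == 0 else v


def nn2_isolation(coords, focal: int, n_neighbors: int = 2) -> float:
    """Mean distance (m) from the focal pond to its two nearest occupied
    neighbors. ``coords`` is (n, 2) lat/lon including the focal pond;
    the focal pond is excluded from its own neighbor set."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n - 1 < n_neighbors:
        raise ValueError(
            f"pond {focal}: needs >= {n_neighbors} other occupied ponds, "
            f"has {n - 1}"
        )
    d = haversine(coords[focal, 0], coords[focal, 1],
                  coords[:, 0], coords[:, 1])
    d = np.delete(d, focal)
    return float(np.sort(d)[:n_neighbors].mean())


def nn2_table(coords, ids=None) -> pd.Series:
    """NN2 for every pond in an occupied-pond coordinate table."""
    coords = np.asarray(coords, dtype=float)
    ids = list(ids) if ids is not None else list(range(coords.shape[0]))
    return pd.Series([nn2_isolation(coords, i) for i in range(coords.shape[0])],
                     index=ids, name="nn2")


def detection_miss_probability(detection_prob: float = 0.74,
                               n_visits: int = 3) -> float:
    """Probability an extant subpopulation is missed on ``n_visits``
    consecutive surveys: ``(1 - detection_prob) ** n_visits``."""
    if not 0.0 <= detection_prob <= 1.0:
        raise ValueError("detection_prob must lie in [0, 1]")
    return (1.0 - detection_prob) ** n_visits


def _to_date(x) -> _dt.date:
    if isinstance(x, _dt.datetime):
        return x.date()
    if isinstance(x, _dt.date):
        return x
    return pd.Timestamp(x).date()


def age_from_survey(
    records,
    reference_date,
    min_gap: int = 3,
    newly_founded_max_age: float = 2.0,
) -> tuple[float | None, bool | None]:
    """Subpopulation age from a biannual presence/absence survey series.

    ``records`` is an iterable of (visit_date, detected) pairs (or a
    DataFrame with ``date`` and ``detected`` columns), ordered in time. A
    founding event is the first detection at the start of the series or
    following at least ``min_gap`` consecutive non-detections; the age is
    the time in years from the latest founding event to
    ``reference_date``. Returns ``(age_years, newly_founded)``; with no
    detections the age is undefined and ``(None, None)`` is returned.
    """
    if isinstance(records, pd.DataFrame):
        pairs = [( _to_date(d), bool(f)) for d, f in
                 zip(records["date"], records["detected"])]
    else:
        pairs = [(_to_date(d), bool(f)) for d, f in records]
    if any(pairs[i][0] > pairs[i + 1][0] for i in range(len(pairs) - 1)):
        raise ValueError("survey visits must be ordered in time")
    ref = _to_date(reference_date)

    founding: _dt.date | None = None
    gap = min_gap  # series start counts as a (censored) gap
    for date, detected in pairs:
        if date > ref:
            break
        if detected:
            if gap >= min_gap:
                founding = date
            gap = 0
        else:
            gap += 1
    if founding is None:
        return None, None
    age = (ref - founding).days / 365.25
    return age, age <= newly_founded_max_age


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fractions: pd.Series
    dropped_columns: list[str]


def covariate_pca(table: pd.DataFrame, log10_columns=()) -> PcaResult:
    """PCA of habitat covariates on the correlation matrix.

    Area/length-type columns named in ``log10_columns`` are
    log10-transformed first; all columns are then standardized. Constant
    columns are dropped with a warning entry in ``dropped_columns``. Each
    loading vector is oriented so that its largest-magnitude entry is
    positive; variance fractions sum to 1.
    """
    import warnings

    df = table.select_dtypes(include=[np.number]).copy()
    for col in log10_columns:
        if np.any(df[col] <= 0):
            raise ValueError(f"column {col!r} must be positive for log10")
        df[col] = np.log10(df[col])
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need >= 2 numeric covariates and >= 3 ponds")
    dropped = [c for c in df.columns if df[c].std() == 0]
    if dropped:
        warnings.warn(f"dropping constant columns: {dropped}")
        df = df.drop(columns=dropped)
    z = (df - df.mean()) / df.std(ddof=1)
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    # orient: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    comp = [f"PC{k + 1}" for k in range(s.size)]
    scores = pd.DataFrame(u * s, index=table.index, columns=comp)
    loadings = pd.DataFrame(vt.T, index=df.columns, columns=comp)
    var_frac = pd.Series(s**2 / np.sum(s**2), index=comp,
                         name="variance_fraction")
    return PcaResult(scores, loadings, var_frac, dropped)


@dataclass
class RegressionResult:
    """Tidy coefficient/test table from the type-II regression."""

    table: pd.DataFrame  # term, df, estimate, t, F, p
    r_squared: float
    n_obs: int


_DEFAULT_PREDICTORS = ("log_age", "pc1", "pc2", "nn2", "infection")


def diversity_regression(
    pi: pd.Series,
    covariates: pd.DataFrame,
    predictors=_DEFAULT_PREDICTORS,
    include_island: bool = False,
) -> RegressionResult:
    """OLS of per-pond diversity on ecological covariates with type-II
    (marginal) tests: each term is tested after all others.

    ``covariates`` must contain an ``age`` column (transformed internally
    to ``log_age = log10(age + 1)``) plus any further predictor columns
    named in ``predictors``; categorical terms (``infection``,
    ``island``) get F tests, continuous terms also report t statistics
    with the sign of their coefficient.
    """
    data = covariates.copy()
    if "age" in data.columns:
        data["log_age"] = np.log10(data["age"].astype(float) + 1.0)
    pi = pd.Series(pi)
    if pi.index.equals(data.index):
        data["pi"] = pi
    elif len(pi) == len(data):
        data["pi"] = pi.to_numpy()
    else:
        data = data.join(pi.rename("pi"), how="inner")
    terms = [t for t in predictors if t in data.columns]
    if include_island:
        terms.append("C(island)")
    missing = [t for t in predictors if t not in data.columns
               and not t.startswith("C(")]
    if missing:
        raise KeyError(f"missing predictor columns: {missing}")
    data = data.dropna(subset=["pi"] + [t for t in terms if not t.startswith("C(")])
    if len(data) < len(terms) + 2:
        raise ValueError("too few complete cases for the model")

    formula = "pi ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(
            "rank-deficient design: aliased terms among "
            + ", ".join(model.exog_names)
        )
    fit = model.fit()
    anova = sm.stats.anova_lm(fit, typ=2)

    rows = []
    for term in terms:
        f = float(anova.loc[term, "F"])
        p = float(anova.loc[term, "PR(>F)"])
        df_term = int(anova.loc[term, "df"])
        est = t = None
        if term in fit.params.index:  # continuous, single-df
            est = float(fit.params[term])
            t = float(fit.tvalues[term])
        rows.append({"term": term, "df": df_term, "estimate": est,
                     "t": t, "F": f, "p": p})
    return RegressionResult(
        table=pd.DataFrame(rows),
        r_squared=float(fit.rsquared),
        n_obs=int(fit.nobs),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (rank-based Pearson, average ranks)."""
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
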