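"""Longitudinal cohort assembly and statistical plumbing.

All per-animal per-session metrics converge here into a tidy long-format
table (animal x group x session x metric, raw value and percent change versus
the animal's own baseline session). Within-animal baseline normalization,
``100 * (value / baseline - 1)``, removes stable between-animal differences
(field position, window quality) so group time-courses compare like with
like. Group summaries report mean and SEM over animals — the animal, not the
cell or the image, is the unit of replication.

The module also provides the descriptive multivariate tools used on such
tables: PCA of parameter matrices, pairwise Pearson correlation matrices with
two-sided p-values (no multiplicity correction), and simple linear
regression. These are deliberately thin wrappers over sklearn/scipy; the
pipeline's job is to produce the tidy table any stats package can consume.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

DEFAULT_SESSION_ORDER: tuple[str, ...] = (
    "Baseline", "Day0", "Day1", "Week1", "Week2", "Week3", "Week4",
)
BASELINE_SESSION = "Baseline"


def percent_change(values: Mapping[str, float] | pd.Series, baseline: str) -> pd.Series:
    """Baseline-normalize a per-session series: 100 * (value/baseline - 1).

    The baseline session maps to exactly 0. A missing, NaN or zero baseline
    makes the whole series NaN, with the reason recorded in
    ``result.attrs['missing_reason']`` (division by an undefined baseline must
    not silently propagate).
    """
    s = pd.Series(values, dtype=float)
    out = pd.Series(np.nan, index=s.index, dtype=float)
    if baseline not in s.index:
        out.attrs["missing_reason"] = f"baseline session {baseline!r} absent"
        return out
    b = s[baseline]
    if pd.isna(b) or b == 0:
        out.attrs["missing_reason"] = f"baseline value is {'NaN' if pd.isna(b) else 0}"
        return out
    out[:] = 100.0 * (s / b - 1.0)
    out[baseline] = 0.0
    return out


def build_cohort(
    metrics: pd.DataFrame,
    session_order: Sequence[str] = DEFAULT_SESSION_ORDER,
    baseline: str = BASELINE_SESSION,
) -> pd.DataFrame:
    """Assemble the tidy cohort table with baseline-normalized values.

    ``metrics`` must have columns (animal_id, group, session, metric, value);
    one row per observation. Returns the same rows ordered by the declared
    session order with an added ``percent_change`` column (NaN where the
    animal's baseline for that metric is absent or zero) and a
    ``missing_reason`` column. Duplicate (animal, session, metric) rows are an
    error; missing sessions are tolerated.
    """
    required = {"animal_id", "group", "session", "metric", "value"}
    missing_cols = required - set(metrics.columns)
    if missing_cols:
        raise ValueError(f"metrics table lacks columns {sorted(missing_cols)}")
    dup = metrics.duplicated(["animal_id", "session", "metric"])
    if dup.any():
        rows = metrics.loc[dup, ["animal_id", "session", "metric"]].iloc[0].tolist()
        raise ValueError(f"duplicate (animal, session, metric) rows, e.g. {rows}")
    unknown = set(metrics["session"]) - set(session_order)
    if unknown:
        raise ValueError(f"sessions {sorted(unknown)} not in the declared order")

    out = metrics.copy()
    out["session"] = pd.Categorical(out["session"], categories=list(session_order),
                                    ordered=True)
    out["percent_change"] = np.nan
    out["missing_reason"] = ""
    for (_, _), idx in out.groupby(["animal_id", "metric"], observed=True).groups.items():
        sub = out.loc[idx]
        series = pd.Series(sub["value"].to_numpy(), index=sub["session"].astype(str))
        pc = percent_change(series, baseline)
        out.loc[idx, "percent_change"] = pc.to_numpy()
        if "missing_reason" in pc.attrs:
            out.loc[idx, "missing_reason"] = pc.attrs["missing_reason"]
    return out.sort_values(["group", "animal_id", "metric", "session"]).reset_index(drop=True)


def group_summary(table: pd.DataFrame, value_col: str = "percent_change") -> pd.DataFrame:
    """Mean and SEM over animals per (group, session, metric).

    SEM = sd/sqrt(n) with ddof=1; NaN (flagged by ``n``) for a single animal.
    """
    def _agg(g: pd.Series) -> pd.Series:
        v = g.dropna()
        n = len(v)
        return pd.Series({
            "mean": v.mean() if n else np.nan,
            "sem": v.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
            "n": n,
        })

    out = (table.groupby(["group", "session", "metric"], observed=True)[value_col]
           .apply(_agg).unstack())
    out["n"] = out["n"].astype(int)
    return out.reset_index()


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str]


def pca_parameters(table: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of a wide per-observation parameter matrix.

    Columns that are entirely missing or have zero variance are dropped with
    a warning; rows with any remaining missing value are dropped (complete-
    case). Columns are centered and, by default, scaled to unit variance —
    the parameters have incommensurate units, so correlation-matrix PCA is
    the sensible default. Explained-variance fractions sum to 1.
    """
    num = table.select_dtypes(include=[np.number])
    dropped = [c for c in num.columns if num[c].isna().all() or num[c].std(ddof=0) == 0
               or np.isnan(num[c].std(ddof=0))]
    if dropped:
        warnings.warn(f"dropping constant/all-missing columns: {dropped}", stacklevel=2)
        num = num.drop(columns=dropped)
    num = num.dropna(axis=0)
    if num.shape[0] < 2 or num.shape[1] < 1:
        raise ValueError("PCA needs at least two complete rows and one column")
    x = num.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        x = x / x.std(axis=0, ddof=0)
    pca = PCA()
    scores = pca.fit_transform(x)
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=num.index, columns=pcs),
        loadings=pd.DataFrame(pca.components_.T, index=num.columns, columns=pcs),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_columns=dropped,
    )


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame  # two-sided p < 0.05, no multiplicity correction

    def __post_init__(self) -> None:
        if not self.r.index.equals(self.r.columns):
            raise ValueError("correlation matrix must be square")


def correlation_matrix(table: pd.DataFrame, min_n: int = 3, alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations of a wide parameter matrix.

    Pairs with fewer than ``min_n`` complete observations, or involving a
    constant column, get NaN (flagged, not dropped). The diagonal is 1.
    """
    num = table.select_dtypes(include=[np.number])
    cols = list(num.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        for j in range(i + 1, k):
            pair = num[[cols[i], cols[j]]].dropna()
            if len(pair) < min_n:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return CorrelationMatrix(r=rdf, p=pdf, significant=pdf < alpha)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float


def simple_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y ~ x with the standard t-test on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError("simple regression needs at least three points")
    if np.std(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
    )
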