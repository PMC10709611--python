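"""Annual-series statistics: Mann–Kendall, Pettitt, Pearson, PCA.

The monitoring variables (fire foci, precipitation, GPP, CO₂ flux,
per-class burned area) arrive as short annual series, typically n ≈ 22.
This module provides the nonparametric trend and change-point tests
standard for such series, plus the pairwise Pearson correlation matrix
and a correlation-based principal component analysis used to summarise
the joint variability of the variables.

Mann–Kendall: S = Σ_{i<j} sign(x_j − x_i); Var(S) carries the usual tie
correction; the standardized Z uses a ±1 continuity correction and a
two-sided normal p-value (adequate for n ≥ 10).

Pettitt: U_t = Σ_{i≤t} Σ_{j>t} sign(x_j − x_i); K = max|U_t|; the
classical approximation p ≈ 2·exp(−6K²/(n³ + n²)), reported capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA


@dataclass
class AnnualSeries:
    """An ordered year → value sequence for one monitoring variable."""

    years: np.ndarray
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.years.shape != self.values.shape or self.years.ndim != 1:
            raise ValueError("years and values must be 1-D and equal length")
        if len(self.years) > 1 and not np.all(np.diff(self.years) > 0):
            raise ValueError("years must be strictly increasing")

    def __len__(self) -> int:
        return len(self.years)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.years, name=self.name)


@dataclass(frozen=True)
class TrendResult:
    s: int                 # signed concordant/discordant pair count
    var_s: float           # tie-corrected variance of S
    z: float               # continuity-corrected standard normal deviate
    tau: float             # Kendall tau (tie-adjusted)
    p_value: float         # two-sided
    direction: str         # increasing / decreasing / none
    n: int


@dataclass(frozen=True)
class ChangePointResult:
    u: np.ndarray          # U_t for t = 1..n-1
    k: int                 # max |U_t|
    change_index: int      # t* in [1, n-1]; series mean shifts after it
    change_year: int | None
    p_value: float         # classical approximation, capped at 1
    significant: bool


def _check_series(series: AnnualSeries, min_n: int = 4) -> np.ndarray:
    x = np.asarray(series.values, dtype=np.float64)
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def _pairwise_sign_sum(x: np.ndarray) -> np.ndarray:
    """sign(x_j − x_i) summed over j for each i<j, via the full sign matrix."""
    return np.sign(x[None, :] - x[:, None])


def mann_kendall(series: AnnualSeries, alpha: float = 0.05) -> TrendResult:
    """Mann–Kendall monotonic-trend test with tie correction.

    Direction is called at significance level ``alpha`` (two-sided);
    an all-equal series yields S = 0, Var(S) = 0, p = 1, direction none.
    """
    x = _check_series(series)
    n = len(x)
    sgn = _pairwise_sign_sum(x)
    s = int(np.triu(sgn, k=1).sum())

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0

    n_pairs = n * (n - 1) / 2
    tau = s / n_pairs if n_pairs else 0.0

    if var_s <= 0 or s == 0:
        z, p = 0.0, 1.0
    else:
        z = (s - np.sign(s)) / np.sqrt(var_s)  # ±1 continuity correction
        p = float(2 * stats.norm.sf(abs(z)))

    if p <= alpha and s > 0:
        direction = "increasing"
    elif p <= alpha and s < 0:
        direction = "decreasing"
    else:
        direction = "none"
    return TrendResult(s=s, var_s=float(var_s), z=float(z), tau=float(tau),
                       p_value=p, direction=direction, n=n)


def pettitt(series: AnnualSeries, alpha: float = 0.05) -> ChangePointResult:
    """Pettitt single change-point test for a shift in the mean.

    U_t is computed for every split t = 1..n−1; the change point t* is
    the (earliest, on ties) argmax of |U_t|, i.e. the last index of the
    first regime. A constant series gives K = 0, p = 1, no change point.
    """
    x = _check_series(series)
    n = len(x)
    sgn = _pairwise_sign_sum(x)
    # U_t = sum_{i<=t} sum_{j>t} sign(x_j - x_i); cumulative over rows,
    # complementary-cumulative over columns of the upper triangle.
    upper = np.triu(sgn, k=1)
    # row i contributes sign(x_j - x_i) for all j > t when i <= t
    row_tail = np.cumsum(upper[:, ::-1], axis=1)[:, ::-1]  # sums over j >= col
    u = np.array([row_tail[: t + 1, t + 1].sum() if t + 1 < n else 0
                  for t in range(n - 1)], dtype=np.int64)

    k = int(np.max(np.abs(u))) if len(u) else 0
    if k == 0:
        return ChangePointResult(u=u, k=0, change_index=0, change_year=None,
                                 p_value=1.0, significant=False)
    t_star = int(np.argmax(np.abs(u)) + 1)  # earliest argmax, 1-based
    p = min(1.0, float(2.0 * np.exp(-6.0 * k * k / (n ** 3 + n ** 2))))
    # t_star is the last index of the first regime; report the first year
    # of the shifted regime as the change year
    year = int(series.years[t_star])
    return ChangePointResult(u=u, k=k, change_index=t_star, change_year=year,
                             p_value=p, significant=p <= alpha)


def pettitt_u_stat(x: np.ndarray) -> np.ndarray:
    """U_t sequence for a plain array (convenience for simulations)."""
    years = np.arange(len(x))
    return pettitt(AnnualSeries(years, x)).u


def align_series(series_set: list[AnnualSeries]) -> pd.DataFrame:
    """Inner-join a set of annual series on year into a year × variable frame."""
    if len(series_set) < 2:
        raise ValueError("need at least 2 series")
    frames = [s.to_pandas().rename(s.name or f"var{i}")
              for i, s in enumerate(series_set)]
    df = pd.concat(frames, axis=1, join="inner")
    df.index.name = "year"
    return df


def pearson_matrix(series_set: list[AnnualSeries]) -> pd.DataFrame:
    """Pairwise Pearson r over the inner-joined years.

    Zero-variance variables give undefined r, reported as NaN off the
    diagonal (the diagonal stays 1 by convention).
    """
    df = align_series(series_set)
    corr = df.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class PcaResult:
    loadings: pd.DataFrame         # variables × components, unit columns
    scores: pd.DataFrame           # observations × components
    explained_variance: np.ndarray  # proportions, sum to 1
    cumulative_variance: np.ndarray


def pca(data: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of an observations × variables table.

    With ``standardize`` (default) variables are centred and scaled to
    unit variance first, i.e. correlation-based PCA — appropriate when
    the variables mix units (mm, counts, kg C, µmol). Components are
    ordered by decreasing eigenvalue with a deterministic sign
    convention: each component's largest-magnitude loading is positive.
    """
    if data.shape[1] < 2 or data.shape[0] < 3:
        raise ValueError("PCA needs >= 2 variables and >= 3 observations")
    if data.isna().any().any():
        raise ValueError("PCA input contains missing values; join years first")
    X = data.to_numpy(dtype=np.float64)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            names = ", ".join(data.columns[i] for i in dead)
            raise ValueError(f"constant variable(s) under standardization: {names}")
        X = X / sd

    model = _SKPCA(n_components=min(X.shape), svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # variables × components, unit columns

    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    ev = model.explained_variance_ratio_
    comps = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=data.columns, columns=comps),
        scores=pd.DataFrame(scores, index=data.index, columns=comps),
        explained_variance=ev,
        cumulative_variance=np.cumsum(ev),
    )


def trend_table(series_set: list[AnnualSeries],
                alpha: float = 0.05) -> pd.DataFrame:
    """Mann–Kendall + Pettitt summary, one row per variable per test."""
    rows = []
    for s in series_set:
        mk = mann_kendall(s, alpha=alpha)
        rows.append((s.name, "mann_kendall", mk.s, mk.p_value, "",
                     mk.direction))
        pt = pettitt(s, alpha=alpha)
        rows.append((s.name, "pettitt", pt.k, pt.p_value,
                     pt.change_year if pt.significant else "", ""))
    return pd.DataFrame(rows, columns=["variable", "test", "statistic",
                                       "p_value", "change_year", "direction"])
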