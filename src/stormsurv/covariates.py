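"""Per-winter covariate assembly: storminess PCA, SST lags, population, oil.

The storminess index is the first principal component of the per-winter storm
characteristic matrix (storm counts, intensity, duration, gaps, threshold
exceedance days).  Because the variables mix units, the PCA is computed on the
correlation matrix (variables standardised first) and PC1 is oriented so that
it correlates positively with the total storm count: high PC1 = stormy winter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PcaResult",
    "storminess_pc1",
    "fill_population",
    "add_lags_and_standardize",
    "standardize",
    "correlation_screen",
    "oil_factor",
]


@dataclass
class PcaResult:
    loadings: pd.DataFrame       # variables x components, orthonormal columns
    explained: np.ndarray        # variance fractions, non-increasing
    scores: pd.DataFrame         # winters x components; "PC1" is first

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def storminess_pc1(
    storm_variables: pd.DataFrame, orient_by: str = "n_storms"
) -> PcaResult:
    """Correlation-matrix PCA of per-winter storm variables.

    ``orient_by`` names the column whose correlation with PC1 is forced
    positive (defaults to the storm count); if absent, the loading sum is
    forced positive instead.  Constant columns are dropped with a warning;
    missing cells are mean-imputed with a warning.
    """
    df = storm_variables.copy()
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 winters and 2 variables")
    if df.isna().any().any():
        warnings.warn("missing storm-variable cells mean-imputed before PCA")
        df = df.fillna(df.mean())
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant storm variables: {constant}")
        df = df.drop(columns=constant)
        if df.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant variables")
    Z = (df - df.mean()) / df.std(ddof=1)
    n = len(df)
    # SVD of the standardised matrix == eigendecomposition of the correlation
    # matrix, and stays valid when winters < variables
    _, svals, Vt = np.linalg.svd(Z.to_numpy(float), full_matrices=False)
    var = svals**2 / (n - 1)
    explained = var / df.shape[1]
    loadings = Vt.T
    scores = Z.to_numpy(float) @ loadings
    # orientation
    if orient_by in df.columns:
        ref = Z[orient_by].to_numpy(float)
    else:
        ref = None
    for c in range(loadings.shape[1]):
        s = scores[:, c]
        sign = np.sign(np.dot(s, ref)) if ref is not None else np.sign(loadings[:, c].sum())
        if sign < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=df.columns, columns=comp_names),
        explained=explained,
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
    )


def fill_population(counts: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Fill missing annual counts; returns (filled, filled_flag).

    Interior gaps take the mean of the nearest preceding and following
    observed counts; trailing gaps carry the last observed value forward and
    leading gaps carry the first observed value backward (both flagged).
    """
    s = counts.astype(float)
    if s.isna().all():
        raise ValueError("all counts missing")
    filled = s.copy()
    flag = s.isna()
    obs_idx = np.flatnonzero(~s.isna().to_numpy())
    vals = s.to_numpy()
    out = vals.copy()
    for i in np.flatnonzero(s.isna().to_numpy()):
        prev = obs_idx[obs_idx < i]
        nxt = obs_idx[obs_idx > i]
        if prev.size and nxt.size:
            out[i] = 0.5 * (vals[prev[-1]] + vals[nxt[0]])
        elif prev.size:
            out[i] = vals[prev[-1]]
        else:
            out[i] = vals[nxt[0]]
    filled[:] = out
    return filled, flag


def standardize(x: pd.Series) -> pd.Series:
    """Center and scale to unit SD over non-missing entries."""
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot standardize constant column {x.name!r}")
    return (x - x.mean()) / sd


def add_lags_and_standardize(
    table: pd.DataFrame,
    lag_columns: tuple[str, ...] = ("sSST", "wSST"),
    standardize_columns: tuple[str, ...] | None = None,
    never_standardize: tuple[str, ...] = ("oil",),
) -> pd.DataFrame:
    """Add one-winter lags and standardise covariates (oil left untouched).

    Rows must be chronological; lag columns shift by one winter so the first
    row's lag is missing (models using lags drop that interval with a note).
    Standardised values replace the raw ones in columns selected; raw values
    are kept with a ``_raw`` suffix.
    """
    df = table.copy()
    for col in lag_columns:
        if col not in df.columns:
            raise ValueError(f"lag source column {col!r} missing")
        df[f"lag_{col}"] = df[col].shift(1)
    if standardize_columns is None:
        standardize_columns = tuple(
            c for c in df.columns
            if c not in never_standardize and pd.api.types.is_numeric_dtype(df[c])
        )
    for col in standardize_columns:
        if col in never_standardize:
            continue
        df[f"{col}_raw"] = df[col]
        df[col] = standardize(df[col])
    return df


def correlation_screen(table: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Pairwise |Pearson r| for numeric columns, flagging pairs above threshold."""
    num = table.select_dtypes("number")
    cols = list(num.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = num[[a, b]].dropna()
            r = pair[a].corr(pair[b]) if len(pair) > 2 else np.nan
            rows.append({"a": a, "b": b, "r": r, "flagged": bool(abs(r) > threshold)})
    return pd.DataFrame(rows)


def oil_factor(
    winter_start_years: list[int] | np.ndarray,
    spill_events: list[tuple[int, int]],
) -> np.ndarray:
    """0/1 oil-spill flag per winter.

    A spill dated (year, month) within November-March is assigned to the
    winter spanning that November-March: months 11-12 to winter ``year``,
    months 1-3 to winter ``year - 1``.  Events outside the study span, or in
    April-October, are ignored with a warning.
    """
    years = np.asarray(winter_start_years, dtype=int)
    flags = np.zeros(len(years), dtype=int)
    for year, month in spill_events:
        if month in (11, 12):
            wy = year
        elif month in (1, 2, 3):
            wy = year - 1
        else:
            warnings.warn(f"spill ({year}-{month:02d}) outside Nov-Mar: ignored")
            continue
        hit = np.flatnonzero(years == wy)
        if hit.size == 0:
            warnings.warn(f"spill ({year}-{month:02d}) outside study span: ignored")
            continue
        flags[hit] = 1
    return flags
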