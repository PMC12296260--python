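"""Outcome conditioning shared by both inference frameworks.

Tukey winsorization of outliers, the two-step covariate adjustment used to
increase precision of the discontinuity estimate, and per-modality
Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WinsorReport",
    "AdjustedOutcome",
    "winsorize_tukey",
    "adjust_for_covariates",
    "bh_fdr",
    "expand_covariates",
]


@dataclass
class WinsorReport:
    """Fences and cap counts from one Tukey winsorization pass."""

    lower_fence: float
    upper_fence: float
    n_capped_low: int
    n_capped_high: int


@dataclass
class AdjustedOutcome:
    """Covariate-adjusted outcome restricted to rows inside the bandwidth.

    ``values`` is indexed by the source rows that entered the adjustment
    regression; ``coefficients`` holds the fitted nuisance coefficients
    (running-variable and cutoff terms are estimated but never subtracted).
    """

    values: pd.Series
    coefficients: dict[str, float]
    bandwidth_used: float


def winsorize_tukey(values) -> tuple[np.ndarray, WinsorReport]:
    """Cap values outside the Tukey fences [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics (numpy's
    default rule); values at or inside the fences are untouched, values
    beyond a fence are set exactly to it. Non-finite entries pass through
    unchanged. Requires at least four finite values.
    """
    arr = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(arr)
    n_finite = int(finite.sum())
    if n_finite == 0:
        raise ValueError("winsorize_tukey: input contains no finite values")
    if n_finite < 4:
        raise ValueError(
            f"winsorize_tukey: need at least 4 finite values to define quartiles, got {n_finite}"
        )
    q1, q3 = np.quantile(arr[finite], [0.25, 0.75])
    iqr = q3 - q1
    lower = q1 - 1.5 * iqr
    upper = q3 + 1.5 * iqr
    low_mask = finite & (arr < lower)
    high_mask = finite & (arr > upper)
    arr[low_mask] = lower
    arr[high_mask] = upper
    report = WinsorReport(
        lower_fence=float(lower),
        upper_fence=float(upper),
        n_capped_low=int(low_mask.sum()),
        n_capped_high=int(high_mask.sum()),
    )
    return arr, report


def expand_covariates(table: pd.DataFrame, covariates) -> pd.DataFrame:
    """Expand a covariate list into a numeric design block.

    Categorical/object columns become indicator columns (first level as
    reference); numeric columns pass through unchanged.
    """
    blocks = []
    for name in covariates:
        if name not in table.columns:
            raise KeyError(f"covariate {name!r} not found in table")
        col = table[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            # propagate missingness: a missing category means all dummies missing
            dummies[col.isna()] = np.nan
            blocks.append(dummies)
        else:
            blocks.append(col.astype(float).to_frame(name))
    if not blocks:
        return pd.DataFrame(index=table.index)
    return pd.concat(blocks, axis=1)


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in piv[rank:]]


def adjust_for_covariates(
    table: pd.DataFrame,
    outcome: str,
    covariates,
    bandwidth: float,
    running: str = "mdob",
    missing: str = "complete",
) -> AdjustedOutcome:
    """Two-step covariate adjustment of an outcome inside a bandwidth.

    Fits, on rows with ``|running| <= bandwidth``, the unweighted OLS

        uY ~ 1 + X + 1[X >= 0] + X * 1[X >= 0] + C'

    and returns ``Y = uY - C' @ beta_star``: only the nuisance-covariate
    part is subtracted, so the discontinuity left in ``Y`` is untouched in
    expectation when the covariates are balanced at the cutoff. The same
    operation applies verbatim to a binary first-stage column.

    ``missing`` is ``"complete"`` (drop rows with missing covariates,
    the default) or ``"impute"`` (single mean/mode imputation).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x_all = table[running].astype(float)
    sub = table.loc[np.abs(x_all) <= bandwidth]
    if len(sub) == 0:
        raise ValueError(f"no rows within bandwidth {bandwidth} of the cutoff")

    cov_block = expand_covariates(sub, covariates)
    y = sub[outcome].astype(float)

    keep = y.notna()
    if missing == "complete":
        keep &= cov_block.notna().all(axis=1) if cov_block.shape[1] else True
        cov_used = cov_block.loc[keep]
    elif missing == "impute":
        cov_used = cov_block.copy()
        for col in cov_used.columns:
            series = cov_used[col]
            if series.isna().any():
                # mode for indicator-like columns, mean otherwise
                if set(series.dropna().unique()) <= {0.0, 1.0}:
                    fill = float(series.mode().iloc[0])
                else:
                    fill = float(series.mean())
                cov_used[col] = series.fillna(fill)
        cov_used = cov_used.loc[keep]
    else:
        raise ValueError(f"unknown missing-data policy {missing!r}")

    sub = sub.loc[keep]
    y = y.loc[keep]
    if len(sub) == 0:
        raise ValueError("no complete-case rows within the bandwidth")

    if cov_used.shape[1] == 0:
        return AdjustedOutcome(values=y.copy(), coefficients={}, bandwidth_used=float(bandwidth))

    x = sub[running].to_numpy(dtype=float)
    ind = (x >= 0).astype(float)
    base = np.column_stack([np.ones_like(x), x, ind, x * ind])
    base_names = ["const", "X", "X>=0", "X:X>=0"]
    cmat = cov_used.to_numpy(dtype=float)
    design = np.column_stack([base, cmat])
    names = base_names + list(cov_used.columns)

    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(design, y.to_numpy(dtype=float), rcond=None)
    beta_star = beta[len(base_names):]
    adjusted = y.to_numpy(dtype=float) - cmat @ beta_star
    coefficients = dict(zip(names, beta.tolist()))
    return AdjustedOutcome(
        values=pd.Series(adjusted, index=sub.index, name=outcome),
        coefficients=coefficients,
        bandwidth_used=float(bandwidth),
    )


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and rejection flags.

    Correction is intended to be applied within one outcome modality at a
    time (m = number of regions in the panel); ``reject`` is
    ``qvalue <= q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    _, qvalues, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvalues, qvalues <= q
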