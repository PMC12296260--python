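"""Design-validity diagnostics for the cutoff design.

A density (bunching) test of the running variable at the cutoff, placebo
outcome tests that run the main estimators on covariates that should be
causally unaffected, and placebo cutoff analyses that artificially move the
cutoff. The placebo machinery calls the main estimators verbatim, so a
placebo null exercises exactly the pipeline used for the real outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .continuity import FuzzyRD
from .localrand import LocalRandomization, PriorSpec, screen_covariates, select_window
from .preprocess import expand_covariates

__all__ = [
    "DensityTestResult",
    "binomial_density_test",
    "density_test_suite",
    "placebo_outcomes",
    "placebo_cutoffs",
]


@dataclass
class DensityTestResult:
    """Exact binomial test of bunching at the cutoff within one window."""

    statistic: float
    p: float
    n_left: int
    n_right: int
    omega: int
    method: str = "exact binomial"


def binomial_density_test(table: pd.DataFrame, omega: int, running: str = "mdob") -> DensityTestResult:
    """Exact two-sided binomial test of H0: births fall equally often in the
    omega months before and after the cutoff.

    With a date-of-birth running variable, sorting across the cutoff would
    show up as an excess of births on one side of equal-width windows. The
    statistic reported is the standardized count difference.
    """
    if omega < 1:
        raise ValueError("omega must be a positive number of months")
    x = table[running]
    n_left = int(((x >= -omega) & (x < 0)).sum())
    n_right = int(((x >= 0) & (x <= omega - 1)).sum())
    n = n_left + n_right
    if n_left == 0 or n_right == 0:
        raise ValueError(f"empty window side at omega={omega} (left={n_left}, right={n_right})")
    p = stats.binomtest(n_right, n, 0.5, alternative="two-sided").pvalue
    z = (n_right - n / 2) / np.sqrt(n * 0.25)
    return DensityTestResult(statistic=float(z), p=float(p), n_left=n_left, n_right=n_right, omega=omega)


def density_test_suite(table: pd.DataFrame, omegas=(1, 3, 6, 12), running: str = "mdob") -> pd.DataFrame:
    """Density test repeated over a ladder of window widths."""
    rows = []
    for omega in omegas:
        res = binomial_density_test(table, omega, running=running)
        rows.append(
            {"omega": omega, "n_left": res.n_left, "n_right": res.n_right,
             "statistic": res.statistic, "p": res.p, "method": res.method}
        )
    return pd.DataFrame(rows)


def _placebo_variables(table: pd.DataFrame, covariates) -> list[str]:
    """Covariate list with categoricals expanded to per-level indicators."""
    names = []
    for name in covariates:
        col = table[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            block = expand_covariates(table, [name])
            for c in block.columns:
                if c not in table.columns:
                    table[c] = block[c]
                names.append(c)
        else:
            names.append(name)
    return names


def placebo_outcomes(
    table: pd.DataFrame,
    covariates,
    frameworks=("continuity", "local_randomization"),
    omega: int = 5,
    prior: PriorSpec = PriorSpec(1.0),
    bayes_method: str = "analytic",
    bayes_iterations: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the main estimators with each covariate as the outcome.

    Remaining covariates are *not* used as adjusters. Covariates
    deterministically tied to assignment (a deterministic function of the
    running variable, or perfectly separated from assignment in-window) are
    excluded with the reason reported. Results are reported per variable
    without multiplicity correction.
    """
    table = table.copy()
    variables = _placebo_variables(table, covariates)
    rows = []
    for framework in frameworks:
        if framework == "local_randomization":
            window = select_window(table, omega)
        for var in variables:
            _, dropped = screen_covariates(
                select_window(table, omega) if framework == "local_randomization" else table,
                [var],
            )
            if dropped:
                rows.append(
                    {"variable": var, "framework": framework, "estimate": np.nan,
                     "se": np.nan, "p": np.nan, "bf10": np.nan,
                     "excluded": True, "reason": dropped[0][1]}
                )
                continue
            try:
                if framework == "continuity":
                    res = FuzzyRD(table, var).fit("mse")
                    rows.append(
                        {"variable": var, "framework": framework,
                         "estimate": res.estimate, "se": res.se, "p": res.p,
                         "bf10": np.nan, "excluded": False, "reason": ""}
                    )
                elif framework == "local_randomization":
                    model = LocalRandomization(window, var, focal="rosla", omega=omega)
                    post = model.fit(prior=prior, method=bayes_method,
                                     iterations=bayes_iterations, seed=seed)
                    bf = post.bayes_factor()
                    rows.append(
                        {"variable": var, "framework": framework,
                         "estimate": post.focal_mean, "se": post.focal_sd,
                         "p": np.nan, "bf10": bf.bf10,
                         "excluded": False, "reason": ""}
                    )
                else:
                    raise ValueError(f"unknown framework {framework!r}")
            except ValueError as err:
                rows.append(
                    {"variable": var, "framework": framework, "estimate": np.nan,
                     "se": np.nan, "p": np.nan, "bf10": np.nan,
                     "excluded": True, "reason": str(err)}
                )
    return pd.DataFrame(rows)


def placebo_cutoffs(
    table: pd.DataFrame,
    outcome: str,
    offsets=(-48, -24, 24, 48),
    running: str = "mdob",
    bandwidth="mse",
    min_months_per_side: int = 20,
) -> pd.DataFrame:
    """Re-center the running variable at artificial cutoffs and re-estimate.

    Each offset shifts the cutoff by that many months and re-runs the sharp
    (intent-to-treat style) discontinuity estimator, the first stage being
    replaced by the shifted assignment dummy. Offsets too close to the data
    edge produce a per-offset error entry instead of failing the run.
    """
    rows = []
    x = table[running].astype(float)
    for offset in offsets:
        shifted = x - offset
        months_left = np.unique(shifted[shifted < 0]).size
        months_right = np.unique(shifted[shifted >= 0]).size
        if min(months_left, months_right) < min_months_per_side:
            rows.append(
                {"offset": offset, "estimate": np.nan, "se": np.nan, "p": np.nan,
                 "h": np.nan, "error": f"only {min(months_left, months_right)} months on one side"}
            )
            continue
        shifted_table = table.copy()
        shifted_table[running] = shifted
        res = FuzzyRD(shifted_table, outcome, running=running).fit(bandwidth)
        rows.append(
            {"offset": offset, "estimate": res.estimate, "se": res.se, "p": res.p,
             "h": res.h, "error": ""}
        )
    return pd.DataFrame(rows)
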