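"""Continuity-based fuzzy local-linear regression discontinuity.

Local-linear fits with triangular kernel weights on each side of the cutoff,
the Imbens-Kalyanaraman regularized MSE-optimal bandwidth, and the fuzzy
(local average treatment effect) estimand with delta-method inference. The
first post-cutoff month is month 0: the left fit uses X < 0, the right fit
X >= 0.

Inference is conventional robust local-linear: HC1 intercept variances per
side plus a delta-method treatment of the reduced-form / first-stage ratio,
with their covariance estimated from the shared observation influence terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import adjust_for_covariates

__all__ = [
    "BandwidthSelection",
    "JumpEstimate",
    "FuzzyRD",
    "FuzzyRDResults",
    "triangular_weights",
    "select_bandwidth_mse",
    "local_linear_jump",
    "fuzzy_rd",
]

#: Kernel-specific constant of the first-order MSE-optimal bandwidth.
_CK_TRIANGULAR = 3.4375

#: Minimum bandwidth (months) supporting two-sided local-linear fits.
MIN_BANDWIDTH = 3.0


def triangular_weights(x, h: float) -> np.ndarray:
    """Triangular kernel weights ``max(0, 1 - |x|/h)``; zero outside [-h, h]."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    x = np.asarray(x, dtype=float)
    return np.maximum(0.0, 1.0 - np.abs(x) / h)


@dataclass
class BandwidthSelection:
    """A selected bandwidth and the pilot quantities behind it."""

    h: float
    method: str
    pilot_quantities: dict = field(default_factory=dict)


@dataclass
class JumpEstimate:
    """A sharp local-linear jump at the cutoff with robust inference."""

    jump: float
    se: float
    n_eff_left: int
    n_eff_right: int
    intercept_left: float
    intercept_right: float
    slope_left: float
    slope_right: float
    h: float
    kernel: str = "triangular"
    # per-row signed influence of each observation on the jump (right minus
    # left intercept weights) and residuals, for cross-equation covariance
    influence: np.ndarray | None = None
    residuals: np.ndarray | None = None
    hc1_factor: np.ndarray | None = None


def _side_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted linear fit on one side; returns coef, influence row for the
    intercept, residuals and the HC1 small-sample factor."""
    if np.unique(x).size < 3:
        raise ValueError(
            f"need at least 3 distinct running-variable values on a side, got {np.unique(x).size}"
        )
    design = np.column_stack([np.ones_like(x), x])
    wd = design * w[:, None]
    xtwx = design.T @ wd
    xtw = wd.T  # (2, n)
    coef = np.linalg.solve(xtwx, xtw @ y)
    # influence of each row on the intercept: e0' (X'WX)^-1 X'W
    a = np.linalg.solve(xtwx, xtw)[0]
    resid = y - design @ coef
    n = x.size
    factor = n / (n - 2)
    return coef, a, resid, factor


def local_linear_jump(
    x,
    y,
    h: float,
    kernel: str = "triangular",
) -> JumpEstimate:
    """Sharp discontinuity in ``y`` at 0 from side-specific weighted fits.

    Fits ``y ~ 1 + x`` by weighted least squares separately on ``x < 0`` and
    ``x >= 0`` with triangular weights of bandwidth ``h``; the jump is the
    difference of the two fitted intercepts. The standard error combines the
    HC1 heteroskedasticity-robust variances of the intercepts.
    """
    if kernel != "triangular":
        raise ValueError(f"unsupported kernel {kernel!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = triangular_weights(x, h)
    nz = w > 0
    left = nz & (x < 0)
    right = nz & (x >= 0)
    if not left.any() or not right.any():
        raise ValueError(f"no observations with positive weight on one side at h={h}")

    coef_l, a_l, resid_l, f_l = _side_fit(x[left], y[left], w[left])
    coef_r, a_r, resid_r, f_r = _side_fit(x[right], y[right], w[right])

    var = f_l * np.sum(a_l**2 * resid_l**2) + f_r * np.sum(a_r**2 * resid_r**2)

    influence = np.zeros(x.size)
    residuals = np.zeros(x.size)
    hc1 = np.zeros(x.size)
    influence[left], influence[right] = -a_l, a_r
    residuals[left], residuals[right] = resid_l, resid_r
    hc1[left], hc1[right] = f_l, f_r

    return JumpEstimate(
        jump=float(coef_r[0] - coef_l[0]),
        se=float(np.sqrt(var)),
        n_eff_left=int(left.sum()),
        n_eff_right=int(right.sum()),
        intercept_left=float(coef_l[0]),
        intercept_right=float(coef_r[0]),
        slope_left=float(coef_l[1]),
        slope_right=float(coef_r[1]),
        h=float(h),
        kernel=kernel,
        influence=influence,
        residuals=residuals,
        hc1_factor=hc1,
    )


def _jump_covariance(est_y: JumpEstimate, est_d: JumpEstimate) -> float:
    """Covariance of two jump estimates sharing rows and weights."""
    return float(
        np.sum(est_y.hc1_factor * est_y.influence * est_d.influence
               * est_y.residuals * est_d.residuals)
    )


def select_bandwidth_mse(x, y, kernel: str = "triangular") -> BandwidthSelection:
    """Imbens-Kalyanaraman regularized first-order MSE-optimal bandwidth.

    The selector estimates the density and conditional variance at the
    cutoff from a Silverman-style pilot window, side-specific second
    derivatives from local quadratic pilot fits (curvature pilots from a
    global cubic), adds the IK regularization terms, and applies the
    triangular-kernel constant 3.4375. The result is clamped to the data
    half-range and floored at 3 months (minimum support for two-sided
    linear fits). Deterministic given the data, and invariant to affine
    transformations of the outcome.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    left, right = x < 0, x >= 0
    for side, label in ((left, "left"), (right, "right")):
        if np.unique(x[side]).size < 20:
            raise ValueError(
                f"too few distinct running-variable values on the {label} side "
                "for MSE bandwidth selection; supply a fixed bandwidth instead"
            )
    if np.var(y) == 0:
        raise ValueError("outcome has zero variance; bandwidth selection undefined")

    # Step 1: pilot window, variance and density at the cutoff
    sx = x.std(ddof=1)
    h1 = 1.84 * sx * n ** (-1 / 5)
    in1_l = left & (x >= -h1)
    in1_r = right & (x <= h1)
    n_l, n_r = int(in1_l.sum()), int(in1_r.sum())
    ybar_l, ybar_r = y[in1_l].mean(), y[in1_r].mean()
    sigma2 = (np.sum((y[in1_l] - ybar_l) ** 2) + np.sum((y[in1_r] - ybar_r) ** 2)) / (n_l + n_r)
    f_hat = (n_l + n_r) / (2.0 * n * h1)

    # Step 2: third derivative from a global cubic with a jump, then
    # side-specific curvature from local quadratic pilots
    t = (x >= 0).astype(float)
    cubic = np.column_stack([np.ones(n), t, x, x**2, x**3])
    gamma, *_ = np.linalg.lstsq(cubic, y, rcond=None)
    m3 = 6.0 * gamma[4]
    m3sq = max(m3**2, 1e-8 * sigma2 / sx**6)  # scale-consistent floor

    h2_l = 3.56 * (sigma2 / (f_hat * m3sq)) ** (1 / 7) * left.sum() ** (-1 / 7)
    h2_r = 3.56 * (sigma2 / (f_hat * m3sq)) ** (1 / 7) * right.sum() ** (-1 / 7)
    h2_l = min(h2_l, -x.min())
    h2_r = min(h2_r, max(x.max(), 1.0))

    def _curvature(side_mask, h2):
        sel = side_mask & (np.abs(x) <= h2)
        # widen until the quadratic is identified
        while np.unique(x[sel]).size < 4 and h2 < np.abs(x).max():
            h2 *= 1.5
            sel = side_mask & (np.abs(x) <= h2)
        xs, ys = x[sel], y[sel]
        quad = np.column_stack([np.ones(xs.size), xs, xs**2])
        beta, *_ = np.linalg.lstsq(quad, ys, rcond=None)
        return 2.0 * beta[2], int(sel.sum()), h2

    m2_l, n2_l, h2_l = _curvature(left, h2_l)
    m2_r, n2_r, h2_r = _curvature(right, h2_r)

    # Step 3: regularization and the final bandwidth
    r_l = 2160.0 * sigma2 / (n2_l * h2_l**4)
    r_r = 2160.0 * sigma2 / (n2_r * h2_r**4)
    denom = (m2_r - m2_l) ** 2 + r_l + r_r
    h = _CK_TRIANGULAR * (2.0 * sigma2 / (f_hat * denom)) ** (1 / 5) * n ** (-1 / 5)

    half_range = min(-x.min(), x.max())
    clamped = min(h, half_range)
    if clamped < MIN_BANDWIDTH:
        warnings.warn(
            f"selected bandwidth {clamped:.2f} below minimum support; using {MIN_BANDWIDTH}",
            stacklevel=2,
        )
        clamped = MIN_BANDWIDTH

    return BandwidthSelection(
        h=float(clamped),
        method="imbens-kalyanaraman",
        pilot_quantities={
            "h_unclamped": float(h),
            "h1": float(h1),
            "sigma2_cutoff": float(sigma2),
            "density_cutoff": float(f_hat),
            "m3": float(m3),
            "m2_left": float(m2_l),
            "m2_right": float(m2_r),
            "h2_left": float(h2_l),
            "h2_right": float(h2_r),
            "reg_left": float(r_l),
            "reg_right": float(r_r),
        },
    )


# --------------------------------------------------------------------- #
# model / results objects


class FuzzyRD:
    """Fuzzy local-linear regression-discontinuity model.

    Parameters
    ----------
    data
        Cohort table with one row per participant.
    outcome
        Name of the (winsorized, upstream) outcome column.
    first_stage
        Binary treatment-received column; ``None`` gives a sharp design
        whose estimate is the reduced-form (intent-to-treat) jump.
    covariates
        Nuisance covariates removed from both stages by the two-step
        adjustment before estimation.
    running
        Centered monthly running variable; month 0 is the first treated
        month.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        first_stage: str | None = None,
        covariates=(),
        running: str = "mdob",
        kernel: str = "triangular",
        missing: str = "complete",
        min_first_stage: float = 0.01,
    ):
        self.data = data
        self.outcome = outcome
        self.first_stage = first_stage
        self.covariates = tuple(covariates)
        self.running = running
        self.kernel = kernel
        self.missing = missing
        self.min_first_stage = min_first_stage

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, **kwargs) -> "FuzzyRD":
        return cls(data, outcome, **kwargs)

    # -- internals ------------------------------------------------------ #

    def _series(self, h: float):
        """Adjusted outcome and first-stage series on the rows inside h."""
        needed = [self.running, self.outcome] + ([self.first_stage] if self.first_stage else [])
        df = self.data.dropna(subset=needed)
        if self.covariates:
            adj_y = adjust_for_covariates(
                df, self.outcome, self.covariates, h, running=self.running, missing=self.missing
            )
            y = adj_y.values
            if self.first_stage:
                adj_d = adjust_for_covariates(
                    df, self.first_stage, self.covariates, h,
                    running=self.running, missing=self.missing,
                )
                d = adj_d.values
                common = y.index.intersection(d.index)
                y, d = y.loc[common], d.loc[common]
            else:
                d = None
            x = df.loc[y.index, self.running].astype(float)
        else:
            sub = df.loc[np.abs(df[self.running].astype(float)) <= h]
            x = sub[self.running].astype(float)
            y = sub[self.outcome].astype(float)
            d = sub[self.first_stage].astype(float) if self.first_stage else None
        return x.to_numpy(), y.to_numpy(), (None if d is None else d.to_numpy())

    def _select_h(self) -> BandwidthSelection:
        needed = [self.running, self.outcome]
        df = self.data.dropna(subset=needed)
        x = df[self.running].astype(float).to_numpy()
        y = df[self.outcome].astype(float).to_numpy()
        pilot = select_bandwidth_mse(x, y, kernel=self.kernel)
        if not self.covariates:
            return pilot
        # re-select once on the covariate-adjusted reduced-form outcome
        adj = adjust_for_covariates(
            df, self.outcome, self.covariates, pilot.h,
            running=self.running, missing=self.missing,
        )
        xa = df.loc[adj.values.index, self.running].astype(float).to_numpy()
        try:
            final = select_bandwidth_mse(xa, adj.values.to_numpy(), kernel=self.kernel)
        except ValueError:
            return pilot
        final.pilot_quantities["h_pilot_unadjusted"] = pilot.h
        return final

    # -- fitting --------------------------------------------------------- #

    def fit(self, bandwidth="mse") -> "FuzzyRDResults":
        """Estimate the discontinuity.

        ``bandwidth`` is a number of months or ``"mse"`` for the
        Imbens-Kalyanaraman selector (run on the covariate-adjusted
        reduced-form outcome for fuzzy designs, and shared with the first
        stage so the ITT = LATE x first-stage identity is exact).
        """
        if bandwidth == "mse":
            selection = self._select_h()
        else:
            h = float(bandwidth)
            if h <= 0:
                raise ValueError("bandwidth must be positive")
            selection = BandwidthSelection(h=h, method="fixed")
        h = selection.h

        x, y, d = self._series(h)
        jump_y = local_linear_jump(x, y, h, kernel=self.kernel)

        if d is not None:
            jump_d = local_linear_jump(x, d, h, kernel=self.kernel)
            cov_yd = _jump_covariance(jump_y, jump_d)
        else:
            jump_d = None
            cov_yd = 0.0

        itt, itt_se = jump_y.jump, jump_y.se
        weak = False
        if jump_d is None:
            estimate, se = itt, itt_se
            fs, fs_se = 1.0, 0.0
        else:
            fs, fs_se = jump_d.jump, jump_d.se
            if abs(fs) < self.min_first_stage:
                weak = True
                estimate, se = np.nan, np.nan
            else:
                estimate = itt / fs
                var = (
                    itt_se**2 / fs**2
                    + itt**2 * fs_se**2 / fs**4
                    - 2.0 * itt * cov_yd / fs**3
                )
                se = float(np.sqrt(max(var, 0.0)))

        if weak or se == 0:
            p = np.nan if weak else (0.0 if estimate != 0 else 1.0)
            ci = (np.nan, np.nan) if weak else (estimate, estimate)
        else:
            z = estimate / se
            p = 2.0 * stats.norm.sf(abs(z))
            zc = stats.norm.ppf(0.975)
            ci = (estimate - zc * se, estimate + zc * se)

        return FuzzyRDResults(
            model=self,
            estimate=float(estimate),
            se=float(se),
            ci_low=float(ci[0]),
            ci_high=float(ci[1]),
            p=float(p),
            reduced_form=float(itt),
            reduced_form_se=float(itt_se),
            first_stage=float(fs),
            first_stage_se=float(fs_se),
            h=float(h),
            n_eff_left=jump_y.n_eff_left,
            n_eff_right=jump_y.n_eff_right,
            kernel=self.kernel,
            bandwidth_selection=selection,
            weak_instrument=weak,
        )


@dataclass
class FuzzyRDResults:
    """Continuity-based estimate: fuzzy LATE with delta-method inference.

    ``estimate`` is in outcome units per unit of the first stage (per year
    of education when the first stage is staying in school one more year);
    ``reduced_form`` is the intent-to-treat jump, always reported alongside.
    """

    model: FuzzyRD
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    reduced_form: float
    reduced_form_se: float
    first_stage: float
    first_stage_se: float
    h: float
    n_eff_left: int
    n_eff_right: int
    kernel: str
    bandwidth_selection: BandwidthSelection
    weak_instrument: bool = False

    @property
    def n_eff(self) -> int:
        return self.n_eff_left + self.n_eff_right

    def summary(self) -> str:
        lines = [
            "Fuzzy local-linear regression discontinuity",
            "=" * 47,
            f"outcome:          {self.model.outcome}",
            f"first stage:      {self.model.first_stage or '(sharp design)'}",
            f"kernel:           {self.kernel}",
            f"bandwidth:        {self.h:.2f} months ({self.bandwidth_selection.method})",
            f"effective n:      {self.n_eff_left} left / {self.n_eff_right} right",
            "-" * 47,
            f"reduced form:     {self.reduced_form: .5f} (SE {self.reduced_form_se:.5f})",
            f"first-stage jump: {self.first_stage: .5f} (SE {self.first_stage_se:.5f})",
        ]
        if self.weak_instrument:
            lines.append("LATE:             suppressed (weak first stage)")
        else:
            lines += [
                f"LATE:             {self.estimate: .5f} (SE {self.se:.5f})",
                f"95% CI:           [{self.ci_low:.5f}, {self.ci_high:.5f}]",
                f"p (two-sided):    {self.p:.4f}",
            ]
        return "\n".join(lines)


def fuzzy_rd(
    table: pd.DataFrame,
    outcome: str,
    first_stage_col: str | None = None,
    covariates=(),
    bandwidth="mse",
    **kwargs,
) -> FuzzyRDResults:
    """Functional front-end: build a :class:`FuzzyRD` model and fit it."""
    model = FuzzyRD(table, outcome, first_stage=first_stage_col, covariates=covariates, **kwargs)
    return model.fit(bandwidth=bandwidth)
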