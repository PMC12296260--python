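"""Window-based "as-if random" analysis of the cutoff.

Participants born within a small window of +/- omega months around the
cutoff are treated as exchangeable and compared with a Bayesian linear
model: outcome ~ assignment + covariates, with independent autoscaled
normal priors on the coefficients. Evidence for the point null of no
assignment effect is quantified with Savage-Dickey density-ratio Bayes
factors under three prior widths and graded on Jeffreys' scale. The same
machinery, with continuous years of education substituted for the
assignment dummy, yields the correlational (non-causal) counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import expand_covariates

__all__ = [
    "PriorSpec",
    "BFResult",
    "BayesLinearResults",
    "LocalRandomization",
    "ConvergenceError",
    "select_window",
    "select_months",
    "autoscale_prior",
    "fit_bayes_linear",
    "savage_dickey_bf",
    "grade_evidence",
    "itt_analysis",
    "association_analysis",
    "screen_covariates",
]

RHAT_LIMIT = 1.05

#: Jeffreys' evidence bands on the Bayes-factor scale.
_JEFFREYS_BANDS = (
    (3.0, "anecdotal"),
    (10.0, "moderate"),
    (30.0, "strong"),
    (100.0, "very strong"),
    (np.inf, "extreme"),
)


class ConvergenceError(RuntimeError):
    """Raised when the sampler fails its rhat contract."""


@dataclass(frozen=True)
class PriorSpec:
    """Autoscaled normal prior on a regression coefficient.

    The realized prior SD is ``scale_multiplier * sd(y) / sd(x)``; the
    location is fixed at 0 for the tested coefficient. Multipliers 0.5, 1.0
    and 1.5 correspond to strongly, medium and weakly informative priors.
    """

    scale_multiplier: float = 1.0
    location: float = 0.0

    def __post_init__(self):
        if self.scale_multiplier <= 0:
            raise ValueError("scale_multiplier must be positive")


@dataclass
class BFResult:
    """Savage-Dickey Bayes factor with Jeffreys grading.

    ``bf01`` always equals ``1 / bf10``; when ``bf10 < 1`` the result is
    reported as the multiplicative inverse (evidence for the null).
    """

    bf10: float
    bf01: float
    grade: str
    direction: str

    @property
    def favors_null(self) -> bool:
        return self.direction == "null"


def select_window(table: pd.DataFrame, omega: int, running: str = "mdob") -> pd.DataFrame:
    """Rows born within +/- omega months of the cutoff.

    The pre window is months {-omega, ..., -1} and the post window
    {0, ..., omega - 1} (month 0 is the first treated month), so both sides
    have equal width and are adjacent to the cutoff.
    """
    if omega < 1:
        raise ValueError("omega must be a positive number of months")
    x = table[running]
    sub = table.loc[(x >= -omega) & (x <= omega - 1)].copy()
    pre, post = (sub[running] < 0).sum(), (sub[running] >= 0).sum()
    if pre == 0 or post == 0:
        raise ValueError(f"window omega={omega} has an empty side (pre={pre}, post={post})")
    sub["rosla"] = (sub[running] >= 0).astype(int)
    return sub


def select_months(table: pd.DataFrame, lo: int, hi: int, running: str = "mdob") -> pd.DataFrame:
    """Rows with the running variable in the inclusive range [lo, hi]."""
    x = table[running]
    sub = table.loc[(x >= lo) & (x <= hi)].copy()
    if len(sub) == 0:
        raise ValueError(f"no rows with {running} in [{lo}, {hi}]")
    return sub


def autoscale_prior(spec: PriorSpec, y, x) -> float:
    """Realized prior SD ``s * sd(y) / sd(x)`` for one coefficient."""
    sy = float(np.std(np.asarray(y, float), ddof=1))
    sx = float(np.std(np.asarray(x, float), ddof=1))
    if sx == 0 or sy == 0:
        raise ValueError("autoscaling undefined for a constant predictor or outcome")
    return spec.scale_multiplier * sy / sx


def screen_covariates(
    window: pd.DataFrame,
    covariates,
    assignment: str = "rosla",
    running: str = "mdob",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Expand covariates to a numeric block, dropping degenerate columns.

    Dropped, with a reason: covariates that are deterministic functions of
    the running variable (zero within-month variance but non-constant, e.g.
    the summer-born indicator), low-cardinality covariates perfectly
    separated from assignment inside the window (a zero cell in the
    covariate x assignment table), and columns without variance (including
    site levels absent in-window).
    """
    dropped: list[tuple[str, str]] = []
    keep_names = []
    for name in covariates:
        col = window[name]
        obs = col.dropna()
        if obs.nunique() <= 1:
            dropped.append((name, "no variance in window"))
            continue
        if running in window.columns:
            per_month = obs.groupby(window.loc[obs.index, running]).nunique()
            if (per_month <= 1).all():
                dropped.append((name, "deterministic function of the running variable"))
                continue
        if assignment in window.columns and obs.nunique() <= 10:
            tab = pd.crosstab(col, window[assignment])
            if tab.shape[1] == 2 and (tab == 0).any().any():
                dropped.append((name, "separated from assignment in window"))
                continue
        keep_names.append(name)

    block = expand_covariates(window, keep_names)
    for col in list(block.columns):
        nonnull = block[col].dropna()
        if nonnull.nunique() <= 1:
            dropped.append((col, "no variance in window (level absent)"))
            block = block.drop(columns=[col])
    return block, dropped


# --------------------------------------------------------------------- #
# posterior machinery


@dataclass
class BayesLinearResults:
    """Posterior summary for a Bayesian linear model of one window.

    Draws (for the MCMC path) or analytic moments (for the conjugate
    plug-in path) of all coefficients, convergence diagnostics, and the
    ingredients of the Savage-Dickey ratio for the focal coefficient.
    """

    focal: str
    names: list[str]
    mean: pd.Series
    sd: pd.Series
    prior_sd: pd.Series
    prior_mean: pd.Series
    method: str
    nobs: int
    sigma: float
    draws: np.ndarray | None = None  # (chains, draws, params)
    rhat: pd.Series | None = None
    n_chains: int = 0
    n_iterations: int = 0
    dropped_covariates: list = field(default_factory=list)

    @property
    def focal_mean(self) -> float:
        return float(self.mean[self.focal])

    @property
    def focal_sd(self) -> float:
        return float(self.sd[self.focal])

    def density_at_zero(self, method: str = "normal") -> float:
        """Marginal posterior density of the focal coefficient at 0.

        ``"normal"`` (default) uses a normal approximation from the
        posterior mean and SD; ``"kde"`` uses a Gaussian kernel density of
        the draws (MCMC path only).
        """
        if method == "normal":
            dens = stats.norm.pdf(0.0, loc=self.focal_mean, scale=self.focal_sd)
        elif method == "kde":
            if self.draws is None:
                raise ValueError("kde density requires posterior draws")
            j = self.names.index(self.focal)
            dens = float(stats.gaussian_kde(self.draws[:, :, j].ravel())(0.0)[0])
        else:
            raise ValueError(f"unknown density method {method!r}")
        if not np.isfinite(dens) or dens <= 0:
            raise ValueError(
                "degenerate posterior density at 0; increase the number of draws"
            )
        return float(dens)

    def bayes_factor(self, density_method: str = "normal") -> BFResult:
        return savage_dickey_bf(self, density_method=density_method)

    def summary(self) -> str:
        lines = [
            "Bayesian linear model (local randomization window)",
            "=" * 52,
            f"focal term: {self.focal}   method: {self.method}   n: {self.nobs}",
        ]
        if self.n_chains:
            lines.append(f"chains: {self.n_chains}   total iterations: {self.n_iterations}")
        lines.append("-" * 52)
        lines.append(f"{'term':<18}{'post mean':>12}{'post sd':>12}{'prior sd':>12}")
        for name in self.names:
            lines.append(
                f"{name:<18}{self.mean[name]:>12.4f}{self.sd[name]:>12.4f}{self.prior_sd[name]:>12.4f}"
            )
        if self.rhat is not None:
            lines.append(f"max rhat: {float(self.rhat.max()):.4f}")
        if self.dropped_covariates:
            lines.append(f"dropped: {self.dropped_covariates}")
        return "\n".join(lines)


def _gibbs_sample(
    y: np.ndarray,
    X: np.ndarray,
    prior_mean: np.ndarray,
    prior_sd: np.ndarray,
    iterations: int,
    chains: int,
    seed: int,
    sigma: float | None,
    sigma_prior_rate: float,
):
    """Gibbs sampler for the normal linear model with independent normal
    coefficient priors.

    Coefficients are drawn from their exact conditional multivariate normal
    given the scale; the residual-scale parameter carries an exponential
    prior and is updated with a random-walk Metropolis step on log(sigma)
    (skipped when ``sigma`` is fixed, the conjugate oracle path). The first
    half of each chain is warmup.
    """
    n, p = X.shape
    per_chain = max(iterations // chains, 2)
    warmup = per_chain // 2
    xtx = X.T @ X
    xty = X.T @ y
    prior_prec = 1.0 / prior_sd**2
    rng = np.random.default_rng([int(seed), 17])

    kept = per_chain - warmup
    draws = np.empty((chains, kept, p + 1))
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid0 = y - X @ ols
    sigma0 = float(np.sqrt(resid0 @ resid0 / max(n - p, 1)))

    for c in range(chains):
        beta = ols.copy()
        sig = sigma if sigma is not None else sigma0 * float(np.exp(0.5 * rng.standard_normal()))
        log_sig = np.log(sig)
        for it in range(per_chain):
            prec = xtx / sig**2 + np.diag(prior_prec)
            chol = np.linalg.cholesky(prec)
            rhs = xty / sig**2 + prior_prec * prior_mean
            mean = np.linalg.solve(prec, rhs)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, z)

            if sigma is None:
                resid = y - X @ beta
                ssr = float(resid @ resid)

                def logpost(ls):
                    s = np.exp(ls)
                    # log-likelihood + exponential prior + log-Jacobian
                    return -n * ls - ssr / (2 * s**2) - sigma_prior_rate * s + ls

                prop = log_sig + 0.3 * rng.standard_normal()
                if np.log(rng.random()) < logpost(prop) - logpost(log_sig):
                    log_sig = prop
                    sig = float(np.exp(log_sig))
            if it >= warmup:
                draws[c, it - warmup, :p] = beta
                draws[c, it - warmup, p] = sig
    return draws


def fit_bayes_linear(
    table: pd.DataFrame,
    outcome: str,
    focal: str,
    covariates=(),
    prior: PriorSpec = PriorSpec(1.0),
    chains: int = 4,
    iterations: int = 80_000,
    seed: int = 0,
    method: str = "gibbs",
    sigma: float | None = None,
    nuisance_multiplier: float = 2.5,
    running: str = "mdob",
) -> BayesLinearResults:
    """Posterior of ``outcome ~ focal + covariates`` on a window subset.

    Priors are independent normals centered at 0 with autoscaled SDs
    (``prior.scale_multiplier`` for the focal coefficient,
    ``nuisance_multiplier`` for the other covariates); the intercept prior
    is centered at the sample mean of the outcome with SD ``2.5 sd(y)``.
    The residual scale carries an exponential prior with rate ``1/sd(y)``
    unless fixed via ``sigma`` (the conjugate oracle path, which is also
    what ``method="analytic"`` evaluates in closed form with a plug-in
    OLS scale).

    Raises :class:`ConvergenceError` if any split-rhat reaches 1.05.
    """
    cov_block, dropped = screen_covariates(
        table, covariates, running=running if running in table.columns else "",
    )
    used = pd.concat(
        [table[[outcome, focal]].astype(float), cov_block], axis=1
    ).dropna()
    y = used[outcome].to_numpy()
    focal_x = used[focal].to_numpy()
    if np.std(focal_x, ddof=1) == 0:
        raise ValueError(f"focal predictor {focal!r} has no variance in the window")
    if np.std(y, ddof=1) == 0:
        raise ValueError(f"outcome {outcome!r} has no variance in the window")

    names = ["const", focal] + [c for c in cov_block.columns]
    X = np.column_stack(
        [np.ones(len(used)), focal_x]
        + [used[c].to_numpy(dtype=float) for c in cov_block.columns]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design in window (columns {names})")

    sy = float(np.std(y, ddof=1))
    prior_sd = np.empty(X.shape[1])
    prior_mean = np.zeros(X.shape[1])
    prior_sd[0] = 2.5 * sy
    prior_mean[0] = float(np.mean(y))
    prior_sd[1] = autoscale_prior(prior, y, focal_x)
    for j, c in enumerate(cov_block.columns, start=2):
        prior_sd[j] = autoscale_prior(PriorSpec(nuisance_multiplier), y, used[c].to_numpy())

    if method == "analytic":
        sig = sigma if sigma is not None else _ols_sigma(y, X)
        prec = X.T @ X / sig**2 + np.diag(1.0 / prior_sd**2)
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ y / sig**2 + prior_mean / prior_sd**2)
        post_mean = pd.Series(mean, index=names)
        post_sd = pd.Series(np.sqrt(np.diag(cov)), index=names)
        return BayesLinearResults(
            focal=focal, names=names, mean=post_mean, sd=post_sd,
            prior_sd=pd.Series(prior_sd, index=names),
            prior_mean=pd.Series(prior_mean, index=names),
            method="analytic", nobs=len(used), sigma=float(sig),
            dropped_covariates=dropped,
        )
    if method != "gibbs":
        raise ValueError(f"unknown method {method!r}")

    draws = _gibbs_sample(
        y, X, prior_mean, prior_sd, iterations, chains, seed,
        sigma=sigma, sigma_prior_rate=1.0 / sy,
    )
    if sigma is not None:
        sampled_names, sampled = names, draws[..., : len(names)]
    else:
        sampled_names, sampled = names + ["sigma"], draws
    rhat_da = az.rhat(az.convert_to_dataset(sampled, dims={"x": ["param"]}))
    rhat = pd.Series(np.asarray(rhat_da["x"]), index=sampled_names)
    if float(rhat.max()) >= RHAT_LIMIT:
        worst = rhat.idxmax()
        raise ConvergenceError(
            f"sampler failed to converge: rhat[{worst}] = {rhat.max():.3f} >= {RHAT_LIMIT}; "
            f"posterior means {draws[..., :len(names)].mean(axis=(0, 1))}"
        )
    flat = draws.reshape(-1, draws.shape[-1])
    post_mean = pd.Series(flat[:, : len(names)].mean(axis=0), index=names)
    post_sd = pd.Series(flat[:, : len(names)].std(axis=0, ddof=1), index=names)
    return BayesLinearResults(
        focal=focal, names=names, mean=post_mean, sd=post_sd,
        prior_sd=pd.Series(prior_sd, index=names),
        prior_mean=pd.Series(prior_mean, index=names),
        method="gibbs", nobs=len(used), sigma=float(flat[:, -1].mean()),
        draws=draws[..., : len(names)], rhat=rhat,
        n_chains=chains, n_iterations=iterations,
        dropped_covariates=dropped,
    )


def _ols_sigma(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(np.sqrt(resid @ resid / max(len(y) - X.shape[1], 1)))


def savage_dickey_bf(posterior: BayesLinearResults, density_method: str = "normal") -> BFResult:
    """Savage-Dickey density-ratio Bayes factor at the point null 0.

    ``bf01`` is the posterior density of the focal coefficient at 0 divided
    by its (autoscaled normal) prior density at 0; ``bf10 = 1 / bf01``.
    """
    post_dens = posterior.density_at_zero(method=density_method)
    prior_sd = float(posterior.prior_sd[posterior.focal])
    prior_dens = stats.norm.pdf(0.0, loc=0.0, scale=prior_sd)
    bf01 = post_dens / prior_dens
    bf10 = 1.0 / bf01
    return BFResult(
        bf10=float(bf10),
        bf01=float(bf01),
        grade=grade_evidence_from_bf10(bf10),
        direction="alternative" if bf10 > 1 else ("null" if bf10 < 1 else "none"),
    )


def grade_evidence_from_bf10(bf10: float) -> str:
    """Jeffreys grade for a BF10 (bands 1-3 anecdotal, 3-10 moderate,
    10-30 strong, 30-100 very strong, >100 extreme)."""
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    if bf10 == 1.0:
        return "no evidence"
    side = "alternative" if bf10 > 1 else "null"
    magnitude = bf10 if bf10 > 1 else 1.0 / bf10
    for limit, label in _JEFFREYS_BANDS:
        if magnitude < limit:
            return f"{label} evidence for the {side}"
    return f"extreme evidence for the {side}"


def grade_evidence(bf) -> str:
    """Jeffreys grade for a :class:`BFResult` or a raw BF10 value."""
    if isinstance(bf, BFResult):
        return grade_evidence_from_bf10(bf.bf10)
    return grade_evidence_from_bf10(float(bf))


# --------------------------------------------------------------------- #
# model object and the two analyses


class LocalRandomization:
    """Local-randomization model of a window around the cutoff.

    Compares participants born just before and just after the cutoff with a
    Bayesian linear model; ``focal="rosla"`` gives the causal intent-to-treat
    contrast, ``focal="eduyears"`` the correlational (association) variant
    on the same participants.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        focal: str = "rosla",
        covariates=(),
        omega: int | None = 5,
        window: tuple[int, int] | None = None,
        running: str = "mdob",
    ):
        if window is not None:
            self.window = select_months(data, window[0], window[1], running=running)
        else:
            self.window = select_window(data, omega, running=running)
        self.outcome = outcome
        self.focal = focal
        self.covariates = tuple(c for c in covariates if c != focal)
        self.omega = omega
        self.running = running

    def fit(
        self,
        prior: PriorSpec = PriorSpec(1.0),
        method: str = "gibbs",
        iterations: int = 80_000,
        chains: int = 4,
        seed: int = 0,
        sigma: float | None = None,
    ) -> BayesLinearResults:
        return fit_bayes_linear(
            self.window,
            self.outcome,
            self.focal,
            covariates=self.covariates,
            prior=prior,
            chains=chains,
            iterations=iterations,
            seed=seed,
            method=method,
            sigma=sigma,
            running=self.running,
        )


def _per_prior(model: LocalRandomization, priors, **fit_kwargs):
    out = []
    for spec in priors:
        spec = spec if isinstance(spec, PriorSpec) else PriorSpec(float(spec))
        posterior = model.fit(prior=spec, **fit_kwargs)
        out.append({"prior": spec, "posterior": posterior, "bf": posterior.bayes_factor()})
    return out


def itt_analysis(
    table: pd.DataFrame,
    outcome: str,
    omega: int,
    priors=(0.5, 1.0, 1.5),
    covariates=(),
    **fit_kwargs,
) -> list[dict]:
    """Intent-to-treat window analysis: one posterior and BF per prior.

    Covariates deterministically tied to assignment in the window (the
    summer-born indicator for narrow windows, site levels without
    observations) are screened out and logged on each posterior.
    """
    model = LocalRandomization(table, outcome, focal="rosla", covariates=covariates, omega=omega)
    return _per_prior(model, priors, **fit_kwargs)


def association_analysis(
    table: pd.DataFrame,
    outcome: str,
    omega: int,
    priors=(0.5, 1.0, 1.5),
    covariates=(),
    **fit_kwargs,
) -> list[dict]:
    """Correlational counterpart: continuous years of education substituted
    for the assignment dummy on the identical window. The estimand is an
    association, not a causal effect."""
    model = LocalRandomization(table, outcome, focal="eduyears", covariates=covariates, omega=omega)
    return _per_prior(model, priors, **fit_kwargs)
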