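"""End-to-end orchestration of the preregistered analysis pattern.

Runs, on one cohort table (synthetic or read from disk): Tukey
winsorization, the global and regional continuity-based analyses with
per-modality FDR correction, the Bayesian local-randomization suite with
its correlational counterpart, the validity diagnostics, the shifted
sub-cohort replication of the association, and binned plot data - with a
provenance block sufficient to regenerate every table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    GLOBAL_OUTCOMES,
    CohortConfig,
    generate_cohort,
    generate_regional_outcomes,
    read_cohort,
    regional_columns,
)
from .continuity import FuzzyRD, local_linear_jump
from .localrand import association_analysis, itt_analysis
from .preprocess import bh_fdr, winsorize_tukey
from .validity import density_test_suite, placebo_cutoffs, placebo_outcomes

__all__ = [
    "RunConfig",
    "ResultsBundle",
    "prepare_table",
    "run_global_continuity",
    "run_regional_continuity",
    "run_local_randomization_suite",
    "run_subcohort_replication",
    "rd_plot_binned",
    "run_all",
]

DEFAULT_COVARIATES = ("sex", "summer", "dos", "dos2", "site", "motion", "t2flair")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    synthetic: CohortConfig = field(default_factory=CohortConfig)
    input_path: str | None = None
    outcomes: tuple = GLOBAL_OUTCOMES
    covariates: tuple = DEFAULT_COVARIATES
    frameworks: tuple = ("continuity", "local_randomization")
    omegas: tuple = (1, 5)
    priors: tuple = (0.5, 1.0, 1.5)
    alpha: float = 0.05
    q: float = 0.05
    first_stage: str = "stayed16"
    regional: bool = True
    placebo_offsets: tuple = (-48, -24, 24, 48)
    bayes_method: str = "gibbs"
    bayes_iterations: int = 20_000
    bayes_chains: int = 4
    subcohort_spacing: int = 24
    subcohort_width: int = 10
    n_subcohorts: int = 8
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.q < 1:
            raise ValueError("alpha and q must lie in (0, 1)")
        if not self.omegas:
            raise ValueError("omega list must be non-empty")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "synthetic" in payload and isinstance(payload["synthetic"], dict):
            payload["synthetic"] = CohortConfig.from_dict(payload["synthetic"])
        for key in ("outcomes", "covariates", "frameworks", "omegas", "priors", "placebo_offsets"):
            if key in payload and payload[key] is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class ResultsBundle:
    """Machine-readable results of one full run."""

    global_continuity: pd.DataFrame
    regional_continuity: pd.DataFrame
    local_randomization: pd.DataFrame
    validity_density: pd.DataFrame
    validity_placebo: pd.DataFrame
    placebo_cutoffs: pd.DataFrame
    subcohorts: pd.DataFrame
    binned: pd.DataFrame
    winsor_log: pd.DataFrame
    provenance: dict

    def save(self, outdir) -> None:
        """Write every table as TSV plus a JSON run manifest."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "global_continuity", "regional_continuity", "local_randomization",
            "validity_density", "validity_placebo", "placebo_cutoffs",
            "subcohorts", "binned", "winsor_log",
        ):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


# --------------------------------------------------------------------- #


def prepare_table(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Obtain the cohort (generate or read) and winsorize every outcome.

    Winsorization is applied once per outcome column on the full analysis
    sample, before any bandwidth logic; the fences and cap counts are
    returned as a log table.
    """
    if config.input_path:
        table = read_cohort(config.input_path)
    else:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        table = generate_cohort(syn)
        if config.regional:
            table = generate_regional_outcomes(table, syn)

    outcome_cols = list(config.outcomes)
    if config.regional and not config.input_path:
        for cols in regional_columns(config.synthetic).values():
            outcome_cols.extend(c for c in cols if c in table.columns)

    log_rows = []
    for col in outcome_cols:
        if col not in table.columns:
            continue
        values, report = winsorize_tukey(table[col].to_numpy())
        table[col] = values
        log_rows.append(
            {"outcome": col, "lower_fence": report.lower_fence,
             "upper_fence": report.upper_fence,
             "n_capped_low": report.n_capped_low,
             "n_capped_high": report.n_capped_high}
        )
    return table, pd.DataFrame(log_rows)


def run_global_continuity(config: RunConfig, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fuzzy local-linear RD per global outcome; errors isolated per row."""
    config.validate()
    if table is None:
        table, _ = prepare_table(config)
    rows = []
    for outcome in config.outcomes:
        try:
            if outcome not in table.columns:
                raise KeyError(f"outcome column {outcome!r} missing from table")
            res = FuzzyRD(
                table, outcome, first_stage=config.first_stage,
                covariates=config.covariates,
            ).fit("mse")
            rows.append(
                {"outcome": outcome, "estimate": res.estimate, "se": res.se,
                 "ci_low": res.ci_low, "ci_high": res.ci_high, "p": res.p,
                 "reduced_form": res.reduced_form, "first_stage": res.first_stage,
                 "h": res.h, "n_eff_left": res.n_eff_left,
                 "n_eff_right": res.n_eff_right,
                 "significant": bool(res.p < config.alpha) if np.isfinite(res.p) else False,
                 "error": ""}
            )
        except (ValueError, KeyError) as err:
            rows.append(
                {"outcome": outcome, "estimate": np.nan, "se": np.nan,
                 "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                 "reduced_form": np.nan, "first_stage": np.nan, "h": np.nan,
                 "n_eff_left": 0, "n_eff_right": 0, "significant": False,
                 "error": str(err)}
            )
    return pd.DataFrame(rows)


def run_regional_continuity(config: RunConfig, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fuzzy RD per region with Benjamini-Hochberg correction per modality
    (m = number of regions in the panel)."""
    config.validate()
    if table is None:
        table, _ = prepare_table(config)
    frames = []
    for panel, cols in regional_columns(config.synthetic).items():
        cols = [c for c in cols if c in table.columns]
        if not cols:
            continue
        rows = []
        for col in cols:
            try:
                res = FuzzyRD(
                    table, col, first_stage=config.first_stage,
                    covariates=config.covariates,
                ).fit("mse")
                rows.append(
                    {"modality": panel, "region": col, "estimate": res.estimate,
                     "se": res.se, "p": res.p, "h": res.h,
                     "n_eff": res.n_eff, "error": ""}
                )
            except (ValueError, KeyError) as err:
                rows.append(
                    {"modality": panel, "region": col, "estimate": np.nan,
                     "se": np.nan, "p": np.nan, "h": np.nan, "n_eff": 0,
                     "error": str(err)}
                )
        frame = pd.DataFrame(rows)
        ok = frame["p"].notna()
        frame["q"] = np.nan
        frame["reject"] = False
        if ok.any():
            qvals, reject = bh_fdr(frame.loc[ok, "p"].to_numpy(), q=config.q)
            frame.loc[ok, "q"] = qvals
            frame.loc[ok, "reject"] = reject
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["modality", "region", "estimate", "se", "p", "h", "n_eff", "error", "q", "reject"]
        )
    return pd.concat(frames, ignore_index=True)


def run_local_randomization_suite(config: RunConfig, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """ITT and association Bayes-factor tables per outcome x window x prior."""
    config.validate()
    if table is None:
        table, _ = prepare_table(config)
    rows = []
    for outcome in config.outcomes:
        for omega in config.omegas:
            for analysis, func in (("itt", itt_analysis), ("association", association_analysis)):
                try:
                    results = func(
                        table, outcome, omega, priors=config.priors,
                        covariates=config.covariates,
                        method=config.bayes_method,
                        iterations=config.bayes_iterations,
                        chains=config.bayes_chains,
                        seed=config.seed,
                    )
                    for entry in results:
                        post, bf = entry["posterior"], entry["bf"]
                        rows.append(
                            {"framework": analysis, "outcome": outcome, "omega": omega,
                             "prior_multiplier": entry["prior"].scale_multiplier,
                             "n": post.nobs,
                             "posterior_mean": post.focal_mean,
                             "posterior_sd": post.focal_sd,
                             "bf10": bf.bf10, "bf01": bf.bf01,
                             "grade": bf.grade,
                             "dropped": ";".join(f"{n}({r})" for n, r in post.dropped_covariates),
                             "error": ""}
                        )
                except (ValueError, RuntimeError) as err:
                    for mult in config.priors:
                        rows.append(
                            {"framework": analysis, "outcome": outcome, "omega": omega,
                             "prior_multiplier": float(mult), "n": 0,
                             "posterior_mean": np.nan, "posterior_sd": np.nan,
                             "bf10": np.nan, "bf01": np.nan, "grade": "",
                             "dropped": "", "error": str(err)}
                        )
    return pd.DataFrame(rows)


def run_subcohort_replication(
    config: RunConfig,
    table: pd.DataFrame | None = None,
    n_cohorts: int | None = None,
    spacing_months: int | None = None,
    width_months: int | None = None,
) -> pd.DataFrame:
    """Association analysis replicated in shifted sub-cohorts.

    Windows of ``width_months`` are spaced ``spacing_months`` apart on both
    sides of (and excluding) the main cutoff window, giving forest-plot
    style posterior estimates of the education-outcome association per
    cohort.
    """
    from .localrand import LocalRandomization, PriorSpec

    config.validate()
    if table is None:
        table, _ = prepare_table(config)
    n_cohorts = n_cohorts or config.n_subcohorts
    spacing = spacing_months or config.subcohort_spacing
    width = width_months or config.subcohort_width
    half = width // 2
    per_side = n_cohorts // 2
    rows = []
    for outcome in config.outcomes:
        for k in [*range(-per_side, 0), *range(1, per_side + 1)]:
            lo = -half + spacing * k
            hi = half - 1 + spacing * k
            try:
                model = LocalRandomization(
                    table, outcome, focal="eduyears",
                    covariates=config.covariates, omega=None, window=(lo, hi),
                )
                post = model.fit(
                    prior=PriorSpec(1.0), method=config.bayes_method,
                    iterations=config.bayes_iterations,
                    chains=config.bayes_chains, seed=config.seed,
                )
                bf = post.bayes_factor()
                rows.append(
                    {"outcome": outcome, "cohort": k, "months_lo": lo, "months_hi": hi,
                     "n": post.nobs, "posterior_mean": post.focal_mean,
                     "posterior_sd": post.focal_sd, "bf10": bf.bf10, "error": ""}
                )
            except (ValueError, RuntimeError) as err:
                rows.append(
                    {"outcome": outcome, "cohort": k, "months_lo": lo, "months_hi": hi,
                     "n": 0, "posterior_mean": np.nan, "posterior_sd": np.nan,
                     "bf10": np.nan, "error": str(err)}
                )
    return pd.DataFrame(rows)


def rd_plot_binned(table: pd.DataFrame, outcome: str, h: float, running: str = "mdob") -> pd.DataFrame:
    """Per-month outcome means with bandwidth flags and fitted lines.

    One row per month of the running variable: the mean outcome of
    individuals born in that month, the count, whether the month lies
    inside the bandwidth, and the two side-specific local-linear fits
    evaluated at the month (inside the bandwidth only).
    """
    sub = table.dropna(subset=[running, outcome])
    grouped = sub.groupby(running)[outcome].agg(["mean", "count"]).reset_index()
    grouped = grouped.rename(columns={running: "month", "mean": "mean_outcome", "count": "n"})
    grouped["in_bandwidth"] = np.abs(grouped["month"]) < h

    x = sub[running].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=float)
    est = local_linear_jump(x, y, h)
    month = grouped["month"].to_numpy(dtype=float)
    fit = np.where(
        month < 0,
        est.intercept_left + est.slope_left * month,
        est.intercept_right + est.slope_right * month,
    )
    grouped["fit"] = np.where(grouped["in_bandwidth"], fit, np.nan)
    return grouped


def plot_rd(binned: pd.DataFrame, outcome: str, path=None):
    """Scatter of monthly means with the local-linear fits (optional PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    out_band = binned.loc[~binned["in_bandwidth"]]
    in_band = binned.loc[binned["in_bandwidth"]]
    ax.scatter(out_band["month"], out_band["mean_outcome"], s=12, color="lightsteelblue")
    ax.scatter(in_band["month"], in_band["mean_outcome"], s=12, color="darkblue")
    for side in (in_band.loc[in_band["month"] < 0], in_band.loc[in_band["month"] >= 0]):
        ax.plot(side["month"], side["fit"], color="firebrick")
    ax.axvline(0, linestyle="--", color="grey")
    ax.set_xlabel("month of birth relative to cutoff")
    ax.set_ylabel(outcome)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def run_all(config: RunConfig) -> ResultsBundle:
    """Execute the full analysis and return (optionally write) the bundle."""
    config.validate()
    table, winsor_log = prepare_table(config)

    global_tab = run_global_continuity(config, table)
    regional_tab = (
        run_regional_continuity(config, table)
        if config.regional
        else pd.DataFrame()
    )
    localrand_tab = run_local_randomization_suite(config, table)
    density_tab = density_test_suite(table)
    placebo_tab = placebo_outcomes(
        table, config.covariates, frameworks=config.frameworks,
        omega=max(config.omegas), seed=config.seed,
    )
    cutoff_tab = placebo_cutoffs(table, config.outcomes[0], offsets=config.placebo_offsets)
    subcohort_tab = run_subcohort_replication(config, table)

    binned_frames = []
    for outcome, h in zip(global_tab["outcome"], global_tab["h"]):
        if not np.isfinite(h):
            continue
        b = rd_plot_binned(table, outcome, h)
        b.insert(0, "outcome", outcome)
        binned_frames.append(b)
    binned = pd.concat(binned_frames, ignore_index=True) if binned_frames else pd.DataFrame()

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "rdnat_version": __version__,
        "n_rows": int(len(table)),
        "outcomes": list(config.outcomes),
    }
    bundle = ResultsBundle(
        global_continuity=global_tab,
        regional_continuity=regional_tab,
        local_randomization=localrand_tab,
        validity_density=density_tab,
        validity_placebo=placebo_tab,
        placebo_cutoffs=cutoff_tab,
        subcohorts=subcohort_tab,
        binned=binned,
        winsor_log=winsor_log,
        provenance=provenance,
    )
    if config.outdir:
        bundle.save(config.outdir)
    return bundle
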