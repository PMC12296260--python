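"""Synthetic birth-cohort generator for a school-leaving-age natural experiment.

The generator emulates the data structure of a policy reform assigned by a
date-of-birth cutoff: a discrete monthly running variable (``mdob``, centered
so the first post-cutoff month is 0), a binary assignment indicator
(``rosla``), a probabilistic first stage (``stayed16``, whether the
participant stayed in school to age 16), continuous years of education
(college completers coded 21), standard neuroimaging nuisance covariates, and
correlated continuous outcomes (six global brain measures plus optional
regional panels).

The treatment model is one-sided: assignment adds schooling with probability
``compliance_jump`` on top of a secular compliance level, so the implied
intent-to-treat effect equals ``compliance_jump`` times the complier effect
exactly in expectation. An optional latent factor confounds education and
outcomes without touching assignment, to emulate the selection processes
that make naive education-brain associations non-causal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortConfig",
    "ConfigError",
    "GLOBAL_OUTCOMES",
    "DEFAULT_PANELS",
    "COVARIATE_COLUMNS",
    "generate_cohort",
    "generate_regional_outcomes",
    "read_cohort",
    "write_cohort",
]

#: The six global imaging-derived outcomes: total surface area, mean cortical
#: thickness, total brain volume, weighted fractional anisotropy, white matter
#: hyperintensities, and cerebrospinal fluid volume.
GLOBAL_OUTCOMES = ("SA", "CT", "TBV", "wFA", "WMh", "CSF")

#: Regional outcome panels and their region counts (bilateral cortical
#: regions for SA and CT, white-matter tracts, subcortical volumes).
DEFAULT_PANELS = {"SA": 66, "CT": 66, "wFA": 27, "subcort": 18}

#: Covariates of no interest carried by every cohort.
COVARIATE_COLUMNS = ("sex", "summer", "dos", "dos2", "site", "motion", "t2flair")

#: Covariate columns eligible for missing-completely-at-random gaps.
MISSINGABLE_COLUMNS = ("sex", "motion", "site", "t2flair")


class ConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


def _default_covariate_effects() -> dict[str, float]:
    return {"sex": 0.5, "motion": -0.2, "dos": -1e-4}


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic data-generating process.

    Parameters
    ----------
    months_range
        Inclusive month indices relative to the cutoff; must span it
        (``min < 0 <= max``). Default covers ten years on either side.
    n_per_month
        Participants per birth month, either a scalar or a per-month vector.
    compliance_pre
        P(stayed to 16) just before the cutoff.
    compliance_jump
        Jump in that probability at the cutoff (the first stage).
    compliance_trend
        Per-month slope of the compliance probability.
    outcome_trend
        Ascending polynomial coefficients of the smooth secular trend in the
        outcomes, as a function of ``mdob`` (units of ``noise_sd``).
    effect_delta
        Discontinuity added to the outcome for participants who stayed to 16,
        in units of ``noise_sd`` (raw units when ``noise_sd == 0``). Either a
        scalar applied to every global outcome or a per-outcome mapping.
    covariate_effects
        Additive outcome effect per unit of each numeric covariate, in units
        of ``noise_sd``.
    site_effects
        Additive offset per acquisition site.
    noise_sd
        Residual SD of the outcomes; a shared person-level factor gives the
        global outcomes pairwise correlation ``outcome_correlation``.
    missing_covariate_rate
        MCAR missingness rate applied per covariate cell (never to the
        running variable, assignment, first stage, or outcomes).
    n_regions
        Regional panel sizes (see :data:`DEFAULT_PANELS`).
    region_correlation
        Equicorrelation of region-specific residuals within a panel.
    regional_effect_delta
        Per-region treatment discontinuity (scalar, or mapping panel ->
        scalar or vector), in units of ``noise_sd``.
    confound_outcome, confound_edu_logit
        Loadings of a latent person-level factor on the outcomes (SD units)
        and on the log-odds of completing college; both default to 0
        (unconfounded null design).
    """

    months_range: tuple[int, int] = (-120, 119)
    n_per_month: int | Sequence[int] = 120
    compliance_pre: float = 0.90
    compliance_jump: float = 0.10
    compliance_trend: float = 0.0
    outcome_trend: Sequence[float] = (0.0, 0.005, 2e-5)
    effect_delta: float | Mapping[str, float] = 0.0
    covariate_effects: dict[str, float] = field(default_factory=_default_covariate_effects)
    site_effects: Sequence[float] = (0.0, 0.08, -0.08)
    noise_sd: float = 1.0
    outcome_correlation: float = 0.6
    missing_covariate_rate: float = 0.04
    n_regions: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PANELS))
    region_correlation: float = 0.5
    regional_effect_delta: float | Mapping[str, object] = 0.0
    confound_outcome: float = 0.0
    confound_edu_logit: float = 0.0
    college_rate: float = 0.30
    alevel_rate: float = 0.40
    dos_max_days: int = 2400
    seed: int = 0

    # ------------------------------------------------------------------ #

    @property
    def months(self) -> np.ndarray:
        lo, hi = self.months_range
        return np.arange(lo, hi + 1)

    def counts(self) -> np.ndarray:
        months = self.months
        if np.isscalar(self.n_per_month):
            return np.full(months.size, int(self.n_per_month))
        counts = np.asarray(self.n_per_month, dtype=int)
        if counts.size != months.size:
            raise ConfigError(
                f"n_per_month vector has length {counts.size}, "
                f"expected {months.size} (one entry per month)"
            )
        return counts

    def compliance_probability(self, month: np.ndarray) -> np.ndarray:
        month = np.asarray(month)
        return (
            self.compliance_pre
            + self.compliance_trend * month
            + self.compliance_jump * (month >= 0)
        )

    def validate(self) -> None:
        lo, hi = self.months_range
        if not (lo < 0 <= hi):
            raise ConfigError(f"months_range {self.months_range} must span the cutoff (min < 0 <= max)")
        counts = self.counts()
        if (counts < 1).any():
            raise ConfigError("n_per_month must be >= 1 for every month")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not 0 <= self.missing_covariate_rate < 1:
            raise ConfigError("missing_covariate_rate must lie in [0, 1)")
        if not 0 <= self.region_correlation < 1:
            raise ConfigError("region_correlation must lie in [0, 1)")
        if not 0 <= self.outcome_correlation < 1:
            raise ConfigError("outcome_correlation must lie in [0, 1)")
        probs = self.compliance_probability(self.months)
        bad = (probs < 0) | (probs > 1)
        if bad.any():
            month = int(self.months[bad][0])
            raise ConfigError(
                f"compliance trajectory leaves [0, 1] at month {month} "
                f"(p = {probs[bad][0]:.4f}); adjust compliance_pre/jump/trend"
            )
        for name, count in self.n_regions.items():
            if count <= 0:
                raise ConfigError(f"n_regions[{name!r}] must be positive")

    # -- serialization -------------------------------------------------- #

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["months_range"] = list(data["months_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        data = dict(data)
        for key in ("months_range", "outcome_trend", "site_effects"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if isinstance(data.get("n_per_month"), list):
            data["n_per_month"] = tuple(data["n_per_month"])
        return cls(**data)

    def delta_for(self, outcome: str) -> float:
        if isinstance(self.effect_delta, Mapping):
            return float(self.effect_delta.get(outcome, 0.0))
        return float(self.effect_delta)

    @property
    def effect_scale(self) -> float:
        """Outcome units per unit of effect_delta (noise_sd, or 1 if noise-free)."""
        return self.noise_sd if self.noise_sd > 0 else 1.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw one seeded cohort table from the configured process.

    Returns a DataFrame with one row per participant: ``participant_id``,
    ``mdob`` (month of birth relative to the cutoff), ``rosla`` (assignment,
    ``mdob >= 0``), ``stayed16`` (first stage), ``eduyears``, the covariates
    of no interest, and the six global outcomes. Reproducible bit-for-bit
    given the configuration seed.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])

    months = config.months
    counts = config.counts()
    mdob = np.repeat(months, counts)
    n = mdob.size
    rosla = (mdob >= 0).astype(int)

    p_stay = config.compliance_probability(mdob)
    stayed16 = (rng.random(n) < p_stay).astype(int)

    # latent person-level factor (SES-like); confounds education and outcomes
    u = rng.standard_normal(n)

    # education pathway: leave at 15 (10 y) unless stayed; stayers either
    # leave at 16 (11 y), take A-levels (13 y), or complete college (coded 21)
    logit_college = np.log(config.college_rate / (1 - config.college_rate))
    p_college = _sigmoid(logit_college + config.confound_edu_logit * u)
    college = (rng.random(n) < p_college) & (stayed16 == 1)
    alevel = (rng.random(n) < config.alevel_rate) & (stayed16 == 1) & ~college
    eduyears = np.where(stayed16 == 1, 11.0, 10.0)
    eduyears = np.where(alevel, 13.0, eduyears)
    eduyears = np.where(college, 21.0, eduyears)

    # covariates of no interest
    sex = rng.integers(0, 2, n).astype(float)
    month_of_year = ((mdob + 8) % 12) + 1  # month 0 is September
    summer = np.isin(month_of_year, (7, 8)).astype(float)
    dos = rng.integers(0, config.dos_max_days + 1, n).astype(float)
    site = rng.choice(["site1", "site2", "site3"], size=n, p=[0.5, 0.3, 0.2])
    motion = rng.lognormal(mean=0.0, sigma=0.4, size=n)
    t2flair = (rng.random(n) < 0.95).astype(float)

    site_offset = dict(zip(["site1", "site2", "site3"], config.site_effects))
    scale = config.effect_scale
    covar_part = np.zeros(n)
    covar_values = {"sex": sex, "summer": summer, "dos": dos, "dos2": dos**2,
                    "motion": motion, "t2flair": t2flair}
    for name, coef in config.covariate_effects.items():
        if name not in covar_values:
            raise ConfigError(f"covariate_effects refers to unknown covariate {name!r}")
        covar_part += coef * covar_values[name]
    covar_part += np.vectorize(site_offset.__getitem__)(site).astype(float)
    covar_part *= scale

    trend = np.polynomial.polynomial.polyval(mdob, np.asarray(config.outcome_trend, float))
    trend = trend * scale

    shared = rng.standard_normal(n)  # person-level factor shared by outcomes
    rho = config.outcome_correlation
    outcomes = {}
    for name in GLOBAL_OUTCOMES:
        y = trend + covar_part
        y = y + config.delta_for(name) * scale * stayed16
        y = y + config.confound_outcome * scale * u
        if config.noise_sd > 0:
            eps = rng.standard_normal(n)
            y = y + config.noise_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps)
        outcomes[name] = y

    table = pd.DataFrame(
        {
            "participant_id": [f"p{i:06d}" for i in range(n)],
            "mdob": mdob,
            "rosla": rosla,
            "stayed16": stayed16,
            "eduyears": eduyears,
            "sex": sex,
            "summer": summer,
            "dos": dos,
            "dos2": dos**2,
            "site": site,
            "motion": motion,
            "t2flair": t2flair,
            **outcomes,
        }
    )

    if config.missing_covariate_rate > 0:
        for col in MISSINGABLE_COLUMNS:
            mask = rng.random(n) < config.missing_covariate_rate
            if col == "site":
                table.loc[mask, col] = pd.NA
            else:
                table.loc[mask, col] = np.nan

    return table


def _regional_delta(config: CohortConfig, panel: str, count: int) -> np.ndarray:
    spec = config.regional_effect_delta
    if isinstance(spec, Mapping):
        spec = spec.get(panel, 0.0)
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        return np.full(count, float(arr))
    if arr.size != count:
        raise ConfigError(
            f"regional_effect_delta for panel {panel!r} has length {arr.size}, expected {count}"
        )
    return arr


def generate_regional_outcomes(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Append regional outcome panels to an existing cohort.

    Each region shares the cohort's secular trend and (optionally) a
    per-region treatment discontinuity, plus equicorrelated region-specific
    noise: regions within a panel have residual correlation
    ``config.region_correlation``.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 1])
    n = len(cohort)
    mdob = cohort["mdob"].to_numpy()
    stayed16 = cohort["stayed16"].to_numpy()
    scale = config.effect_scale
    trend = np.polynomial.polynomial.polyval(mdob, np.asarray(config.outcome_trend, float)) * scale
    rho = config.region_correlation

    new_cols: dict[str, np.ndarray] = {}
    for panel, count in config.n_regions.items():
        deltas = _regional_delta(config, panel, count)
        shared = rng.standard_normal(n)
        for j in range(count):
            name = f"{panel}_{j + 1:02d}"
            if name in cohort.columns or name in new_cols:
                raise ConfigError(f"duplicate region name {name!r}")
            y = trend + deltas[j] * scale * stayed16
            if config.noise_sd > 0:
                eps = rng.standard_normal(n)
                y = y + config.noise_sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps)
            new_cols[name] = y

    out = pd.concat([cohort, pd.DataFrame(new_cols, index=cohort.index)], axis=1)
    return out


def regional_columns(config: CohortConfig) -> dict[str, list[str]]:
    """Map each regional panel to its column names."""
    return {
        panel: [f"{panel}_{j + 1:02d}" for j in range(count)]
        for panel, count in config.n_regions.items()
    }


def write_cohort(table: pd.DataFrame, path, sep: str | None = None) -> None:
    """Write a cohort as CSV/TSV with header; missing values become empty fields."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table.to_csv(path, sep=sep, index=False, na_rep="")


def read_cohort(path, sep: str | None = None) -> pd.DataFrame:
    """Read a cohort table written by :func:`write_cohort`."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)
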