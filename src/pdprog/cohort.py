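"""Synthetic longitudinal Parkinson's disease cohorts.

Generates long-format participant-visit tables with the statistical
structure the downstream models assume: an ordinal cognitive status
(NCI < MCI < PDD) driven by a cumulative-logit latent model with a
subject random intercept, ten cognitive test scores driven by status and
genotype, a prevalent-cohort visit schedule (1-2 year gaps, 1-8 years of
follow-up), absorbing dementia, and MCAR missingness.  Ground-truth
generator parameters are retained so estimators can be tested for
parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

# Ordinal cognitive status codes, worst last.  PDD is absorbing.
NCI, MCI, PDD = 0, 1, 2
STATUS_LABELS = {NCI: "NCI", MCI: "MCI", PDD: "PDD"}

TEST_COLUMNS = [
    "moca",
    "hvlt_total_recall",
    "hvlt_delayed_recall",
    "hvlt_rdi",
    "tmt_b_minus_a",
    "digit_symbol",
    "letter_number_sequencing",
    "phonemic_fluency",
    "semantic_fluency",
    "jolo",
]

PROFILE_COLUMNS = [
    "site",
    "sex",
    "education_years",
    "onset_age_years",
    "apoe4",
    "gba",
    "mapt_h1",
]

VISIT_COLUMNS = [
    "visit_time_years",
    "age_years",
    "disease_duration_years",
    "ledd_mg",
    "gds15",
]

COLUMNS = ["subject_id"] + PROFILE_COLUMNS + VISIT_COLUMNS + TEST_COLUMNS + ["status"]

# Columns eligible for MCAR masking: per-visit measurements only, never
# identifiers, times, or the outcome.
MASKABLE_COLUMNS = TEST_COLUMNS + ["ledd_mg", "gds15"]

# Higher TMT B-A = worse performance; every other test higher = better.
HIGHER_IS_WORSE = {"tmt_b_minus_a"}

# Per-test generation parameters: status-group means (NCI, MCI, PDD),
# residual SD, subject random-intercept SD, and additive genotype effects
# (GBA carrier, APOE e4 carrier, MAPT H1 homozygote).
_TEST_PARAMS = {
    "moca": ((27.5, 24.6, 19.2), 2.0, 2.53, (-1.75, -0.37, 0.20)),
    "hvlt_total_recall": ((27.3, 21.1, 14.2), 3.5, 3.76, (-1.92, -0.38, 0.58)),
    "hvlt_delayed_recall": ((9.9, 6.6, 3.1), 2.2, 1.97, (-0.67, -0.07, 0.36)),
    "hvlt_rdi": ((10.9, 9.3, 7.2), 1.5, 1.30, (-0.56, 0.00, 0.11)),
    "tmt_b_minus_a": ((38.8, 80.1, 166.9), 40.0, 40.27, (31.47, 4.50, -8.30)),
    "digit_symbol": ((50.6, 38.9, 24.2), 7.5, 8.97, (-4.85, -1.63, 0.27)),
    "letter_number_sequencing": ((11.0, 8.7, 5.6), 1.8, 1.73, (-0.95, -0.11, 0.35)),
    "phonemic_fluency": ((48.3, 38.6, 26.9), 8.0, 9.47, (-1.50, -1.46, -0.05)),
    "semantic_fluency": ((23.3, 18.5, 11.6), 3.5, 4.06, (-1.83, -1.11, 0.10)),
    "jolo": ((13.0, 11.8, 9.8), 1.8, 1.67, (-0.99, -0.44, 0.12)),
}

# Covariates entering the ordinal latent model and their centring values
# (approximate cohort means); centring keeps the prevalence targets
# interpretable as the status distribution of an average participant.
_STATUS_COVARIATES = [
    "age_years",
    "disease_duration_years",
    "sex",
    "apoe4",
    "gba",
    "mapt_h1",
]
_COVARIATE_CENTERS = {
    "age_years": 68.0,
    "disease_duration_years": 9.0,
    "sex": 0.70,
    "apoe4": 0.22,
    "gba": 0.11,
    "mapt_h1": 0.33,
}


def _default_beta() -> dict[str, float]:
    # Per-year log-odds for age and disease duration, log-odds for the
    # binary factors, on the cumulative-logit scale toward worse status.
    return {
        "age_years": 0.18,
        "disease_duration_years": 0.15,
        "sex": 2.92,
        "apoe4": 0.23,
        "gba": 2.72,
        "mapt_h1": -0.21,
    }


def _default_test_effects() -> dict[str, tuple[float, float, float]]:
    return {name: params[3] for name, params in _TEST_PARAMS.items()}


@dataclass
class GeneratorConfig:
    """Ground-truth parameters of a simulated cohort.

    ``prevalence`` is the status distribution of a covariate-average
    subject at their first visit; ``beta`` the true cumulative-logit
    coefficients; ``sigma_b`` the SD of the subject random intercept on
    the latent scale; ``test_effects`` maps each test to its additive
    (GBA, APOE4, MAPT) carrier effects.  ``visit_gap_probs`` gives the
    probability of a 1-, 2-, or 3-year gap between consecutive visits.
    """

    n_subjects: int = 500
    prevalence: tuple[float, float, float] = (0.25, 0.55, 0.20)
    beta: dict[str, float] = field(default_factory=_default_beta)
    test_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_test_effects
    )
    sigma_b: float = 1.5
    test_sigma_b_scale: float = 1.0
    test_noise_scale: float = 1.0
    # status -> measurement couplings; set to 0 for calibration nulls
    test_status_gap_scale: float = 1.0
    ledd_status_effect: float = 130.0
    gds15_status_effect: float = 0.7
    time_trend: float = 0.0
    missingness_rate: float = 0.0
    single_visit_fraction: float = 0.38
    max_follow_up_years: float = 8.0
    visit_gap_probs: tuple[float, float, float] = (0.70, 0.25, 0.05)
    male_fraction: float = 0.70
    apoe4_rate: float = 0.22
    gba_rate: float = 0.11
    mapt_h1_rate: float = 0.33
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        p = np.asarray(self.prevalence, dtype=float)
        if p.shape != (3,) or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("prevalence must be 3 positive values summing to 1")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must be in [0, 1)")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be nonnegative")
        g = np.asarray(self.visit_gap_probs, dtype=float)
        if np.any(g < 0) or abs(g.sum() - 1.0) > 1e-8:
            raise ValueError("visit_gap_probs must be nonnegative and sum to 1")
        unknown = set(self.beta) - set(_STATUS_COVARIATES)
        if unknown:
            raise ValueError(f"unknown beta covariates: {sorted(unknown)}")

    def thresholds(self) -> tuple[float, float]:
        """Cumulative-logit cut-points implied by the prevalence target."""
        p0, p1, _ = self.prevalence
        return float(logit(p0)), float(logit(p0 + p1))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["test_effects"] = {k: list(v) for k, v in self.test_effects.items()}
        return d


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate a long-format cohort table under ``config``.

    Status at each visit is drawn from a cumulative logit
    ``P(Y <= k) = logistic(alpha_k - x'beta - b_i - trend*t)`` and then
    post-processed so that PDD is absorbing.  Test scores are linear in
    status-group means, genotype effects, a per-test subject intercept,
    and Gaussian noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    site = rng.integers(0, 3, size=n)
    sex = (rng.random(n) < config.male_fraction).astype(int)
    education = np.clip(np.round(rng.normal(15.9, 2.5, size=n)), 8, 20)
    onset_age = np.clip(rng.normal(60.0, 10.0, size=n), 30.0, 85.0)
    apoe4 = (rng.random(n) < config.apoe4_rate).astype(int)
    gba = (rng.random(n) < config.gba_rate).astype(int)
    mapt = (rng.random(n) < config.mapt_h1_rate).astype(int)
    # Prevalent cohort: enrolment happens years after motor onset.
    baseline_duration = np.clip(rng.gamma(2.0, 4.0, size=n), 0.0, 35.0)
    b_status = rng.normal(0.0, config.sigma_b, size=n) if config.sigma_b > 0 else np.zeros(n)
    b_tests = {
        name: rng.normal(0.0, config.test_sigma_b_scale * params[2], size=n)
        if config.test_sigma_b_scale > 0
        else np.zeros(n)
        for name, params in _TEST_PARAMS.items()
    }

    single = rng.random(n) < config.single_visit_fraction
    follow_cap = np.where(
        single, 0.0, np.clip(np.round(rng.normal(4.0, 2.0, size=n)), 1.0, config.max_follow_up_years)
    )

    beta = {k: config.beta.get(k, 0.0) for k in _STATUS_COVARIATES}

    # Calibrate thresholds so the *marginal* first-visit status
    # distribution matches the prevalence target: the latent spread from
    # covariates and the random intercept dilates the cumulative-logit
    # cut-points (logistic-normal approximation, exact when the spread
    # is zero).
    x0 = {
        "age_years": onset_age + baseline_duration,
        "disease_duration_years": baseline_duration,
        "sex": sex,
        "apoe4": apoe4,
        "gba": gba,
        "mapt_h1": mapt,
    }
    eta0 = b_status + sum(
        beta[k] * (x0[k] - _COVARIATE_CENTERS[k]) for k in _STATUS_COVARIATES
    )
    eta_mean = float(np.mean(eta0))
    eta_var = float(np.var(eta0))
    dilate = np.sqrt(1.0 + eta_var / 2.89)  # logistic variance / 1.7^2
    a1_t, a2_t = config.thresholds()
    a1 = eta_mean + a1_t * dilate
    a2 = eta_mean + a2_t * dilate

    rows: list[dict] = []
    for i in range(n):
        t = 0.0
        status = None
        while True:
            age = onset_age[i] + baseline_duration[i] + t
            duration = baseline_duration[i] + t
            x = {
                "age_years": age,
                "disease_duration_years": duration,
                "sex": sex[i],
                "apoe4": apoe4[i],
                "gba": gba[i],
                "mapt_h1": mapt[i],
            }
            eta = b_status[i] + config.time_trend * t
            eta += sum(beta[k] * (x[k] - _COVARIATE_CENTERS[k]) for k in _STATUS_COVARIATES)
            u = rng.random()
            if status == PDD:
                new_status = PDD  # absorbing
            else:
                p_le0 = expit(a1 - eta)
                p_le1 = expit(a2 - eta)
                new_status = 0 if u < p_le0 else (1 if u < p_le1 else 2)
            status = new_status

            row = {
                "subject_id": f"S{i:05d}",
                "site": int(site[i]),
                "sex": int(sex[i]),
                "education_years": float(education[i]),
                "onset_age_years": float(onset_age[i]),
                "apoe4": int(apoe4[i]),
                "gba": int(gba[i]),
                "mapt_h1": int(mapt[i]),
                "visit_time_years": float(t),
                "age_years": float(age),
                "disease_duration_years": float(duration),
                "ledd_mg": float(
                    max(0.0, rng.normal(500.0 + config.ledd_status_effect * status, 400.0))
                ),
                "gds15": int(
                    np.clip(
                        np.round(rng.normal(5.4 + config.gds15_status_effect * status, 1.7)),
                        0,
                        15,
                    )
                ),
                "status": int(status),
            }
            for name, (means, noise_sd, _ri_sd, _eff) in _TEST_PARAMS.items():
                g_eff, a_eff, m_eff = config.test_effects.get(name, (0.0, 0.0, 0.0))
                grand = sum(means) / 3.0
                mu = (
                    grand + config.test_status_gap_scale * (means[status] - grand)
                    + g_eff * gba[i]
                    + a_eff * apoe4[i]
                    + m_eff * mapt[i]
                    + b_tests[name][i]
                )
                row[name] = float(mu + rng.normal(0.0, config.test_noise_scale * noise_sd))
            rows.append(row)

            if t >= follow_cap[i]:
                break
            gap = rng.choice((1.0, 2.0, 3.0), p=config.visit_gap_probs)
            if t + gap > config.max_follow_up_years:
                break
            t += gap

    table = pd.DataFrame(rows, columns=COLUMNS)
    if config.missingness_rate > 0:
        table = inject_missingness(
            table, config.missingness_rate, seed=int(rng.integers(0, 2**31 - 1))
        )
    return table


def inject_missingness(
    table: pd.DataFrame,
    rate: float,
    seed: int,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """MCAR-mask a fraction ``rate`` of cells in the maskable columns.

    Status, identifiers, and time fields are never masked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    cols = MASKABLE_COLUMNS if columns is None else list(columns)
    forbidden = {"subject_id", "status", "visit_time_years", "age_years"}
    bad = forbidden & set(cols)
    if bad:
        raise ValueError(f"columns not maskable: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(cols))) < rate
    for j, c in enumerate(cols):
        out.loc[mask[:, j], c] = np.nan
    return out


def first_visits(table: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: the earliest visit."""
    idx = table.groupby("subject_id")["visit_time_years"].idxmin()
    return table.loc[idx.values].reset_index(drop=True)


def summarize_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics by first-visit status group.

    Continuous fields get n, mean, sd, and range; binary fields get
    n and percent.  Groups of size 1 have an undefined sd (NaN, flagged).
    """
    if table.empty:
        raise ValueError("empty cohort table")
    base = first_visits(table)
    continuous = [
        "age_years",
        "education_years",
        "disease_duration_years",
        "ledd_mg",
        "gds15",
    ] + TEST_COLUMNS
    binary = ["sex", "apoe4", "gba", "mapt_h1"]
    rows = []
    for code, label in STATUS_LABELS.items():
        grp = base[base["status"] == code]
        n = len(grp)
        for col in continuous:
            vals = grp[col].dropna()
            rows.append(
                {
                    "group": label,
                    "variable": col,
                    "kind": "continuous",
                    "n": n,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                    "min": float(vals.min()) if len(vals) else np.nan,
                    "max": float(vals.max()) if len(vals) else np.nan,
                    "count": np.nan,
                    "percent": np.nan,
                }
            )
        for col in binary:
            vals = grp[col].dropna()
            count = int(vals.sum()) if len(vals) else 0
            rows.append(
                {
                    "group": label,
                    "variable": col,
                    "kind": "binary",
                    "n": n,
                    "mean": np.nan,
                    "sd": np.nan,
                    "min": np.nan,
                    "max": np.nan,
                    "count": count,
                    "percent": round(100.0 * count / len(vals), 1) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_truth(config: GeneratorConfig, path) -> None:
    """Write the generator's ground-truth parameters as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)


def read_truth(path) -> GeneratorConfig:
    with open(path) as fh:
        d = json.load(fh)
    d["prevalence"] = tuple(d["prevalence"])
    d["visit_gap_probs"] = tuple(d["visit_gap_probs"])
    d["test_effects"] = {k: tuple(v) for k, v in d["test_effects"].items()}
    return GeneratorConfig(**d)
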