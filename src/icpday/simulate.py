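"""Synthetic SAH cohort generator.

Emulates the statistical structure of a first-ICU-day intracranial-pressure
(ICP) monitoring cohort: four latent trajectory archetypes (two low-mean
around 9 mmHg, two high-mean around 19 mmHg, one of the high-mean archetypes
strongly fluctuating), irregular within-hour sampling with occasional
contiguous monitoring dropouts, baseline ICU covariates, and ICU mortality
driven by the first-day mean ICP through a logistic model.

Every quantity is drawn from a :class:`numpy.random.Generator` seeded through
the config, so a fixed seed reproduces the tables bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "simulate_trajectories",
    "simulate_covariates",
    "simulate_outcomes",
    "simulate_cohort",
    "simulate_confounded_binary",
    "ARCHETYPE_NAMES",
]

ARCHETYPE_NAMES = ("I", "II", "III", "IV")

#: trajectory shape template per archetype: flat / slow oscillation / flat /
#: within-day ramp.  Shapes are scaled by the archetype sd so that a zero-sd
#: configuration degenerates to a constant series at the archetype mean.
_SHAPES = ("flat", "osc", "flat", "ramp")

_DAY_HOURS = 24


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Archetype defaults mirror the reference cohort structure: means
    (9, 19, 19, 9) mmHg, proportions (0.62, 0.03, 0.10, 0.25) and a strongly
    fluctuating second archetype.  ``archetype_sds`` set the within-day
    fluctuation scale; the between-subject spread of latent daily means is
    ``jitter_frac`` times the archetype sd.
    """

    n_subjects: int = 400
    archetype_props: tuple[float, float, float, float] = (0.62, 0.03, 0.10, 0.25)
    archetype_means: tuple[float, float, float, float] = (9.0, 19.0, 19.0, 9.0)
    archetype_sds: tuple[float, float, float, float] = (1.0, 6.0, 1.5, 1.5)
    jitter_frac: float = 0.05
    sampling_rate: float = 1.5  # mean measurements per hour
    missing_block_prob: float = 0.10
    # ICU-mortality logistic model on (latent daily mean, age, GCS_min)
    mortality_intercept: float = -3.2
    beta_icpmean: float = 0.15
    beta_age: float = 0.02
    beta_gcs: float = -0.10
    # optional threshold effect: log-odds jump when latent mean exceeds the cut
    icp_step_at: float | None = None
    beta_icp_step: float = 0.0
    censor_time_max: float = 240.0  # hours (10-day ICU horizon)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        props = np.asarray(self.archetype_props, dtype=float)
        if props.shape != (4,) or (props < 0).any() or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("archetype_props must be 4 non-negative values summing to 1")
        sds = np.asarray(self.archetype_sds, dtype=float)
        if sds.shape != (4,) or (sds < 0).any():
            raise ValueError("archetype_sds must be 4 non-negative values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0.0 <= self.missing_block_prob <= 1.0:
            raise ValueError("missing_block_prob must be a probability")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    """Independent per-stage generator derived from the config seed."""
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(stream + 1)[stream])


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    arch = rng.choice(4, size=n, p=np.asarray(config.archetype_props, dtype=float))
    means = np.asarray(config.archetype_means, float)[arch]
    sds = np.asarray(config.archetype_sds, float)[arch]
    latent = means + config.jitter_frac * sds * rng.standard_normal(n)
    intime = pd.Timestamp("2020-01-01 00:00:00") + pd.to_timedelta(
        rng.integers(0, 365 * 24 * 60, size=n), unit="m"
    )
    return pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "archetype": [ARCHETYPE_NAMES[a] for a in arch],
            "archetype_idx": arch,
            "latent_mean": latent,
            "icu_intime": intime,
        }
    )


def _trajectory(t: np.ndarray, latent_mean: float, sd: float, shape: str,
                rng: np.random.Generator) -> np.ndarray:
    """Latent ICP value at hours-from-admission ``t`` for one subject.

    Archetype shape (a coherent 12-h oscillation for the high-variance
    archetype, a within-day ramp for the second low-mean archetype) plus a
    low-order random smooth drift and i.i.d. measurement noise; every term
    scales with the archetype sd so a zero-sd configuration is constant.
    """
    phase = rng.uniform(0, 2 * np.pi, size=2)
    amp = 0.05 * sd * rng.standard_normal(2)  # low-order random smooth drift
    x = latent_mean + amp[0] * np.sin(2 * np.pi * t / _DAY_HOURS + phase[0])
    x = x + amp[1] * np.sin(4 * np.pi * t / _DAY_HOURS + phase[1])
    if shape == "osc":
        x = x + 1.5 * sd * np.sin(2 * np.pi * t / 12.0)
    elif shape == "ramp":
        x = x + 2.5 * sd * (t - _DAY_HOURS / 2) / (_DAY_HOURS / 2)
    return x + 0.06 * sd * rng.standard_normal(t.size)


def simulate_trajectories(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate irregular first-day ICP chart events.

    Returns ``(chartevents, truth)``.  ``chartevents`` has columns
    ``subject_id, charttime, icp_mmHg``; all timestamps fall inside each
    subject's 24-hour window from ICU admission.  ``truth`` carries the
    planted archetype label and latent daily mean per subject.

    Event times arrive as a homogeneous Poisson stream (``sampling_rate``
    events/hour); with probability ``missing_block_prob`` a subject loses a
    contiguous block of 4-9 hours, so blocks longer than 6 h occur and
    exercise the downstream monitoring-gap exclusion rule.
    """
    truth = _draw_truth(config, _rng(config, 0))
    rng = _rng(config, 1)

    rows: list[pd.DataFrame] = []
    for rec in truth.itertuples(index=False):
        counts = rng.poisson(config.sampling_rate, size=_DAY_HOURS)
        times = np.sort(
            np.concatenate(
                [h + np.sort(rng.uniform(0, 1, size=c)) for h, c in enumerate(counts)]
            )
            if counts.sum()
            else np.empty(0)
        )
        if rng.uniform() < config.missing_block_prob:
            length = int(rng.integers(4, 10))
            start = int(rng.integers(0, _DAY_HOURS - length + 1))
            times = times[(times < start) | (times >= start + length)]
        if times.size == 0:
            continue
        sd = config.archetype_sds[rec.archetype_idx]
        values = _trajectory(times, rec.latent_mean, sd, _SHAPES[rec.archetype_idx], rng)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "charttime": rec.icu_intime + pd.to_timedelta(times, unit="h"),
                    "icp_mmHg": values,
                }
            )
        )
    events = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["subject_id", "charttime", "icp_mmHg"]
    )
    return events, truth.drop(columns="archetype_idx")


def simulate_covariates(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Baseline ICU covariates from simple parametric distributions.

    Age ~ N(58.8, 14.5) clipped to [18, 95]; gender Bernoulli(0.58 female);
    GCS_min categorical skewed toward severe grades; APS III, OASIS, SOFA
    normal with cohort-typical moments; first-day fluid balance increases
    weakly with the latent daily ICP mean.
    """
    rng = _rng(config, 2)
    n = len(truth)
    age = np.clip(rng.normal(58.8, 14.5, n), 18, 95)
    gender = np.where(rng.uniform(size=n) < 0.58, "F", "M")
    bands = rng.choice(4, size=n, p=(0.06, 0.14, 0.38, 0.42))
    gcs = np.select(
        [bands == 0, bands == 1, bands == 2, bands == 3],
        [15, rng.integers(13, 15, n), rng.integers(7, 13, n), rng.integers(3, 7, n)],
    )
    apsiii = np.clip(rng.normal(52.8, 22.6, n), 0, None)
    oasis = np.clip(rng.normal(37.6, 7.7, n), 0, None)
    sofa = np.clip(np.round(rng.normal(5.2, 2.7, n)), 0, 24)
    fluid = 400.0 + 50.0 * truth["latent_mean"].to_numpy() + rng.normal(0, 1000, n)
    return pd.DataFrame(
        {
            "subject_id": truth["subject_id"].to_numpy(),
            "age": age,
            "gender": gender,
            "gcs_min": gcs.astype(int),
            "apsiii": apsiii,
            "oasis": oasis,
            "sofa": sofa,
            "fluid_balance_ml": fluid,
        }
    )


def simulate_outcomes(
    truth: pd.DataFrame, covariates: pd.DataFrame, config: SimConfig
) -> pd.DataFrame:
    """ICU mortality and follow-up times for the simulated cohort.

    Death is Bernoulli with log-odds linear in the latent daily ICP mean, age
    and GCS_min (plus an optional threshold jump at ``icp_step_at``).  Deaths
    get an event time uniform on (0, ``censor_time_max``); survivors are
    censored at ICU discharge (24 h minimum stay plus an exponential tail).
    """
    if not truth["subject_id"].equals(covariates["subject_id"]):
        raise ValueError("truth and covariates must cover the same subjects in order")
    rng = _rng(config, 3)
    n = len(truth)
    mean_icp = truth["latent_mean"].to_numpy()
    eta = (
        config.mortality_intercept
        + config.beta_icpmean * mean_icp
        + config.beta_age * covariates["age"].to_numpy()
        + config.beta_gcs * covariates["gcs_min"].to_numpy()
    )
    if config.icp_step_at is not None:
        eta = eta + config.beta_icp_step * (mean_icp > config.icp_step_at)
    p = 1.0 / (1.0 + np.exp(-eta))
    death = rng.uniform(size=n) < p
    t_death = rng.uniform(0, config.censor_time_max, size=n)
    t_disch = np.minimum(24.0 + rng.exponential(96.0, size=n), config.censor_time_max)
    time = np.where(death, t_death, t_disch)
    out = covariates.copy()
    out["icu_death"] = death.astype(int)
    out["time_hours"] = time
    out["icu_intime"] = truth["icu_intime"].to_numpy()
    out["icu_outtime"] = out["icu_intime"] + pd.to_timedelta(time, unit="h")
    return out


def simulate_cohort(config: SimConfig) -> dict[str, pd.DataFrame]:
    """Full synthetic study: chart events, truth, covariate/outcome table."""
    events, truth = simulate_trajectories(config)
    cov = simulate_covariates(truth, config)
    cohort = simulate_outcomes(truth, cov, config)
    return {"chartevents": events, "cohort": cohort, "truth": truth}


def simulate_confounded_binary(
    n: int,
    log_or: float,
    seed: int,
    confounding: float = 0.8,
    intercept: float = -1.0,
) -> pd.DataFrame:
    """Confounded binary treatment/outcome cohort for weighting studies.

    Two standard-normal covariates ``x1, x2`` drive both treatment assignment
    (log-odds ``confounding * (x1 + x2)``) and the outcome (log-odds
    ``intercept + log_or * T + 0.5 x1 + 0.5 x2``).  Returns the frame with the
    true propensity score and both potential-outcome probabilities, so the
    true marginal estimand is computable from the sample.
    """
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    ps = 1.0 / (1.0 + np.exp(-confounding * (x1 + x2)))
    t = (rng.uniform(size=n) < ps).astype(int)
    eta0 = intercept + 0.5 * x1 + 0.5 * x2
    p1 = 1.0 / (1.0 + np.exp(-(eta0 + log_or)))
    p0 = 1.0 / (1.0 + np.exp(-eta0))
    p = np.where(t == 1, p1, p0)
    y = (rng.uniform(size=n) < p).astype(int)
    return pd.DataFrame(
        {"x1": x1, "x2": x2, "treatment": t, "outcome": y,
         "true_ps": ps, "p_treated": p1, "p_control": p0}
    )
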