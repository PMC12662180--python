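"""Synthetic panel cohorts with known ground truth.

Emulates the structure of the aging-cohort panels the analysis assumes:
three biennial symptom-assessment waves, bounded integer scores with
person-level heterogeneity and drift, a covariate mix with marginals
typical of these aging cohorts, and
dementia event times drawn from an exponential-baseline proportional-hazards
model whose linear predictor applies user-specified true log hazard ratios
to each participant's *derived* exposures (CumDS, CumADS, per-SD z-scores,
high-symptom duration categories) and covariates. Because the event model
is exactly proportional hazards in those derived quantities, the generator
doubles as the oracle for parameter-recovery tests: the downstream Cox
stage should recover the configured coefficients up to Monte-Carlo error.

Latent trajectories are person-intercept + person-slope * t + noise,
rounded half-away-from-zero and clipped to the scale range. Exposures are
treated as fixed (baseline) covariates from the time origin, matching the
analytic treatment of cumulative exposure. Identical seed implies
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import exposures as expo
from .classify import compute_norms
from .scales import CESD8, CESD10, EUROD, DepressionScale

EDU_LEVELS = ("below_hs", "hs", "college")

#: exposure terms the hazard model understands, beyond raw covariate columns
EXPOSURE_TERMS = ("cumds", "cumads", "cumads_z", "duration_2y", "duration_4y",
                  "burden_nonneg", "slope_nonneg")

COVARIATE_COLS = [
    "age", "female", "married", "urban", "edu_hs", "edu_college",
    "smoke_former", "smoke_current", "drinking", "bmi", "sbp", "dbp",
    "crp", "hba1c", "tc", "hdl", "hypertension", "diabetes",
    "heart_disease", "stroke",
]


@dataclass
class SimulationConfig:
    """Generator settings; defaults mirror a biennial three-wave cohort."""

    n_participants: int = 2000
    scale: DepressionScale = CESD8
    n_waves: int = 3
    wave_spacing_years: float = 2.0
    # latent trajectory: intercept + slope * t + noise
    intercept_mean: float = 1.3
    intercept_sd: float = 1.3
    slope_mean: float = 0.05
    slope_sd: float = 0.15
    noise_sd: float = 0.9
    # demographics
    age_mean: float = 65.0
    age_sd: float = 8.0
    min_age: float = 50.0
    covariate_mix: dict = field(default_factory=dict)
    # hazard model
    true_loghr: dict = field(default_factory=dict)
    baseline_hazard: float = 0.008
    censoring_years: float = 10.8
    # derived-exposure settings used when duration/burden terms enter the hazard
    duration_window: tuple[int, int] = (0, 1)
    cutoff: float | None = None  # defaults to the scale screening threshold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_waves < 3:
            raise ValueError("need at least 3 assessment waves")
        for sd in (self.intercept_sd, self.slope_sd, self.noise_sd, self.age_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        window = (self.n_waves - 1) * self.wave_spacing_years
        if self.censoring_years <= window:
            raise ValueError("censoring time must exceed the exposure window")
        for key in self.true_loghr:
            if key not in EXPOSURE_TERMS and key not in COVARIATE_COLS:
                raise ValueError(f"unknown hazard term {key!r}")


@dataclass
class Cohort:
    """A simulated cohort: long-format panel plus participant-level table.

    `panel` has one row per participant-wave (id, wave, wave_time, score,
    education, and - after `simulate_cognition_adl` - cognition/ADL columns).
    `participants` has one row per participant with covariates and the
    survival outcome (time, event, event_wave).
    """

    panel: pd.DataFrame
    participants: pd.DataFrame
    config: SimulationConfig


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


# marginal mix typical of aging cohorts; override via SimulationConfig.covariate_mix
_DEFAULT_MIX = {
    "female": 0.55, "married": 0.70, "urban": 0.75,
    "education": (0.35, 0.35, 0.30),       # below hs / hs / college
    "smoking": (0.50, 0.30, 0.20),         # never / former / current
    "drinking": 0.50, "hypertension": 0.42, "diabetes": 0.13,
    "heart_disease": 0.17, "stroke": 0.04,
}


def _draw_covariates(n: int, cfg: SimulationConfig, rng) -> pd.DataFrame:
    mix = {**_DEFAULT_MIX, **cfg.covariate_mix}
    edu = rng.choice(3, size=n, p=mix["education"])
    smoke = rng.choice(3, size=n, p=mix["smoking"])
    df = pd.DataFrame(
        {
            "age": np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n),
                           cfg.min_age, 95.0),
            "female": (rng.random(n) < mix["female"]).astype(int),
            "married": (rng.random(n) < mix["married"]).astype(int),
            "urban": (rng.random(n) < mix["urban"]).astype(int),
            "edu_level": edu,
            "education": np.array(EDU_LEVELS)[edu],
            "edu_hs": (edu == 1).astype(int),
            "edu_college": (edu == 2).astype(int),
            "smoke_former": (smoke == 1).astype(int),
            "smoke_current": (smoke == 2).astype(int),
            "drinking": (rng.random(n) < mix["drinking"]).astype(int),
            "bmi": rng.normal(27.0, 4.5, n),
            "sbp": rng.normal(130.0, 16.0, n),
            "dbp": rng.normal(78.0, 10.0, n),
            "crp": np.exp(rng.normal(0.4, 0.8, n)),
            "hba1c": rng.normal(5.8, 0.7, n),
            "tc": rng.normal(5.2, 1.1, n),
            "hdl": rng.normal(1.4, 0.35, n),
            "hypertension": (rng.random(n) < mix["hypertension"]).astype(int),
            "diabetes": (rng.random(n) < mix["diabetes"]).astype(int),
            "heart_disease": (rng.random(n) < mix["heart_disease"]).astype(int),
            "stroke": (rng.random(n) < mix["stroke"]).astype(int),
        }
    )
    return df


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort with event times from the configured hazard model.

    Continuous exposure terms (cumds/cumads and covariates such as age) are
    mean-centered inside the linear predictor; centering is absorbed by the
    baseline hazard and does not change the hazard ratios being recovered.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    scale = cfg.scale
    cutoff = scale.high_threshold if cfg.cutoff is None else cfg.cutoff

    wave_times = np.arange(cfg.n_waves) * cfg.wave_spacing_years
    intercepts = rng.normal(cfg.intercept_mean, cfg.intercept_sd, n)
    slopes = rng.normal(cfg.slope_mean, cfg.slope_sd, n)
    noise = rng.normal(0.0, cfg.noise_sd, (n, cfg.n_waves))
    latent = intercepts[:, None] + slopes[:, None] * wave_times[None, :] + noise
    scores = np.clip(_round_half_away(latent), scale.min_score, scale.max_score)

    participants = _draw_covariates(n, cfg, rng)
    participants.insert(0, "id", np.arange(n))

    # derived exposures entering the hazard
    cumds = np.trapezoid(scores, wave_times, axis=1)
    span = wave_times[-1] - wave_times[0]
    cumads = cumds / span
    high = scores[:, list(cfg.duration_window)] >= cutoff
    duration = 2.0 * high.sum(axis=1)
    sd_ads = np.std(cumads, ddof=1)
    terms = {
        "cumds": cumds - cumds.mean(),
        "cumads": cumads - cumads.mean(),
        "cumads_z": (cumads - cumads.mean()) / sd_ads if sd_ads > 0 else np.zeros(n),
        "duration_2y": (duration == 2.0).astype(float),
        "duration_4y": (duration == 4.0).astype(float),
        "burden_nonneg": (cumds - cutoff * span >= 0).astype(float),
        "slope_nonneg": (slopes >= 0).astype(float),
    }

    eta = np.zeros(n)
    for key, beta in cfg.true_loghr.items():
        if key in terms:
            x = terms[key]
        else:
            x = participants[key].to_numpy(dtype=float)
            x = x - x.mean()
        eta += beta * x

    rate = cfg.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rate)
    window = (cfg.n_waves - 1) * cfg.wave_spacing_years
    if np.mean(t_event <= window) > 0.99:
        raise ValueError(
            "degenerate configuration: >99% of subjects fail inside the "
            "exposure window"
        )
    event = (t_event <= cfg.censoring_years).astype(int)
    time = np.minimum(t_event, cfg.censoring_years)

    # wave at which an algorithmic classifier would first see the event:
    # first assessment at or after onset, clamped to the final wave
    event_wave = np.full(n, -1)
    for w in range(cfg.n_waves - 1, -1, -1):
        event_wave[t_event <= wave_times[w]] = w + 1
    event_wave[(event == 1) & (event_wave == -1)] = cfg.n_waves
    event_wave = np.where(event == 1, np.maximum(event_wave, 2), 0)

    participants["time"] = time
    participants["event"] = event
    participants["event_wave"] = np.where(event == 1, event_wave, np.nan)

    panel = pd.DataFrame(
        {
            "id": np.repeat(np.arange(n), cfg.n_waves),
            "wave": np.tile(np.arange(1, cfg.n_waves + 1), n),
            "wave_time": np.tile(wave_times, n),
            "score": scores.ravel(),
        }
    )
    panel = panel.merge(participants[["id", "education"]], on="id")
    return Cohort(panel=panel, participants=participants, config=cfg)


def simulate_cognition_adl(
    cohort: Cohort,
    noise_sd: float = 0.0,
    self_report_rate: float = 0.0,
) -> Cohort:
    """Fill cognition, ADL and self-report columns consistent with outcomes.

    Baseline cognitive scores are drawn with education-graded means; norms
    are then computed from that baseline wave (exactly as the classifier
    does), and impairment is planted *relative to those realized norms*:
    participants flagged as events receive, at and after their event wave,
    a memory score 2.5 SD below their stratum mean, a cognition composite
    <= 6, and one ADL difficulty; non-events keep composites >= 7 and zero
    ADL difficulties throughout, so a zero-noise cohort classifies with
    sensitivity and specificity 1.
    """
    cfg = cohort.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    parts = cohort.participants
    n = len(parts)
    W = cfg.n_waves
    edu = parts["edu_level"].to_numpy()

    memory0 = np.clip(rng.normal(10.0 + edu, 2.0, n), 2.0, 20.0)
    orient0 = np.clip(rng.normal(3.4 + 0.15 * edu, 0.5, n), 0.0, 4.0)
    execu0 = np.clip(rng.normal(3.5 + 0.5 * edu, 1.2, n), 1.0, 7.0)

    base = pd.DataFrame(
        {
            "id": parts["id"], "wave": 1, "education": parts["education"],
            "memory": memory0, "orientation": orient0, "executive": execu0,
        }
    )
    norms = compute_norms(base, wave_col="wave", baseline_wave=1)

    mem = np.repeat(memory0[:, None], W, axis=1)
    ori = np.repeat(orient0[:, None], W, axis=1)
    exe = np.repeat(execu0[:, None], W, axis=1)
    if noise_sd > 0:
        mem[:, 1:] += rng.normal(0, noise_sd, (n, W - 1))
        ori[:, 1:] += rng.normal(0, noise_sd, (n, W - 1))
        exe[:, 1:] += rng.normal(0, noise_sd, (n, W - 1))
    adl = np.zeros((n, W), dtype=int)
    selfrep = np.zeros((n, W), dtype=bool)

    ev = parts["event"].to_numpy() == 1
    ew = parts["event_wave"].to_numpy()
    for i in np.flatnonzero(ev):
        w0 = int(ew[i]) - 1
        mean, sd = norms.get(parts["education"].iloc[i], "memory")
        low = max(0.0, mean - 2.5 * sd)
        mem[i, w0:] = min(low, 5.5)
        exe[i, w0:] = 0.5
        adl[i, w0:] = 1
        if self_report_rate > 0 and rng.random() < self_report_rate:
            selfrep[i, w0:] = True
    # keep non-event composites clear of the summary-score cut
    nonev = ~ev
    comp = mem + exe
    bump = np.where(comp < 7.5, 7.5 - comp, 0.0)
    mem[nonev] += bump[nonev]

    panel = cohort.panel.copy()
    order = panel.sort_values(["id", "wave"]).index
    panel.loc[order, "memory"] = mem.ravel()
    panel.loc[order, "orientation"] = ori.ravel()
    panel.loc[order, "executive"] = exe.ravel()
    panel.loc[order, "adl"] = adl.ravel()
    panel.loc[order, "self_report"] = selfrep.ravel()
    panel["adl"] = panel["adl"].astype(int)
    panel["self_report"] = panel["self_report"].astype(bool)
    panel["cog_summary"] = np.clip(panel["memory"] + panel["executive"], 0, 27)
    return Cohort(panel=panel, participants=parts, config=cfg)


def cohort_preset(name: str, **overrides) -> SimulationConfig:
    """Named presets matching the symptom scales' typical prevalence.

    "cesd8" (ELSA/HRS-like, ~18-21% elevated), "eurod" (SHARE-like, ~23%),
    "cesd10" (CHARLS-like, ~32%). Keyword overrides are applied on top.
    """
    presets = {
        "cesd8": SimulationConfig(scale=CESD8, intercept_mean=1.3,
                                  intercept_sd=1.3, noise_sd=0.9),
        "eurod": SimulationConfig(scale=EUROD, intercept_mean=2.3,
                                  intercept_sd=1.5, noise_sd=1.0),
        "cesd10": SimulationConfig(scale=CESD10, intercept_mean=7.8,
                                   intercept_sd=4.0, noise_sd=2.0,
                                   age_mean=57.0, min_age=45.0),
    }
    try:
        base = presets[name.lower()]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; expected one of {sorted(presets)}")
    return replace(base, **overrides)
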