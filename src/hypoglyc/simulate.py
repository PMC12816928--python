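"""Synthetic CGM cohort generator with known ground truth.

Because no clinical recordings are distributed with this package, every
downstream stage is exercised on simulated cohorts whose structure is fully
specified and therefore recoverable. Each subject has covariates (age, BMI
truncated below 18.5 kg/m², illness duration, eating-disorder-inventory total
score) drawn from truncated normals, and a glucose trace on the nominal
15-minute grid built from:

* a subject-level mean ``mu = a0 + a1*illness_duration + a2*edi2_total + d``,
  where ``d`` is a subject random intercept with SD ``subject_sd`` — the
  between-subject variability against which an embedded duration effect has
  to be detected;
* a circadian sinusoid (afternoon peak, small-hours trough);
* exponentially decaying post-meal excursions at fixed clock times;
* stationary AR(1) sensor/physiology noise;
* sporadic hypoglycaemic dips (half-sine depressions) at a Poisson rate,

with glucose floored at a physiological minimum of 40 mg/dL. Missingness is
applied afterwards as i.i.d. point dropouts plus contiguous dropout blocks.

The sensor starts in the early afternoon (13:30 by default), so day 0 and the
final day are partial and typically fail the 80%-completeness rule, mirroring
real wear schedules.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

from .io import SensorTrace, SubjectRecord
from .qc import ConfigurationError, _parse_clock


class CalibrationError(RuntimeError):
    """Raised when a target correlation is unreachable under the config."""


@dataclass(frozen=True)
class TruncNormal:
    """A truncated normal distribution: N(mean, sd) restricted to [min, max]."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError("sd must be non-negative")
        if self.min > self.max:
            raise ConfigurationError(
                f"invalid bounds: min {self.min} > max {self.max}"
            )
        if self.sd == 0 and not self.min <= self.mean <= self.max:
            raise ConfigurationError(
                "degenerate distribution (sd=0) needs mean within [min, max]"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        a = (self.min - self.mean) / self.sd
        b = (self.max - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


def _dist(mean, sd, lo, hi):
    return lambda: TruncNormal(mean, sd, lo, hi)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults describe a plausible underweight adult outpatient cohort wearing
    a 15-min CGM sensor for five days from ~13:30 of day 0. Glucose units are
    mg/dL, durations in the units named by each field.
    """

    n_subjects: int = 300
    seed: int = 0
    wear_days: float = 5.0
    wear_days_sd: float = 0.0          # per-subject wear jitter (days)
    sensor_start_clock: dt.time = dt.time(13, 30)
    start_date: dt.date = dt.date(2024, 1, 1)
    sampling_min: int = 15
    # covariates
    age: TruncNormal = field(default_factory=_dist(25.0, 6.0, 18.0, 55.0))
    bmi: TruncNormal = field(default_factory=_dist(16.2, 1.3, 11.0, 18.49))
    illness_duration: TruncNormal = field(default_factory=_dist(8.0, 6.0, 0.25, 30.0))
    edi2_total: TruncNormal = field(default_factory=_dist(110.0, 40.0, 5.0, 250.0))
    # latent glucose model
    baseline_mean: float = 82.0        # a0, mg/dL
    adaptation_slope: float = 0.35     # a1, mg/dL per illness-duration year
    edi_slope: float = -0.02           # a2, mg/dL per EDI-2 point
    subject_sd: float = 6.0            # between-subject intercept SD, mg/dL
    circadian_amplitude: float = 5.0   # mg/dL; peak 14:00, trough 02:00
    meal_times: tuple = (dt.time(8, 0), dt.time(12, 30), dt.time(19, 30))
    meal_amplitude: float = 25.0       # mg/dL at meal onset
    meal_decay_min: float = 90.0       # exponential decay constant, minutes
    ar_coefficient: float = 0.7        # AR(1) coefficient, in [0, 1)
    noise_sd: float = 8.0              # stationary noise SD, mg/dL
    hypo_dip_rate: float = 0.5         # dips per day (Poisson)
    hypo_dip_depth: float = 25.0       # dip depth at nadir, mg/dL
    hypo_dip_duration_min: float = 60.0
    glucose_floor: float = 40.0        # physiological floor, mg/dL
    # missingness
    dropout_point_prob: float = 0.02
    dropout_block_rate: float = 0.3    # blocks per day (Poisson)
    dropout_block_min: float = 120.0   # block length, minutes

    def __post_init__(self) -> None:
        self.sensor_start_clock = _parse_clock(self.sensor_start_clock)
        if isinstance(self.start_date, str):
            self.start_date = dt.date.fromisoformat(self.start_date)
        self.meal_times = tuple(_parse_clock(t) for t in self.meal_times)
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be at least 1")
        if self.sampling_min <= 0:
            raise ConfigurationError("sampling_min must be positive")
        if self.wear_days <= 0 or self.wear_days_sd < 0:
            raise ConfigurationError("wear_days must be positive, jitter >= 0")
        if not 0 <= self.ar_coefficient < 1:
            raise ConfigurationError("ar_coefficient must be in [0, 1)")
        for name in ("noise_sd", "subject_sd", "circadian_amplitude",
                     "meal_amplitude", "hypo_dip_depth", "hypo_dip_rate",
                     "dropout_block_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0 <= self.dropout_point_prob <= 1:
            raise ConfigurationError("dropout_point_prob must be in [0, 1]")
        if self.bmi.max >= 18.5:
            raise ConfigurationError("BMI distribution must be truncated below 18.5")

    # -- latent model -----------------------------------------------------
    def latent_mean(self, record: SubjectRecord) -> float:
        """Fixed part of the subject's latent mean glycaemia (mg/dL)."""
        return (self.baseline_mean
                + self.adaptation_slope * record.illness_duration
                + self.edi_slope * record.edi2_total)

    def grid_size(self, wear_days: float | None = None) -> int:
        wear = self.wear_days if wear_days is None else wear_days
        return int(round(wear * 1440.0 / self.sampling_min))

    def grid_minutes(self) -> np.ndarray:
        """Sample times in minutes since midnight of day 0, full wear."""
        start = self.sensor_start_clock.hour * 60 + self.sensor_start_clock.minute
        return start + np.arange(self.grid_size()) * float(self.sampling_min)

    def ground_truth(self) -> dict:
        """Latent parameters recorded alongside simulated cohorts."""
        return {
            "baseline_mean": self.baseline_mean,
            "adaptation_slope": self.adaptation_slope,
            "edi_slope": self.edi_slope,
            "subject_sd": self.subject_sd,
            "noise_sd": self.noise_sd,
            "ar_coefficient": self.ar_coefficient,
            "circadian_amplitude": self.circadian_amplitude,
            "meal_amplitude": self.meal_amplitude,
            "meal_decay_min": self.meal_decay_min,
            "hypo_dip_rate": self.hypo_dip_rate,
            "hypo_dip_depth": self.hypo_dip_depth,
            "dropout_point_prob": self.dropout_point_prob,
            "dropout_block_rate": self.dropout_block_rate,
            "dropout_block_min": self.dropout_block_min,
            "wear_days": self.wear_days,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
        }


# ---------------------------------------------------------------------------
# covariates

def sample_covariates(config: GeneratorConfig,
                      rng: np.random.Generator) -> list[SubjectRecord]:
    """Draw the cohort's covariate records (reproducible given the rng)."""
    n = config.n_subjects
    if n < 1:
        raise ConfigurationError("n_subjects must be at least 1")
    age = config.age.sample(n, rng)
    bmi = config.bmi.sample(n, rng)
    duration = config.illness_duration.sample(n, rng)
    edi2 = config.edi2_total.sample(n, rng)
    width = max(4, len(str(n)))
    return [
        SubjectRecord(
            subject_id=f"S{i + 1:0{width}d}",
            age=float(age[i]),
            bmi=float(bmi[i]),
            illness_duration=float(duration[i]),
            edi2_total=float(edi2[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# glucose traces

def _deterministic_profile(config: GeneratorConfig) -> np.ndarray:
    """Circadian + meal components on the full grid (same for all subjects)."""
    t = config.grid_minutes()
    hours = (t % 1440.0) / 60.0
    profile = config.circadian_amplitude * np.cos(2 * np.pi * (hours - 14.0) / 24.0)
    if config.meal_amplitude > 0:
        n_days = int(np.ceil(t[-1] / 1440.0)) + 1
        for day in range(n_days):
            for meal in config.meal_times:
                m = day * 1440.0 + meal.hour * 60 + meal.minute
                after = t >= m
                profile[after] += config.meal_amplitude * np.exp(
                    -(t[after] - m) / config.meal_decay_min
                )
    return profile


def _ar1_noise(config: GeneratorConfig, shape: tuple[int, int],
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``noise_sd``."""
    if config.noise_sd == 0:
        return np.zeros(shape)
    a = config.ar_coefficient
    innov = rng.normal(0.0, config.noise_sd * np.sqrt(1 - a * a), size=shape)
    innov[:, 0] = rng.normal(0.0, config.noise_sd, size=shape[0])
    if a == 0:
        return innov
    return signal.lfilter([1.0], [1.0, -a], innov, axis=1)


def _apply_dips(glucose: np.ndarray, t: np.ndarray, config: GeneratorConfig,
                rng: np.random.Generator) -> None:
    """Subtract half-sine hypoglycaemic dips, in place, row per subject."""
    if config.hypo_dip_rate == 0 or config.hypo_dip_depth == 0:
        return
    span = t[-1] - t[0]
    width = config.hypo_dip_duration_min
    counts = rng.poisson(config.hypo_dip_rate * span / 1440.0, size=glucose.shape[0])
    for i, k in enumerate(counts):
        if k == 0:
            continue
        centers = rng.uniform(t[0], t[-1], size=k)
        for c in centers:
            near = np.abs(t - c) < width / 2.0
            phase = (t[near] - c + width / 2.0) / width
            glucose[i, near] -= config.hypo_dip_depth * np.sin(np.pi * phase)


def _simulate_glucose_matrix(mu: np.ndarray, config: GeneratorConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """Glucose matrix (n_subjects × grid) for given latent means ``mu``."""
    t = config.grid_minutes()
    g = mu[:, None] + _deterministic_profile(config)[None, :]
    g = g + _ar1_noise(config, (mu.size, t.size), rng)
    _apply_dips(g, t, config, rng)
    np.maximum(g, config.glucose_floor, out=g)
    return g


def simulate_trace(subject: SubjectRecord, config: GeneratorConfig,
                   rng: np.random.Generator) -> SensorTrace:
    """Simulate one subject's gap-free trace on the nominal grid.

    The subject's latent mean is the config's linear model plus a random
    intercept drawn here; per-subject wear time is ``wear_days`` jittered by
    ``wear_days_sd`` (truncated to [1, wear_days] — sensors fail early, not
    late).
    """
    wear = config.wear_days
    if config.wear_days_sd > 0:
        wear = float(np.clip(rng.normal(wear, config.wear_days_sd),
                             1.0, config.wear_days))
    mu = config.latent_mean(subject)
    if config.subject_sd > 0:
        mu += rng.normal(0.0, config.subject_sd)
    glucose = _simulate_glucose_matrix(np.array([mu]), config, rng)[0]
    n = min(config.grid_size(wear), glucose.size)
    start = np.datetime64(
        f"{config.start_date.isoformat()}T"
        f"{config.sensor_start_clock.strftime('%H:%M')}:00", "s"
    )
    times = start + (np.arange(n) * config.sampling_min * 60).astype("timedelta64[s]")
    return SensorTrace(subject.subject_id, times, glucose[:n],
                       nominal_interval=config.sampling_min)


def apply_missingness(trace: SensorTrace, config: GeneratorConfig,
                      rng: np.random.Generator) -> SensorTrace:
    """Thin a trace with i.i.d. point dropouts and contiguous dropout blocks.

    Surviving samples keep their timestamps; nothing is imputed.
    """
    n = trace.n_samples
    if n == 0:
        return trace
    keep = np.ones(n, dtype=bool)
    if config.dropout_point_prob > 0:
        keep &= rng.random(n) >= config.dropout_point_prob
    if config.dropout_block_rate > 0:
        span_min = (trace.times[-1] - trace.times[0]).astype(
            "timedelta64[s]").astype(float) / 60.0
        k = rng.poisson(config.dropout_block_rate * span_min / 1440.0)
        if k:
            offsets = (trace.times - trace.times[0]).astype(
                "timedelta64[s]").astype(float) / 60.0
            starts = rng.uniform(0.0, span_min, size=k)
            for s in starts:
                keep &= ~((offsets >= s) & (offsets < s + config.dropout_block_min))
    return SensorTrace(trace.subject_id, trace.times[keep], trace.glucose[keep],
                       trace.nominal_interval)


# ---------------------------------------------------------------------------
# cohort-level entry points

def generate_cohort(config: GeneratorConfig
                    ) -> tuple[list[SubjectRecord], list[SensorTrace]]:
    """Generate the full cohort: covariates and post-missingness traces.

    A single seed drives everything; each subject's covariates, trace and
    missingness are drawn from that subject's own deterministic substream, so
    a subject does not depend on how many others are generated around them.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects)
    width = max(4, len(str(config.n_subjects)))
    one = replace(config, n_subjects=1)
    records = []
    traces = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        (record,) = sample_covariates(one, rng)
        record = replace(record, subject_id=f"S{i + 1:0{width}d}")
        trace = simulate_trace(record, config, rng)
        traces.append(apply_missingness(trace, config, rng))
        records.append(record)
    return records, traces


def simulate_subject_means(records: list[SubjectRecord], config: GeneratorConfig,
                           rng: np.random.Generator) -> np.ndarray:
    """Vectorised per-subject mean glycaemia over the full wear.

    Runs the same generative model as :func:`simulate_trace` (fixed wear, no
    missingness) for a whole cohort at once and returns each subject's trace
    mean. Used for Monte-Carlo calibration and large replicate studies where
    per-subject day-level QC is not the quantity under test.
    """
    mu = np.array([config.latent_mean(r) for r in records])
    if config.subject_sd > 0:
        mu = mu + rng.normal(0.0, config.subject_sd, size=mu.size)
    g = _simulate_glucose_matrix(mu, config, rng)
    return g.mean(axis=1)


def calibrate_adaptation_slope(config: GeneratorConfig, target_rho: float,
                               n_cal: int = 2000,
                               rng: np.random.Generator | None = None,
                               tol: float = 0.01,
                               max_slope: float = 10.0) -> float:
    """Find the adaptation slope inducing a target duration–glycaemia Spearman ρ.

    One cohort of ``n_cal`` subjects is simulated with the slope set to zero;
    because the slope enters the subject mean additively as
    ``slope * illness_duration``, the induced ρ for any slope can then be
    evaluated on the same draws (common random numbers), making ρ(slope)
    deterministic and non-decreasing. Bisection returns a slope whose induced
    ρ is within ``tol`` of ``target_rho``.
    """
    if not 0 <= target_rho < 1:
        raise ValueError("target_rho must be in [0, 1)")
    if target_rho == 0:
        return 0.0
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    base = replace(config, adaptation_slope=0.0, n_subjects=n_cal)
    records = sample_covariates(base, rng)
    m0 = simulate_subject_means(records, base, rng)
    duration = np.array([r.illness_duration for r in records])

    def induced(slope: float) -> float:
        return float(stats.spearmanr(duration, m0 + slope * duration).statistic)

    if induced(max_slope) < target_rho - tol:
        raise CalibrationError(
            f"target rho {target_rho} unreachable: even slope {max_slope} "
            f"induces only {induced(max_slope):.3f} under the configured "
            "variance budget (subject_sd, noise, EDI spread)"
        )
    lo, hi = 0.0, max_slope
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if induced(mid) < target_rho:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    slope = 0.5 * (lo + hi)
    achieved = induced(slope)
    if abs(achieved - target_rho) > tol:
        raise CalibrationError(
            f"bisection converged to slope {slope:.4g} with induced rho "
            f"{achieved:.3f}, outside tolerance {tol} of {target_rho}"
        )
    return slope
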