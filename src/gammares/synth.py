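"""Synthetic source-space cohort generator.

Emulates the visual gamma-response (GR) experiment: large high-contrast
gratings, static (0 deg/s) or drifting at 1.2 / 3.6 / 6.0 deg/s, ~90 trials per
condition, MEG beamformed to cortical vertices and epoched from -1.0 to 1.2 s
at 500 Hz.  Each subject carries a latent gain-control profile: gamma amplitude
follows a bell-shaped velocity curve ``r(v) = (1 + alpha*v) * exp(-beta*v)``
(enhancement coefficient ``alpha`` drives the ascending branch, attenuation
coefficient ``beta`` the descending branch), while gamma frequency increases
linearly with velocity.  The background is pink (1/f) noise, independent across
vertices; the gamma component has a trial-random phase, so it is induced (it
survives in power but cancels in the trial-averaged waveform).

A questionnaire-like sensory-sensitivity score is coupled to the attenuation
trait ``beta`` through a Gaussian copula so that the population Spearman
correlation between ``beta`` and the score equals a configured target exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError

__all__ = [
    "ParamDist",
    "SubjectParams",
    "CohortConfig",
    "EpochSet",
    "velocity_response_curve",
    "theoretical_indices",
    "sample_cohort",
    "spatial_gains",
    "generate_epochs",
    "generate_subject_epochs",
    "simulate_cohort",
    "calibrate_rho_sens",
    "condition_name",
]

#: canonical condition labels for the four-velocity protocol
CONDITION_NAMES = ("static", "slow", "medium", "fast")


def condition_name(velocities: Sequence[float], v: float) -> str:
    """Label for velocity ``v`` within the protocol's velocity list."""
    idx = list(velocities).index(v)
    if len(velocities) == len(CONDITION_NAMES):
        return CONDITION_NAMES[idx]
    return f"v{idx}"


@dataclass(frozen=True)
class ParamDist:
    """Truncated-normal distribution for one subject-level parameter."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")
        if not (self.lower <= self.mean <= self.upper):
            raise ConfigError("mean must lie within [lower, upper]")

    def _frozen(self):
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, self.mean)
        return self._frozen().ppf(rng.uniform(size=size))

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Quantile transform; monotone, used for copula coupling."""
        if self.sd == 0:
            return np.full(np.shape(q), self.mean)
        return self._frozen().ppf(q)


@dataclass
class SubjectParams:
    """Ground-truth generative parameters for one subject.

    alpha, beta
        Enhancement / attenuation coefficients (per deg/s) of the bell-shaped
        velocity-response curve.
    f0, gamma_slope
        Gamma frequency at v = 0 (Hz) and its linear increase (Hz per deg/s).
    snr
        Gamma-to-background amplitude ratio in the 'slow' condition at a
        unit-gain vertex.
    pink_exponent
        Background spectral slope: power ~ 1/f**pink_exponent.
    sens_score
        Simulated sensory-sensitivity questionnaire score.
    """

    subject_id: str
    alpha: float
    beta: float
    f0: float
    gamma_slope: float
    snr: float
    pink_exponent: float
    sens_score: float
    age: float = math.nan

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.snr < 0:
            raise ConfigError("alpha, beta, snr must be >= 0")
        if not 35.0 < self.f0 < 90.0:
            raise ConfigError("f0 must lie in (35, 90) Hz")
        if not math.isfinite(self.sens_score):
            raise ConfigError("sens_score must be finite")


@dataclass
class CohortConfig:
    """Cohort geometry and generative distributions.

    Defaults mirror the experiment: 27 subjects, two visits, four grating
    velocities (0 / 1.2 / 3.6 / 6.0 deg/s), 90 trials per condition, 500 Hz
    sampling, epochs from -1.0 to 1.2 s around stimulus onset.
    """

    n_subjects: int = 27
    n_trials: int = 90
    n_vertices: int = 64
    n_visits: int = 2
    sfreq: float = 500.0
    t_start: float = -1.0
    t_end: float = 1.2
    velocities: tuple[float, ...] = (0.0, 1.2, 3.6, 6.0)
    #: target population Spearman correlation between beta and sens_score;
    #: negative by default: stronger attenuation <-> lower reported sensitivity
    rho_sens: float = -0.4
    seed: int = 0

    alpha: ParamDist = field(default_factory=lambda: ParamDist(1.1, 0.2, 0.05, 3.0))
    beta: ParamDist = field(default_factory=lambda: ParamDist(0.5, 0.09, 0.05, 1.5))
    f0: ParamDist = field(default_factory=lambda: ParamDist(55.0, 5.0, 40.0, 80.0))
    gamma_slope: ParamDist = field(default_factory=lambda: ParamDist(2.5, 0.3, 0.5, 5.0))
    snr: ParamDist = field(default_factory=lambda: ParamDist(0.6, 0.15, 0.0, 5.0))
    pink_exponent: ParamDist = field(default_factory=lambda: ParamDist(1.0, 0.0, 0.5, 2.0))
    age: ParamDist = field(default_factory=lambda: ParamDist(27.6, 6.0, 18.0, 40.0))
    sens_mean: float = 37.7
    sens_sd: float = 6.5

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.velocities
        if len(v) < 2 or v[0] != 0.0 or any(b <= a for a, b in zip(v, v[1:])):
            raise ConfigError("velocities must be ascending and start at 0")
        for name in ("n_subjects", "n_trials", "n_vertices", "n_visits"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if abs(self.rho_sens) > 1:
            raise ConfigError("|rho_sens| must be <= 1")
        if self.sfreq <= 0:
            raise ConfigError("sfreq must be positive")
        if self.t_start > -0.9 or self.t_end < 1.2:
            raise ConfigError("epoch must cover the (-0.9, 0) and (0.3, 1.2) s windows")

    @property
    def n_samples(self) -> int:
        return int(round((self.t_end - self.t_start) * self.sfreq))

    @property
    def v_slow(self) -> float:
        """Reference velocity at which snr is defined (first moving condition)."""
        return self.velocities[1]


@dataclass
class EpochSet:
    """One condition's trials: array (trials, vertices, samples) of source
    amplitude, with timing metadata."""

    condition: str
    velocity: float
    data: np.ndarray
    sfreq: float
    t0: float
    visit: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ConfigError("data must be (trials, vertices, samples)")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("data contains NaN/Inf")
        if self.t0 > -0.9 or self.t_end < 1.2:
            raise ConfigError("epoch must cover the analysis windows")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def t_end(self) -> float:
        return self.t0 + self.data.shape[2] / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sfreq


# --------------------------------------------------------------------------
# velocity-response curve


def velocity_response_curve(params: SubjectParams, v) -> np.ndarray | float:
    """Relative gamma amplitude r(v) = (1 + alpha*v) * exp(-beta*v).

    r(0) = 1 by construction.  For alpha > beta > 0 the curve rises then
    falls, with interior maximum at v* = 1/beta - 1/alpha.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocity must be >= 0")
    r = (1.0 + params.alpha * v) * np.exp(-params.beta * v)
    return float(r) if r.ndim == 0 else r


def theoretical_indices(params: SubjectParams, velocities: Sequence[float]) -> dict:
    """Noise-free GSS/GEI implied by the generative curve.

    Normalized GR power is proportional to squared amplitude, so the
    theoretical per-condition powers are r(v)**2; the indices are computed
    from those exactly as the estimation stage defines them.
    """
    from .indices import compute_gei, compute_gss  # local import, no cycle at load

    v = np.asarray(velocities, dtype=float)
    power = np.asarray(velocity_response_curve(params, v)) ** 2
    moving = {float(vi): float(p) for vi, p in zip(v, power) if vi > 0}
    return {
        "gss": compute_gss(moving),
        "gei": compute_gei(float(power[0]), float(power[1])),
        "power": dict(zip(map(float, v), map(float, power))),
    }


# --------------------------------------------------------------------------
# seeding discipline: per-subject substreams keyed by (seed, stream, subject,
# visit) counters so cohort-size changes never reshuffle existing subjects

_STREAM_COHORT = 0
_STREAM_GAINS = 1
_STREAM_EPOCHS = 2


def _rng(seed: int, stream: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream)) + tuple(int(k) for k in key)))


# --------------------------------------------------------------------------
# cohort sampling


def sample_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> list[SubjectParams]:
    """Draw per-subject generative parameters.

    ``beta`` is obtained as a monotone quantile transform of a standard-normal
    latent, and the sensitivity score shares that latent through a Gaussian
    copula with Pearson loading ``2*sin(pi*rho_sens/6)`` — the classical
    relation that makes the population Spearman correlation equal ``rho_sens``
    exactly.  Deterministic under a fixed config seed.
    """
    config.validate()
    if rng is None:
        rng = _rng(config.seed, _STREAM_COHORT)
    n = config.n_subjects

    z_beta = rng.standard_normal(n)
    beta = config.beta.ppf(stats.norm.cdf(z_beta))

    rho_p = 2.0 * math.sin(math.pi * config.rho_sens / 6.0)
    noise = rng.standard_normal(n)
    if config.beta.sd == 0:
        z_sens = noise  # degenerate beta: score is pure noise
    else:
        z_sens = rho_p * z_beta + math.sqrt(1.0 - rho_p**2) * noise
    sens = config.sens_mean + config.sens_sd * z_sens

    alpha = config.alpha.sample(rng, n)
    f0 = config.f0.sample(rng, n)
    slope = config.gamma_slope.sample(rng, n)
    snr = config.snr.sample(rng, n)
    pink = config.pink_exponent.sample(rng, n)
    age = config.age.sample(rng, n)

    return [
        SubjectParams(
            subject_id=f"S{i:03d}",
            alpha=float(alpha[i]),
            beta=float(beta[i]),
            f0=float(f0[i]),
            gamma_slope=float(slope[i]),
            snr=float(snr[i]),
            pink_exponent=float(pink[i]),
            sens_score=float(sens[i]),
            age=float(age[i]),
        )
        for i in range(n)
    ]


def calibrate_rho_sens(
    target_gss_rho: float,
    config: CohortConfig | None = None,
    n_mc: int = 100_000,
    seed: int = 12345,
) -> float:
    """Find the beta<->score coupling ``rho_sens`` that yields a designed
    population Spearman correlation between the *theoretical GSS* and the score.

    GSS is a function of both alpha and beta, so its rank correlation with a
    score coupled to beta alone is attenuated; no closed form exists and the
    required rho_sens is solved numerically on a large Monte-Carlo sample of
    (alpha, beta) pairs, by bisection on the copula loading.
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(seed)
    z_beta = rng.standard_normal(n_mc)
    beta = config.beta.ppf(stats.norm.cdf(z_beta))
    alpha = config.alpha.sample(rng, n_mc)
    noise = rng.standard_normal(n_mc)

    v = np.asarray(config.velocities)
    vm = v[v > 0]
    # theoretical gss for each draw (vectorized)
    r = (1.0 + alpha[:, None] * vm[None, :]) * np.exp(-beta[:, None] * vm[None, :])
    p = r**2
    y = p / p[:, :1] - 1.0
    gss = (vm * y).sum(axis=1) / (vm**2).sum()
    gss_rank = stats.rankdata(gss)

    def spearman_at(rho_s: float) -> float:
        rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
        z = rho_p * z_beta + math.sqrt(1.0 - rho_p**2) * noise
        return float(stats.spearmanr(gss_rank, z).statistic)

    # spearman_at is monotone decreasing in rho_s (beta up -> gss down)
    lo, hi = -1.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if spearman_at(mid) > target_gss_rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# epoch generation


def spatial_gains(n_vertices: int, rng: np.random.Generator, n_high: int | None = None) -> np.ndarray:
    """Fixed per-subject vertex gain profile.

    Log-normal gains with a clearly elevated subset (default min(26, n/2)
    vertices) so the top-26 vertex-selection stage is exercised non-trivially.
    Shuffled so high-gain vertices are not a contiguous block.
    """
    if n_high is None:
        n_high = min(26, max(1, n_vertices // 2))
    n_high = min(n_high, n_vertices)
    g = np.empty(n_vertices)
    g[:n_high] = np.exp(rng.normal(0.0, 0.2, n_high))
    g[n_high:] = np.exp(rng.normal(-2.0, 0.4, n_vertices - n_high))
    rng.shuffle(g)
    return g


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int, exponent: float, sfreq: float) -> np.ndarray:
    """Unit-variance 1/f**exponent noise along the last axis (length n)."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _envelope(times: np.ndarray, ramp_end: float = 0.3) -> np.ndarray:
    """Stimulus envelope: 0 before onset, raised-cosine ramp to 1 by 0.3 s
    (the stimulation analysis window starts after the onset transient)."""
    env = np.zeros_like(times)
    ramp = (times >= 0) & (times < ramp_end)
    env[ramp] = 0.5 - 0.5 * np.cos(np.pi * times[ramp] / ramp_end)
    env[times >= ramp_end] = 1.0
    return env


def generate_epochs(
    params: SubjectParams,
    v: float,
    config: CohortConfig,
    rng: np.random.Generator,
    gains: np.ndarray | None = None,
    visit: int = 0,
) -> EpochSet:
    """Simulate one condition's trials for one subject.

    Signal model per trial and vertex::

        x(t) = pink(t) + g_vertex * A(v) * env(t) * cos(2*pi*f(v)*t + phi_trial)

    with ``f(v) = f0 + gamma_slope*v``, ``A(v) = sqrt(2)*snr*r(v)/r(v_slow)``
    (so the gamma RMS at a unit-gain vertex in the slow condition is ``snr``
    times the unit background RMS), and trial-uniform phase ``phi`` (induced,
    not evoked).  Baseline statistics do not depend on v.
    """
    config.validate()
    n = config.n_samples
    times = config.t_start + np.arange(n) / config.sfreq
    if gains is None:
        gains = spatial_gains(config.n_vertices, rng)
    if gains.shape != (config.n_vertices,):
        raise ConfigError("gains must have shape (n_vertices,)")

    x = _pink_noise(rng, (config.n_trials, config.n_vertices), n, params.pink_exponent, config.sfreq)

    r_rel = velocity_response_curve(params, v) / velocity_response_curve(params, config.v_slow)
    amp = math.sqrt(2.0) * params.snr * r_rel
    if amp > 0:
        f_g = params.f0 + params.gamma_slope * v
        phi = rng.uniform(0.0, 2.0 * np.pi, size=(config.n_trials, 1, 1))
        carrier = np.cos(2.0 * np.pi * f_g * times[None, None, :] + phi)
        x = x + gains[None, :, None] * (amp * _envelope(times))[None, None, :] * carrier

    return EpochSet(
        condition=condition_name(config.velocities, v),
        velocity=float(v),
        data=x,
        sfreq=config.sfreq,
        t0=config.t_start,
        visit=visit,
    )


def generate_subject_epochs(
    params: SubjectParams,
    config: CohortConfig,
    subject_index: int,
    visit: int,
) -> dict[str, EpochSet]:
    """All conditions for one subject x visit, with the subject's fixed spatial
    gain profile (shared across visits and conditions) and a visit-specific
    noise stream."""
    gains = spatial_gains(config.n_vertices, _rng(config.seed, _STREAM_GAINS, subject_index))
    rng = _rng(config.seed, _STREAM_EPOCHS, subject_index, visit)
    return {
        condition_name(config.velocities, v): generate_epochs(params, v, config, rng, gains=gains, visit=visit)
        for v in config.velocities
    }


def simulate_cohort(config: CohortConfig) -> Iterator[tuple[SubjectParams, int, dict[str, EpochSet]]]:
    """Lazily yield (params, visit, epochs-by-condition) for every subject and
    visit, so a full cohort never needs to be held in memory."""
    cohort = sample_cohort(config)
    for i, params in enumerate(cohort):
        for visit in range(config.n_visits):
            yield params, visit, generate_subject_epochs(params, config, i, visit)
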