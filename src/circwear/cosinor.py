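"""Bayesian cosinor model of the circadian rhythm in heart rate (CRHR).

Heart rate on the 5-minute grid is modelled as a 24-h cosine plus a linear
activity effect with AR(1) errors:

    HR_t = a - b cos(pi/12 (t - c)) + d A_t + eps_t,
    eps_{t+1} = k eps_t + N(0, sigma^2),

where ``a`` is basal heart rate (bpm), ``b`` the circadian amplitude
(bpm), ``c`` the clock time of the circadian HR minimum (hours, circular
modulo 24), ``d`` the heart-rate change per step, ``k`` the AR(1)
carryover fraction and ``sigma`` the innovation standard deviation.  The
AR chain is defined within contiguous runs of usable bins only and resets
across any gap (missing data, sleep, day boundary): carryover across a
multi-hour gap has no physical meaning.  The first bin of a run takes the
stationary marginal N(0, sigma^2 / (1 - k^2)).

Each day is fitted by the affine-invariant ensemble sampler with the log
posterior (log prior + AR(1) log likelihood) as target, spending 100,000
target evaluations per day with the first half of each chain discarded as
burn-in.  Days are chained sequentially: the posterior of day n, moment-
matched to independent Gaussians (with the phase handled on the unwrapped
circle) and inflated, serves as the prior of day n + 1, so information
accumulates while the chain can still track phase drift.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import BinnedSeries
from .sampler import gw_ensemble_sample

__all__ = [
    "CosinorParams",
    "SamplerConfig",
    "BasePrior",
    "GaussianPrior",
    "CrhrPosterior",
    "PhaseTrack",
    "hr_model_predict",
    "ar1_log_likelihood",
    "fit_day",
    "sequential_fit",
    "phase_credible_interval",
    "circular_mean",
    "fit_cosinor_ls",
]

log = logging.getLogger(__name__)

PARAM_NAMES = ("a", "b", "c", "d", "k_ar", "sigma")
_IA, _IB, _IC, _ID, _IK, _IS = range(6)


@dataclass(frozen=True)
class CosinorParams:
    """The six parameters of the heart-rate cosinor model."""

    a: float          # basal heart rate, bpm
    b: float          # circadian amplitude, bpm (>= 0)
    c: float          # clock time of HR minimum, hours in [0, 24)
    d: float          # bpm per step
    k_ar: float = 0.0  # AR(1) carryover fraction in [0, 1)
    sigma: float = 1.0  # innovation s.d., bpm (> 0)

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("amplitude b must be non-negative")
        if not 0.0 <= self.k_ar < 1.0:
            raise ValueError("k_ar must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "c", float(self.c) % 24.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.k_ar, self.sigma])


def hr_model_predict(params: CosinorParams, time_h, activity):
    """Noise-free model heart rate: a - b cos(pi/12 (t - c)) + d * activity."""
    t = np.asarray(time_h, dtype=float)
    A = np.asarray(activity, dtype=float)
    out = params.a - params.b * np.cos(np.pi / 12.0 * (t - params.c)) + params.d * A
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# priors

_LOG2PI = math.log(2.0 * math.pi)


def _norm_logpdf(x, mu, sd):
    return -0.5 * (_LOG2PI + 2.0 * np.log(sd) + ((x - mu) / sd) ** 2)


@dataclass(frozen=True)
class BasePrior:
    """Weakly informative prior, scale-matched to human heart rate.

    a ~ N(70, 15^2) bpm; b ~ HalfNormal(10) bpm; c ~ Uniform on the 24-h
    circle; d ~ N(0, 0.5^2) bpm/step; k_ar ~ Uniform[0, 1);
    sigma ~ HalfNormal(10) bpm.
    """

    a_mu: float = 70.0
    a_sd: float = 15.0
    b_scale: float = 10.0
    d_sd: float = 0.5
    sigma_scale: float = 10.0

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(theta)
        lp = _norm_logpdf(th[:, _IA], self.a_mu, self.a_sd)
        lp = lp + np.where(th[:, _IB] >= 0,
                           math.log(2.0) + _norm_logpdf(th[:, _IB], 0.0, self.b_scale),
                           -np.inf)
        lp = lp - math.log(24.0)  # c: wrapped uniform, constant on the reals
        lp = lp + _norm_logpdf(th[:, _ID], 0.0, self.d_sd)
        lp = lp + np.where((th[:, _IK] >= 0) & (th[:, _IK] < 1.0), 0.0, -np.inf)
        lp = lp + np.where(th[:, _IS] > 0,
                           math.log(2.0) + _norm_logpdf(th[:, _IS], 0.0, self.sigma_scale),
                           -np.inf)
        return lp

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        th = np.empty((n, 6))
        th[:, _IA] = rng.normal(self.a_mu, self.a_sd, n)
        th[:, _IB] = np.abs(rng.normal(0.0, self.b_scale, n))
        th[:, _IC] = rng.uniform(0.0, 24.0, n)
        th[:, _ID] = rng.normal(0.0, self.d_sd, n)
        th[:, _IK] = rng.uniform(0.0, 1.0, n)
        th[:, _IS] = np.abs(rng.normal(0.0, self.sigma_scale, n))
        th[th[:, _IS] < 1e-3, _IS] = 1e-3
        return th


@dataclass(frozen=True)
class GaussianPrior:
    """Independent-Gaussian prior from a moment-matched previous posterior.

    The phase mean lives on the circle: its density term uses the minimal
    circular deviation from ``mu[c]``, so chains may wander off [0, 24)
    freely.  Support constraints (b >= 0, k in [0, 1), sigma > 0) are kept
    as hard boundaries.
    """

    mu: np.ndarray
    sd: np.ndarray

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        th = np.atleast_2d(theta)
        lp = np.zeros(th.shape[0])
        for j in range(6):
            if j == _IC:
                dev = (th[:, _IC] - self.mu[_IC] + 12.0) % 24.0 - 12.0
                lp = lp + _norm_logpdf(dev, 0.0, self.sd[_IC])
            else:
                lp = lp + _norm_logpdf(th[:, j], self.mu[j], self.sd[j])
        lp = np.where(th[:, _IB] >= 0, lp, -np.inf)
        lp = np.where((th[:, _IK] >= 0) & (th[:, _IK] < 1.0), lp, -np.inf)
        lp = np.where(th[:, _IS] > 0, lp, -np.inf)
        return lp

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        th = self.mu + self.sd * rng.standard_normal((n, 6))
        th[:, _IB] = np.abs(th[:, _IB])
        th[:, _IK] = np.clip(th[:, _IK], 1e-6, 1.0 - 1e-6)
        th[:, _IS] = np.maximum(np.abs(th[:, _IS]), 1e-3)
        return th


# ---------------------------------------------------------------------------
# likelihood

def _usable(series: BinnedSeries, day: int | None = None):
    """Times, hr, activity and run-start flags of usable bins.

    Usable = worn, not sleep, with both heart rate and activity present.
    A new AR run starts wherever the preceding usable bin is not the
    immediately preceding grid bin.
    """
    sl = series.day_slice(day) if day is not None else slice(None)
    hr = series.hr[sl]
    act = series.activity[sl]
    ok = series.wear[sl] & ~series.sleep[sl] & np.isfinite(hr) & np.isfinite(act)
    idx = np.nonzero(ok)[0]
    hours = series.hour_of_day()[sl][idx]
    is_start = np.ones(idx.size, dtype=bool)
    if idx.size > 1:
        is_start[1:] = np.diff(idx) != 1
    return hours, hr[idx], act[idx], is_start


def ar1_log_likelihood(theta, time_h, hr, activity, is_start=None):
    """AR(1) cosinor log likelihood, vectorized over parameter rows.

    ``theta`` is (k, 6) (or length-6); ``is_start`` marks the first bin of
    each contiguous run (defaults to a single run).  Within a run the
    innovation eps_{t+1} - k eps_t is N(0, sigma^2); each run's first
    residual takes the stationary marginal N(0, sigma^2 / (1 - k^2)).
    """
    th = np.atleast_2d(np.asarray(theta, dtype=float))
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(hr, dtype=float)
    A = np.asarray(activity, dtype=float)
    if t.size == 0:
        raise ValueError("no usable bins: likelihood undefined")
    if is_start is None:
        is_start = np.zeros(t.size, dtype=bool)
        is_start[0] = True
    is_start = np.asarray(is_start, dtype=bool)

    a, b, c, d, k, s = (th[:, j][:, None] for j in range(6))
    pred = a - b * np.cos(np.pi / 12.0 * (t[None, :] - c)) + d * A[None, :]
    eps = y[None, :] - pred
    prev = np.empty_like(eps)
    prev[:, 0] = 0.0
    prev[:, 1:] = eps[:, :-1]
    innov = eps - k * prev
    resid = np.where(is_start[None, :], eps, innov)
    var = s**2 * np.where(is_start[None, :], 1.0 / (1.0 - k**2), 1.0)
    ll = -0.5 * np.sum(np.log(2.0 * np.pi * var) + resid**2 / var, axis=1)
    out = np.where(np.isfinite(ll), ll, -np.inf)
    return out if np.asarray(theta).ndim > 1 else float(out[0])


# ---------------------------------------------------------------------------
# fitting

@dataclass(frozen=True)
class SamplerConfig:
    """Per-day MCMC budget and interval settings.

    The default budget is 100,000 target evaluations per day with burn-in
    ratio 0.5.  ``fast()`` gives the reduced test budget (5,000
    evaluations); intervals widen but the machinery is identical.
    """

    n_walkers: int = 50
    n_total_evals: int = 100_000
    burn_in: float = 0.5
    stretch_a: float = 2.0
    min_bins: int = 24
    ci_level: float = 0.8
    prior_inflation: float = 1.5
    seed: int = 0

    @classmethod
    def fast(cls, seed: int = 0) -> "SamplerConfig":
        return cls(n_walkers=20, n_total_evals=5_000, seed=seed)


@dataclass
class CrhrPosterior:
    """Post-burn-in sample cloud for one day, with recomputable summaries."""

    day: object
    samples: np.ndarray  # (n_kept, 6)
    n_data: int
    fitted: bool = True

    def summary(self, level: float = 0.8) -> dict:
        out = {}
        lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
        for j, name in enumerate(PARAM_NAMES):
            col = self.samples[:, j]
            if name == "c":
                mean = circular_mean(col)
                lo, hi, half = phase_credible_interval(col, level)
                out[name] = {"mean": mean, "lo": lo, "hi": hi, "half_width": half}
            else:
                out[name] = {"mean": float(np.mean(col)),
                             "lo": float(np.quantile(col, lo_q)),
                             "hi": float(np.quantile(col, hi_q))}
        return out


@dataclass
class PhaseTrack:
    """Daily phase marker with circular credible intervals."""

    dates: list = field(default_factory=list)
    phase_h: list = field(default_factory=list)
    ci_low_h: list = field(default_factory=list)
    ci_high_h: list = field(default_factory=list)
    half_width_h: list = field(default_factory=list)
    n_bins: list = field(default_factory=list)

    def append(self, date, phase, lo, hi, half, n) -> None:
        self.dates.append(date)
        self.phase_h.append(phase)
        self.ci_low_h.append(lo)
        self.ci_high_h.append(hi)
        self.half_width_h.append(half)
        self.n_bins.append(n)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "date": self.dates, "phase_h": self.phase_h,
            "ci_low_h": self.ci_low_h, "ci_high_h": self.ci_high_h,
            "half_width_h": self.half_width_h, "n_bins": self.n_bins,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PhaseTrack":
        import pandas as pd

        df = pd.read_csv(path)
        tr = cls()
        for _, r in df.iterrows():
            tr.append(pd.to_datetime(r["date"]).date(), r["phase_h"],
                      r["ci_low_h"], r["ci_high_h"], r["half_width_h"],
                      int(r["n_bins"]))
        return tr


def circular_mean(hours: np.ndarray) -> float:
    """Mean direction of clock times, in hours [0, 24)."""
    ang = np.asarray(hours, dtype=float) * (2.0 * np.pi / 24.0)
    m = math.atan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return (m * 24.0 / (2.0 * np.pi)) % 24.0


def phase_credible_interval(c_samples: np.ndarray, level: float = 0.8,
                            ) -> tuple[float, float, float]:
    """Equal-tailed circular interval for the phase.

    Samples are unwrapped to the arc (mu - 12, mu + 12] about their
    circular mean mu, the equal-tailed quantile interval is taken there,
    and the endpoints are wrapped back to [0, 24).  Returns
    (low, high, half_width).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    c = np.asarray(c_samples, dtype=float)
    if c.size == 0:
        raise ValueError("empty sample")
    mu = circular_mean(c)
    dev = (c - mu + 12.0) % 24.0 - 12.0
    lo = float(np.quantile(dev, (1.0 - level) / 2.0))
    hi = float(np.quantile(dev, 1.0 - (1.0 - level) / 2.0))
    return (mu + lo) % 24.0, (mu + hi) % 24.0, (hi - lo) / 2.0


def fit_day(series: BinnedSeries, day: int, prior,
            config: SamplerConfig = SamplerConfig()) -> CrhrPosterior:
    """Fit one day's usable bins by ensemble MCMC under ``prior``.

    With fewer than ``config.min_bins`` usable bins the day is skipped:
    the returned posterior is a draw cloud from the prior itself with
    ``fitted=False`` so the sequential chain can carry it forward.
    """
    t, y, A, is_start = _usable(series, day)
    the_date = series.dates[day]
    rng = np.random.Generator(np.random.PCG64([config.seed, day, 91]))
    if t.size < config.min_bins:
        log.info("day %s skipped: %d usable bins (< %d)", the_date, t.size,
                 config.min_bins)
        n_kept = max(1000, config.n_walkers)
        return CrhrPosterior(day=the_date, samples=prior.sample(rng, n_kept),
                             n_data=int(t.size), fitted=False)

    def log_target(theta):
        lp = prior.log_prior(theta)
        fin = np.isfinite(lp)
        if np.any(fin):
            lp[fin] = lp[fin] + ar1_log_likelihood(theta[fin], t, y, A, is_start)
        return lp

    init = prior.sample(rng, config.n_walkers)
    chain, _ = gw_ensemble_sample(log_target, init, config.n_total_evals,
                                  stretch_a=config.stretch_a,
                                  seed=int(rng.integers(2**31)))
    n_steps = chain.shape[0]
    keep = chain[int(round(config.burn_in * n_steps)):]
    return CrhrPosterior(day=the_date, samples=keep.reshape(-1, 6),
                         n_data=int(t.size))


def _moment_match(post: CrhrPosterior, inflation: float) -> GaussianPrior:
    s = post.samples
    mu = np.empty(6)
    sd = np.empty(6)
    for j in range(6):
        col = s[:, j]
        if j == _IC:
            m = circular_mean(col)
            dev = (col - m + 12.0) % 24.0 - 12.0
            mu[j] = m
            sd[j] = max(float(np.std(dev)), 0.05)
        else:
            mu[j] = float(np.mean(col))
            sd[j] = max(float(np.std(col)), 1e-3)
    return GaussianPrior(mu=mu, sd=sd * inflation)


def sequential_fit(series: BinnedSeries, base_prior=None,
                   config: SamplerConfig = SamplerConfig(),
                   ) -> tuple[list[CrhrPosterior], PhaseTrack]:
    """Fit every day in order, chaining each posterior into the next prior.

    Day 1 uses ``base_prior`` (default :class:`BasePrior`); each later day
    uses the previous day's posterior, moment-matched to independent
    Gaussians with standard deviations inflated by
    ``config.prior_inflation`` so the chain can track drifting phase.
    """
    if series.n_days < 1:
        raise ValueError("series must hold at least one day")
    prior = base_prior if base_prior is not None else BasePrior()
    posts: list[CrhrPosterior] = []
    track = PhaseTrack()
    for day in range(series.n_days):
        post = fit_day(series, day, prior, config)
        posts.append(post)
        lo, hi, half = phase_credible_interval(post.samples[:, _IC], config.ci_level)
        track.append(post.day, circular_mean(post.samples[:, _IC]), lo, hi,
                     half, post.n_data)
        prior = _moment_match(post, config.prior_inflation)
    return posts, track


def fit_cosinor_ls(series: BinnedSeries, day: int | None = None) -> CosinorParams:
    """Deterministic least-squares fit of (a, b, c, d), ignoring the AR term.

    The cosine is linearized as B1 cos(wt) + B2 sin(wt), which makes the
    fit an ordinary linear regression; (b, c) are recovered from the polar
    form.  Used for noiseless recovery checks and sanity baselines.
    """
    t, y, A, _ = _usable(series, day)
    if t.size < 4:
        raise ValueError("need at least 4 usable bins")
    w = np.pi / 12.0
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t), A])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b1, b2, d = beta
    b = math.hypot(b1, b2)
    # -b cos(w (t - c)) = b1 cos + b2 sin  =>  b1 = -b cos(wc), b2 = -b sin(wc)
    c = (math.atan2(-b2, -b1) / w) % 24.0
    resid = y - X @ beta
    sigma = float(np.std(resid)) if np.std(resid) > 0 else 1e-6
    return CosinorParams(a=float(a), b=float(b), c=float(c), d=float(d),
                         k_ar=0.0, sigma=max(sigma, 1e-6))
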