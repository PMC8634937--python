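"""Limit-cycle oscillator model of the human circadian pacemaker.

The pacemaker is modelled as a higher-order van der Pol-type oscillator in
two dimensionless variables: ``x``, which tracks the core body temperature
rhythm, and ``xc``, a complementary variable required to close the limit
cycle.  A third state ``n`` is the fraction of activated (light-adapted)
photoreceptor, driving the photic input ``B`` through Process L:

    dx/dt  = (pi/12) [ xc + mu (x/3 + 4 x^3/3 - 256 x^7/105) + B ]
    dxc/dt = (pi/12) { q B xc - [ (24 / (0.99729 tau_x))^2 + k B ] x }
    dn/dt  = 60 [ alpha (1 - n) - beta n ]

    B_hat = G alpha (1 - n)
    B     = (1 - 0.4 x)(1 - 0.4 xc) B_hat
    alpha = alpha0 (I / I0)^p

Time is measured in hours; ``alpha`` and ``beta`` are per-minute rates,
hence the factor 60 in the ``n`` equation.  In darkness the oscillator free
runs with intrinsic period ``tau_x`` (the 0.99729 correction makes the
realized nonlinear period equal ``tau_x``); under a strong 24-h light
schedule it entrains to 24 h.

In the wearable setting no illuminance is recorded, so step counts stand in
for light through a configurable linear-capped mapping
(:func:`activity_to_light`).  The phase marker extracted from a simulated
trajectory is CBTmin, the daily minimum of ``x``; predicted DLMO is CBTmin
minus a fixed offset (7 h by convention for this model family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np

__all__ = [
    "ClockParams",
    "ClockState",
    "LightSeries",
    "DlmoTrack",
    "alpha_drive",
    "clock_rhs",
    "integrate",
    "free_running_period",
    "limit_cycle_ic",
    "activity_to_light",
    "predict_dlmo",
]


@dataclass(frozen=True)
class ClockParams:
    """Constants of the pacemaker model.

    Defaults are the published values for this model family; ``q`` is the
    xc-drive coefficient of the model lineage (1/3), not separately
    restated with the other constants.
    """

    mu: float = 0.13
    q: float = 1.0 / 3.0
    tau_x: float = 24.2
    k_stiff: float = 0.55
    beta: float = 0.013
    G: float = 19.875
    alpha0: float = 0.16
    I0: float = 9500.0
    p_exp: float = 0.6
    period_correction: float = 0.99729

    def __post_init__(self) -> None:
        for name in ("mu", "tau_x", "k_stiff", "beta", "G", "alpha0", "I0",
                     "p_exp", "period_correction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ClockParams.{name} must be strictly positive")


@dataclass(frozen=True)
class ClockState:
    """Pacemaker state (x, xc, n); ``n`` is a fraction in [0, 1]."""

    x: float
    xc: float
    n: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.xc)):
            raise ValueError("x and xc must be finite")
        if not 0.0 <= self.n <= 1.0:
            raise ValueError("n must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.xc, self.n], dtype=float)


# A point on the dark limit cycle (endpoint of a 40-cycle dark integration);
# used as the canonical on-cycle starting state.
ON_CYCLE_STATE = ClockState(x=0.995311, xc=0.001763, n=0.0)


@dataclass(frozen=True)
class LightSeries:
    """Illuminance per bin (lux, >= 0) on a uniform grid.

    ``start_date`` is informational; ``t0_hours`` is the clock hour of the
    first bin edge relative to local midnight of ``start_date``.
    """

    lux: np.ndarray
    bin_width_min: float = 5.0
    start_date: date | None = None
    t0_hours: float = 0.0

    def __post_init__(self) -> None:
        lux = np.asarray(self.lux, dtype=float)
        if lux.ndim != 1:
            raise ValueError("lux must be one-dimensional")
        if np.any(lux < 0) or np.any(~np.isfinite(lux)):
            raise ValueError("illuminance must be finite and non-negative")
        object.__setattr__(self, "lux", lux)

    @property
    def bin_width_h(self) -> float:
        return self.bin_width_min / 60.0

    @property
    def duration_h(self) -> float:
        return self.lux.size * self.bin_width_h


@dataclass
class DlmoTrack:
    """Per-day predicted DLMO clock times (hours in [0, 24))."""

    dates: list = field(default_factory=list)
    dlmo_h: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"date": self.dates, "dlmo_h": self.dlmo_h})


def alpha_drive(illuminance, params: ClockParams = ClockParams()):
    """Photic activation rate alpha = alpha0 * (I / I0)^p (per minute).

    Vectorized over ``illuminance``; exactly zero at zero lux.
    """
    I = np.asarray(illuminance, dtype=float)
    if np.any(I < 0):
        raise ValueError("illuminance must be non-negative")
    out = params.alpha0 * (I / params.I0) ** params.p_exp
    return out if out.ndim else float(out)


def _rhs(y: np.ndarray, I: float, p: ClockParams) -> np.ndarray:
    x, xc, n = y
    alpha = p.alpha0 * (I / p.I0) ** p.p_exp if I > 0 else 0.0
    b_hat = p.G * alpha * (1.0 - n)
    B = (1.0 - 0.4 * x) * (1.0 - 0.4 * xc) * b_hat
    pi12 = math.pi / 12.0
    dx = pi12 * (xc + p.mu * (x / 3.0 + (4.0 / 3.0) * x**3
                              - (256.0 / 105.0) * x**7) + B)
    stiff = (24.0 / (p.period_correction * p.tau_x)) ** 2
    dxc = pi12 * (p.q * B * xc - (stiff + p.k_stiff * B) * x)
    dn = 60.0 * (alpha * (1.0 - n) - p.beta * n)
    return np.array([dx, dxc, dn])


def clock_rhs(state: ClockState, illuminance: float,
              params: ClockParams = ClockParams()) -> np.ndarray:
    """Time derivative (dx/dt, dxc/dt, dn/dt) in per-hour units."""
    if illuminance < 0:
        raise ValueError("illuminance must be non-negative")
    return _rhs(state.as_array(), float(illuminance), params)


def integrate(initial: ClockState, light: LightSeries,
              params: ClockParams = ClockParams(),
              dt: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the pacemaker driven by a piecewise-constant light series.

    Fixed-step classical Runge-Kutta (RK4) with illuminance held constant
    within each bin (zero-order hold); ``n`` is clamped to [0, 1] after
    every step.  ``dt`` (hours) must divide the bin width; it defaults to
    one step per bin.

    Returns ``(t, Y)`` where ``t`` has shape (n_steps + 1,) in hours since
    the series start and ``Y`` has shape (n_steps + 1, 3).  A zero-length
    light series returns the initial state only.
    """
    bw = light.bin_width_h
    if dt is None:
        dt = bw
    if dt > bw + 1e-12:
        raise ValueError("dt must not exceed the bin width")
    steps_per_bin = int(round(bw / dt))
    if abs(steps_per_bin * dt - bw) > 1e-9:
        raise ValueError("dt must divide the bin width")

    n_bins = light.lux.size
    n_steps = n_bins * steps_per_bin
    t = light.t0_hours + np.arange(n_steps + 1) * dt
    Y = np.empty((n_steps + 1, 3))
    y = initial.as_array()
    Y[0] = y
    k = 0
    for b in range(n_bins):
        I = float(light.lux[b])
        for _ in range(steps_per_bin):
            k1 = _rhs(y, I, params)
            k2 = _rhs(y + 0.5 * dt * k1, I, params)
            k3 = _rhs(y + 0.5 * dt * k2, I, params)
            k4 = _rhs(y + dt * k3, I, params)
            y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            y[2] = min(1.0, max(0.0, y[2]))
            if not np.all(np.isfinite(y)):
                raise FloatingPointError(
                    f"integration blew up at t = {t[k + 1]:.3f} h")
            k += 1
            Y[k] = y
    return t, Y


def _upward_zero_crossings(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Times where x crosses zero going upward, by linear interpolation."""
    s = np.sign(x)
    idx = np.nonzero((s[:-1] < 0) & (s[1:] >= 0))[0]
    frac = -x[idx] / (x[idx + 1] - x[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def free_running_period(params: ClockParams = ClockParams(),
                        n_cycles: int = 25, dt: float = 1.0 / 12.0) -> float:
    """Realized dark (free-running) period, in hours.

    Integrates in darkness from an on-cycle state for ``n_cycles`` nominal
    cycles and returns the mean spacing of the last 10 upward
    zero-crossings of ``x``.
    """
    span_h = n_cycles * params.tau_x
    n_bins = int(math.ceil(span_h / (dt)))
    dark = LightSeries(np.zeros(n_bins), bin_width_min=dt * 60.0)
    t, Y = integrate(ON_CYCLE_STATE, dark, params, dt=dt)
    crossings = _upward_zero_crossings(t, Y[:, 0])
    if crossings.size < 11:
        raise RuntimeError("oscillation degenerate: fewer than 11 zero crossings")
    last = crossings[-11:]
    return float(np.mean(np.diff(last)))


def limit_cycle_ic(template_day: LightSeries,
                   params: ClockParams = ClockParams(),
                   tol: float = 1e-6, max_days: int = 90,
                   start: ClockState = ON_CYCLE_STATE,
                   ) -> tuple[ClockState, bool]:
    """Entrained initial condition: iterate one template day to a fixed point.

    The 24-h ``template_day`` light schedule is repeated until the state at
    the daily reference time (the day start) changes by less than ``tol``
    in every component between successive days, up to ``max_days``.

    Returns ``(state, converged)``; on non-convergence the last state is
    returned with ``converged = False``.
    """
    if abs(template_day.duration_h - 24.0) > 1e-9:
        raise ValueError("template day must span exactly 24 h")
    y = start
    for _ in range(max_days):
        _, Y = integrate(y, template_day, params)
        new = ClockState(*Y[-1])
        delta = np.max(np.abs(new.as_array() - y.as_array()))
        y = new
        if delta < tol:
            return y, True
    return y, False


def activity_to_light(activity: np.ndarray,
                      sleep_mask: np.ndarray | None = None,
                      scale: float = 1.0, cap_lux: float = 1000.0,
                      bin_width_min: float = 5.0,
                      start_date: date | None = None) -> LightSeries:
    """Map binned step counts to a surrogate illuminance series.

    Default mapping: ``lux = min(scale * steps, cap_lux)``; bins flagged as
    sleep, and bins with missing activity, map to 0 lux (dark).  The
    mapping is a declared stand-in for unrecorded light exposure.
    """
    act = np.asarray(activity, dtype=float)
    if np.any(act[np.isfinite(act)] < 0):
        raise ValueError("step counts must be non-negative")
    lux = np.where(np.isfinite(act), np.minimum(scale * act, cap_lux), 0.0)
    if sleep_mask is not None:
        lux = np.where(np.asarray(sleep_mask, dtype=bool), 0.0, lux)
    return LightSeries(lux, bin_width_min=bin_width_min, start_date=start_date)


def predict_dlmo(t: np.ndarray, x: np.ndarray, offset_h: float = 7.0,
                 start_date: date | None = None) -> DlmoTrack:
    """Extract per-day predicted DLMO from a pacemaker trajectory.

    Per calendar day of the trajectory, CBTmin is the time of the daily
    minimum of ``x``, refined by fitting a parabola through the three
    bracketing samples; predicted DLMO = CBTmin - ``offset_h`` wrapped to
    [0, 24).  Days whose minimum falls on the day boundary (no interior
    minimum) are skipped.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    track = DlmoTrack()
    day0 = int(math.floor(t[0] / 24.0))
    day_last = int(math.floor(t[-1] / 24.0))
    for d in range(day0, day_last + 1):
        sel = np.nonzero((t >= 24.0 * d) & (t < 24.0 * (d + 1)))[0]
        if sel.size < 3:
            continue
        i = sel[np.argmin(x[sel])]
        if i == sel[0] or i == sel[-1]:
            continue  # minimum on the window edge: not an interior minimum
        # parabolic refinement through (t[i-1..i+1], x[i-1..i+1])
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        h = t[i + 1] - t[i]
        t_min = t[i] + shift * h
        dlmo = (t_min - offset_h) % 24.0
        if start_date is not None:
            track.dates.append(start_date + timedelta(days=d - day0))
        else:
            track.dates.append(d)
        track.dlmo_h.append(float(dlmo))
    return track
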