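"""Kinetic and circadian model fits.

Three fits used across the accompanying assays:

* damped cosine for circadian bioluminescence rhythms,
      y(x) = m*x + c + A * exp(-k*x) * cos(2*pi*(x - phase) / period),
  where m, c describe a linear trend, A the initial oscillation amplitude,
  k the decay constant (1/k is reported as the half-life alongside the
  conventional ln2/k) and phase is the shift of the cosine in hours;
* di-/tri-exponential dwell-time fits of single-molecule TIRF bright/dark
  time distributions (complementary CDF of a mixture of exponentials),
  preceded by the standard detection quality filters;
* the one-site specific binding curve y = x / (Kd + x) with Bmax fixed to 1
  for TR-FRET titrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from ._util import substream

__all__ = [
    "TimeSeries",
    "DampedCosineFit",
    "DwellSet",
    "Detection",
    "ExpMixtureFit",
    "damped_cosine",
    "fit_damped_cosine",
    "filter_detections",
    "fit_exp_mixture",
    "fit_one_site",
]


@dataclass(frozen=True)
class TimeSeries:
    """A sampled trace: strictly increasing time (h) and signal values."""

    time: np.ndarray
    signal: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, float)
        y = np.asarray(self.signal, float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", y)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class DampedCosineFit:
    """Fitted parameters of the damped cosine oscillation model."""

    m: float
    c: float
    amplitude: float
    k: float
    phase: float
    period: float
    rss: float
    oscillation_identifiable: bool = True

    @property
    def half_life(self) -> float:
        """1/k, the half-life as conventionally quoted alongside this model."""
        return np.inf if self.k == 0 else 1.0 / self.k

    @property
    def half_life_ln2(self) -> float:
        """ln(2)/k, the conventional exponential half-life."""
        return np.inf if self.k == 0 else np.log(2) / self.k

    def predict(self, x: np.ndarray) -> np.ndarray:
        return damped_cosine(np.asarray(x, float), self.m, self.c, self.amplitude,
                             self.k, self.phase, self.period)


def damped_cosine(x, m, c, amplitude, k, phase, period):
    """y = m*x + c + A * exp(-k*x) * cos(2*pi*(x - phase)/period)."""
    return m * x + c + amplitude * np.exp(-k * x) * np.cos(2 * np.pi * (x - phase) / period)


def _period_guess(t: np.ndarray, resid: np.ndarray) -> float:
    """Dominant period from a periodogram (Lomb-Scargle; sampling-agnostic)."""
    duration = t[-1] - t[0]
    dt = np.median(np.diff(t))
    periods = np.linspace(max(4 * dt, duration / 50), duration / 1.5, 2000)
    ang = 2 * np.pi / periods
    power = signal.lombscargle(t, resid - resid.mean(), ang, normalize=True)
    return float(periods[np.argmax(power)])


def fit_damped_cosine(ts: TimeSeries, init: dict | None = None) -> DampedCosineFit:
    """Nonlinear least-squares fit of the damped cosine model.

    Default initialisation: linear detrend -> Lomb-Scargle periodogram peak
    for the period -> envelope regression (log |residual| extrema in two
    halves) for amplitude and decay -> phase by grid scan. A trace with no
    detectable oscillation returns the linear trend with the oscillation
    parameters zeroed and flagged unidentifiable.
    """
    if len(ts) < 8:
        raise ValueError("need >= 8 points to fit an oscillation")
    t, y = ts.time, ts.signal

    coef = np.polyfit(t, y, 1)
    resid = y - np.polyval(coef, t)
    scale = max(np.max(np.abs(y)), 1.0)
    if np.std(resid) < 1e-10 * scale:
        return DampedCosineFit(
            m=float(coef[0]), c=float(coef[1]), amplitude=0.0, k=0.0,
            phase=0.0, period=np.nan, rss=float(np.sum(resid**2)),
            oscillation_identifiable=False,
        )

    p0 = dict(init or {})
    period0 = p0.get("period", _period_guess(t, resid))
    # envelope: amplitude/decay from the oscillation magnitude in two halves
    half = len(t) // 2
    s1, s2 = np.std(resid[:half]), np.std(resid[half:])
    tm1, tm2 = t[:half].mean(), t[half:].mean()
    if s1 > 0 and s2 > 0 and s2 < s1:
        k0 = p0.get("k", float(np.log(s1 / s2) / (tm2 - tm1)))
    else:
        k0 = p0.get("k", 0.0)
    amp0 = p0.get("amplitude", float(np.sqrt(2) * s1 * np.exp(k0 * tm1)))
    # phase by coarse grid at fixed period/amplitude
    phases = np.linspace(0, period0, 24, endpoint=False)
    rss_grid = [
        np.sum((resid - amp0 * np.exp(-k0 * t) * np.cos(2 * np.pi * (t - ph) / period0)) ** 2)
        for ph in phases
    ]
    phase0 = p0.get("phase", float(phases[int(np.argmin(rss_grid))]))

    x0 = [p0.get("m", coef[0]), p0.get("c", coef[1]), amp0, max(k0, 0.0), phase0, period0]

    def residual(theta):
        return damped_cosine(t, *theta) - y

    lb = [-np.inf, -np.inf, 0.0, 0.0, -np.inf, 1e-6]
    ub = [np.inf] * 6
    x0[2] = max(x0[2], 1e-12)
    sol = optimize.least_squares(residual, x0, bounds=(lb, ub), method="trf")
    if not sol.success:
        raise RuntimeError(
            f"damped-cosine fit failed to converge (status {sol.status}); "
            f"initialisation was m={x0[0]:.3g}, c={x0[1]:.3g}, A={x0[2]:.3g}, "
            f"k={x0[3]:.3g}, phase={x0[4]:.3g}, period={x0[5]:.3g}"
        )
    m, c, A, k, phase, period = sol.x
    phase = float(phase % period)
    return DampedCosineFit(
        m=float(m), c=float(c), amplitude=float(A), k=float(k),
        phase=phase, period=float(period), rss=float(2 * sol.cost),
    )


@dataclass(frozen=True)
class Detection:
    """A single-molecule detection with its quality metrics."""

    psf_width_nm: float
    offset_nm: float
    intensity: float

    def __post_init__(self) -> None:
        if min(self.psf_width_nm, self.offset_nm, self.intensity) < 0:
            raise ValueError("detection metrics must be non-negative")


def filter_detections(
    detections,
    psf_max_nm: float = 400.0,
    offset_max_nm: float = 250.0,
    intensity_max: float = 5000.0,
) -> list:
    """Quality filter for single-molecule detections.

    A detection is kept iff psf <= 400 nm AND offset <= 250 nm AND
    intensity <= 5000 counts; "exceeding" a threshold (strictly greater)
    excludes, so the boundaries themselves are kept. Idempotent.
    """
    return [
        d for d in detections
        if d.psf_width_nm <= psf_max_nm
        and d.offset_nm <= offset_max_nm
        and d.intensity <= intensity_max
    ]


@dataclass(frozen=True)
class DwellSet:
    """Dwell durations (s) of one kind: bright (bound) or dark (unbound)."""

    durations: np.ndarray
    kind: str = "bright"

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, float)
        if d.size == 0 or np.any(d <= 0):
            raise ValueError("durations must be positive and non-empty")
        if self.kind not in ("bright", "dark"):
            raise ValueError("kind must be 'bright' or 'dark'")
        object.__setattr__(self, "durations", d)


@dataclass
class ExpMixtureFit:
    """Weights and time constants of an exponential mixture."""

    weights: np.ndarray
    tau: np.ndarray
    rss: float
    degenerate: bool = False

    @property
    def mean(self) -> float:
        return float(np.sum(self.weights * self.tau))

    def survival(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return np.sum(self.weights[:, None] * np.exp(-t[None, :] / self.tau[:, None]), axis=0)


def fit_exp_mixture(
    dwells: DwellSet,
    n_components: int = 2,
    n_starts: int = 10,
    seed: int = 0,
) -> ExpMixtureFit:
    """Fit the empirical complementary CDF with a 2- or 3-exponential mixture.

    S(t) = sum_i w_i exp(-t / tau_i), sum w_i = 1, tau_i > 0; unweighted
    least squares on the empirical survival at the sorted dwell times,
    seeded multi-start (starts spread around quantile-based tau guesses).
    Nearly coincident time constants are flagged ``degenerate``.
    """
    if n_components not in (2, 3):
        raise ValueError("n_components must be 2 or 3")
    d = np.sort(dwells.durations)
    n = d.size
    if n < 50:
        warnings.warn(f"only {n} dwells; mixture fits below ~50 are unreliable", stacklevel=2)
    s_emp = 1.0 - (np.arange(1, n + 1) - 0.5) / n

    kc = n_components
    rng = substream(seed, f"expmix/{dwells.kind}/{kc}")

    def model(theta):
        logtau = theta[:kc]
        wfree = theta[kc:]
        w = _softmax(np.append(wfree, 0.0))
        tau = np.exp(logtau)
        return w, tau

    def residual(theta):
        w, tau = model(theta)
        return np.sum(w[:, None] * np.exp(-d[None, :] / tau[:, None]), axis=0) - s_emp

    qs = np.quantile(d, np.linspace(0.2, 0.9, kc))
    best = None
    for s in range(n_starts):
        jitter = rng.normal(0, 0.5, size=kc) if s else 0.0
        theta0 = np.concatenate([np.log(qs) + jitter, np.zeros(kc - 1)])
        try:
            sol = optimize.least_squares(residual, theta0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("exponential-mixture fit failed from every start")
    w, tau = model(best.x)
    order = np.argsort(tau)
    w, tau = w[order], tau[order]
    # components closer than two-fold are not resolvable from a survival curve
    degenerate = bool(np.any(tau[1:] / tau[:-1] < 2.0))
    if degenerate:
        warnings.warn("nearly coincident time constants; consider fewer components", stacklevel=2)
    return ExpMixtureFit(weights=w, tau=tau, rss=float(2 * best.cost), degenerate=degenerate)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - np.max(z))
    return e / e.sum()


def fit_one_site(conc: np.ndarray, fret_signal: np.ndarray) -> float:
    """One-site specific binding fit with Bmax fixed to 1: y = x / (Kd + x).

    Returns the dissociation constant Kd (same units as ``conc``). Raises
    when the titration carries no curvature (all points saturated or all at
    baseline), which leaves Kd unidentifiable.
    """
    x = np.asarray(conc, float)
    y = np.asarray(fret_signal, float)
    if x.size < 4:
        raise ValueError("need >= 4 titration points")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    if np.all(y > 0.9) or np.all(y < 0.1):
        raise ValueError("no curvature in the titration; Kd unidentifiable")

    def f(x, kd):
        return x / (kd + x)

    # initial Kd: concentration at half-maximal signal
    kd0 = float(np.interp(0.5, np.clip(y[np.argsort(x)], 0, 1), np.sort(x))) or float(np.median(x[x > 0]))
    popt, _ = optimize.curve_fit(f, x, y, p0=[max(kd0, 1e-12)], bounds=(1e-15, np.inf))
    return float(popt[0])
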