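"""1:1 Langmuir binding kinetics and sigmoidal titration fitting.

Biolayer-interferometry sensorgrams are modelled with the standard 1:1
solution: during association at analyte concentration C,

    R(t) = Rmax · C/(C + KD) · (1 − exp(−(kon·C + koff)·t)),

and during dissociation R decays as R(t_assoc)·exp(−koff·t).  Fitting is
nonlinear least squares in log-parameter space with multi-start
initialization; the default global mode shares kon, koff and Rmax across
the dilution series, matching common instrument practice.  Titration
curves use a four-parameter logistic (4PL) with free Hill slope.

Mass-transport limitation, baseline drift and reference subtraction are
outside the model; lack-of-fit shows up in the residual diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares


class KineticsError(ValueError):
    pass


class FitConvergenceError(RuntimeError):
    """Raised when no start converges; carries the best attempt."""

    def __init__(self, message, best_fit=None, diagnostics=None):
        super().__init__(message)
        self.best_fit = best_fit
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class SensorgramSet:
    """Response traces over a shared time grid, one per concentration."""

    concentrations: Sequence[float]  # molar
    times: np.ndarray  # s, strictly increasing, spans both phases
    t_assoc: float  # association/dissociation boundary, s
    responses: np.ndarray  # (n_conc, n_times) response units
    noise_sd: Optional[float] = None

    def __post_init__(self):
        t = np.asarray(self.times, float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise KineticsError("time grid must be strictly increasing")
        r = np.asarray(self.responses, float)
        if r.shape != (len(self.concentrations), t.size):
            raise KineticsError(
                f"responses shape {r.shape} does not match "
                f"({len(self.concentrations)}, {t.size})"
            )
        if not 0 < self.t_assoc < t[-1]:
            raise KineticsError("t_assoc must lie inside the time grid")


@dataclass(frozen=True)
class KineticsFit:
    kon: float  # 1/(M·s)
    koff: float  # 1/s
    rmax: float  # response units
    residual_rms: tuple[float, ...]  # per trace
    fit_mode: str  # "global" | "per_trace"

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass(frozen=True)
class Ec50Fit:
    ec50: float
    hill_slope: float
    top: float
    bottom: float
    residual_rms: float


def model_1to1(
    times: np.ndarray,
    t_assoc: float,
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
) -> np.ndarray:
    """Noise-free 1:1 sensorgram on a time grid spanning both phases."""
    t = np.asarray(times, float)
    kd = koff / kon
    req = rmax * conc / (conc + kd)
    kobs = kon * conc + koff
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-koff * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, assoc, dissoc)


def simulate_sensorgrams(
    kon: float,
    koff: float,
    rmax: float,
    concentrations: Sequence[float],
    t_assoc: float = 180.0,
    t_dissoc: float = 180.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    dt: float = 1.0,
) -> SensorgramSet:
    """Simulate a dilution series of 1:1 sensorgrams with Gaussian noise."""
    if min(kon, koff, rmax, t_assoc, t_dissoc, dt) <= 0:
        raise KineticsError("rates, Rmax, phase durations and dt must be positive")
    if any(c <= 0 for c in concentrations):
        raise KineticsError("concentrations must be positive")
    times = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    traces = np.array(
        [model_1to1(times, t_assoc, kon, koff, rmax, c) for c in concentrations]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        traces = traces + rng.normal(0.0, noise_sd, traces.shape)
    return SensorgramSet(
        concentrations=list(concentrations),
        times=times,
        t_assoc=t_assoc,
        responses=traces,
        noise_sd=noise_sd or None,
    )


def _global_residuals(logp, data: SensorgramSet) -> np.ndarray:
    kon, koff, rmax = np.exp(np.clip(logp, -60.0, 60.0))
    res = []
    for c, trace in zip(data.concentrations, data.responses):
        res.append(model_1to1(data.times, data.t_assoc, kon, koff, rmax, c) - trace)
    return np.concatenate(res)


def _fit_traces(data: SensorgramSet) -> tuple[np.ndarray, np.ndarray]:
    """Multi-start global least squares; returns (params, residual vector)."""
    rmax0 = max(float(np.nanmax(data.responses)), 1e-6)
    cmid = float(np.median(data.concentrations))
    starts = []
    for kon0 in (1e4, 1e5, 1e6):
        for koff0 in (1e-2, 1e-3, 1e-4):
            starts.append(np.log([kon0, koff0, rmax0 * 1.5]))
    starts.append(np.log([1.0 / cmid / 100.0, 1e-3, rmax0 * 1.2]))
    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                _global_residuals, x0, args=(data,), method="lm", max_nfev=4000
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError("no start converged", diagnostics={"starts": len(starts)})
    return np.exp(np.clip(best.x, -60.0, 60.0)), best.fun


def fit_1to1(data: SensorgramSet, mode: str = "global"):
    """Fit the 1:1 model to a sensorgram set.

    ``global`` (default) shares kon/koff/Rmax across the dilution series and
    returns one :class:`KineticsFit`; ``per_trace`` fits each concentration
    independently and returns a list (diagnostic use).
    """
    if mode == "global":
        if len(data.concentrations) < 2:
            raise KineticsError("global mode needs at least two concentrations")
        params, resid = _fit_traces(data)
        kon, koff, rmax = params
        n = data.times.size
        rms = tuple(
            float(np.sqrt(np.mean(resid[i * n : (i + 1) * n] ** 2)))
            for i in range(len(data.concentrations))
        )
        return KineticsFit(kon, koff, rmax, rms, "global")
    if mode == "per_trace":
        fits = []
        for c, trace in zip(data.concentrations, data.responses):
            sub = SensorgramSet(
                [c], data.times, data.t_assoc, trace[None, :], data.noise_sd
            )
            params, resid = _fit_traces(sub)
            kon, koff, rmax = params
            fits.append(
                KineticsFit(
                    kon, koff, rmax,
                    (float(np.sqrt(np.mean(resid**2))),),
                    "per_trace",
                )
            )
        return fits
    raise KineticsError(f"unknown fit mode {mode!r}")


def logistic_4pl(conc, ec50, hill, top, bottom):
    c = np.asarray(conc, float)
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill)


def fit_ec50(concentrations: Sequence[float], responses: Sequence[float]) -> Ec50Fit:
    """Four-parameter logistic fit of a titration; EC50 on the input scale."""
    c = np.asarray(concentrations, float)
    r = np.asarray(responses, float)
    if c.size < 5:
        raise KineticsError("need at least 5 concentration points")
    if np.any(c <= 0):
        raise KineticsError("concentrations must be positive")
    span = float(r.max() - r.min())
    if span < 1e-12 or span < 0.02 * max(abs(float(r.max())), 1e-12):
        raise KineticsError("no dose-dependence: response is flat")

    def residuals(p):
        log_ec50, hill, top, bottom = p
        return logistic_4pl(c, np.exp(log_ec50), hill, top, bottom) - r

    best = None
    for ec0 in (np.median(c), np.sqrt(c.min() * c.max())):
        for hill0 in (0.7, 1.0, 1.5):
            x0 = [np.log(ec0), hill0, float(r.max()), float(r.min())]
            try:
                sol = least_squares(residuals, x0, method="lm", max_nfev=4000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitConvergenceError("EC50 fit did not converge")
    log_ec50, hill, top, bottom = best.x
    if top < bottom:  # flip to the conventional orientation
        top, bottom, hill = bottom, top, -hill
    return Ec50Fit(
        ec50=float(np.exp(log_ec50)),
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        residual_rms=float(np.sqrt(np.mean(best.fun**2))),
    )
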