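"""Image-derived arterial input functions: extraction, fitting, extrapolation.

The arterial curve is sampled from an artery mask over the dynamic frames,
modelled as a linear rise from bolus arrival to the peak followed by a sum of
decaying exponentials, and integrated analytically out to the therapy horizon
with tracer-decay exchange and administered-activity scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ArterialCurve",
    "AIFFit",
    "AIFFitError",
    "extract_aif",
    "fit_aif",
    "therapy_auc",
]

_S_PER_MIN = 60.0

#: number of multi-start attempts for the nonlinear tail fit
_N_STARTS = 16

#: fraction of the peak below which a pre-peak sample marks bolus arrival
_ARRIVAL_FRACTION = 0.05


class AIFFitError(RuntimeError):
    """Nonlinear AIF fit failed to converge within the multi-start budget."""


@dataclass(frozen=True)
class ArterialCurve:
    """Sampled arterial activity concentration (Bq mL^-1 vs seconds)."""

    times_s: np.ndarray
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("activities must be >= 0")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "values", v)

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.times_s, self.values])
        np.savetxt(path, arr, delimiter=",", header="time_s,activity_Bq_per_mL",
                   comments="", fmt="%.10g")

    @classmethod
    def from_csv(cls, path, source: str = "") -> "ArterialCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(times_s=arr[:, 0], values=arr[:, 1], source=source or str(path))


@dataclass(frozen=True)
class AIFFit:
    """Piecewise arterial model: linear rise then an exponential-sum tail.

    The curve is zero before ``t_arrival_s``, rises linearly to
    ``sum(amplitudes)`` at ``t_peak_s``, and decays as
    ``sum_i A_i exp(-r_i (t - t_peak))`` afterwards (rates in min^-1).
    ``t_scan_end_s`` records the end of measured data; a population terminal
    clearance may replace the slowest fitted rate beyond it.
    """

    t_arrival_s: float
    t_peak_s: float
    amplitudes: np.ndarray  # Bq mL^-1
    rates_per_min: np.ndarray
    t_scan_end_s: float
    rel_rms: float = float("nan")

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        r = np.asarray(self.rates_per_min, dtype=float)
        if a.shape != r.shape or a.ndim != 1 or not (1 <= a.size <= 3):
            raise ValueError("need 1-3 (amplitude, rate) pairs")
        if np.any(r <= 0):
            raise ValueError("rates must be > 0")
        if np.any(a < 0):
            raise ValueError("amplitudes must be >= 0 (fit guarantees non-negativity)")
        if not self.t_arrival_s <= self.t_peak_s:
            raise ValueError("bolus arrival must precede the peak")
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "rates_per_min", r)

    @property
    def peak_value(self) -> float:
        return float(self.amplitudes.sum())

    def __call__(self, t_s: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the fitted curve at times in seconds."""
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        dt_min = np.maximum(t - self.t_peak_s, 0.0) / _S_PER_MIN
        tail = self.amplitudes @ np.exp(-np.outer(self.rates_per_min, dt_min))
        out = np.where(t >= self.t_peak_s, tail, 0.0)
        if self.t_peak_s > self.t_arrival_s:
            rise = self.peak_value * (t - self.t_arrival_s) / (self.t_peak_s - self.t_arrival_s)
            out = np.where((t >= self.t_arrival_s) & (t < self.t_peak_s), rise, out)
        return float(out[0]) if np.ndim(t_s) == 0 else out

    def to_json(self, path) -> None:
        payload = {
            "t_arrival_s": self.t_arrival_s,
            "t_peak_s": self.t_peak_s,
            "amplitudes_Bq_per_mL": self.amplitudes.tolist(),
            "rates_per_min": self.rates_per_min.tolist(),
            "t_scan_end_s": self.t_scan_end_s,
            "rel_rms": self.rel_rms,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AIFFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            t_arrival_s=d["t_arrival_s"],
            t_peak_s=d["t_peak_s"],
            amplitudes=np.asarray(d["amplitudes_Bq_per_mL"]),
            rates_per_min=np.asarray(d["rates_per_min"]),
            t_scan_end_s=d["t_scan_end_s"],
            rel_rms=d.get("rel_rms", float("nan")),
        )


def extract_aif(study, artery_mask: np.ndarray) -> ArterialCurve:
    """Mean arterial TAC over a mask, one sample per frame at frame mid-time.

    ``study`` provides a 4-D activity array (``data``, time axis last) and a
    ``schedule`` (:class:`~ldvdose.kinetics.FrameSchedule`).
    """
    mask = np.asarray(artery_mask, dtype=bool)
    if mask.shape != study.data.shape[:-1]:
        raise ValueError("artery mask geometry does not match the study grid")
    if not mask.any():
        raise ValueError("artery mask is empty")
    curve = study.data[mask, :].mean(axis=0)
    return ArterialCurve(
        times_s=study.schedule.mid_s, values=np.maximum(curve, 0.0),
        source=f"mask mean over {int(mask.sum())} voxels",
    )


def _tail_model(params_log: np.ndarray, dt_min: np.ndarray, n_exp: int) -> np.ndarray:
    a = np.exp(params_log[:n_exp])
    r = np.exp(params_log[n_exp:])
    return np.sum(a[:, None] * np.exp(-r[:, None] * dt_min[None, :]), axis=0)


def fit_aif(curve: ArterialCurve, n_exp: int = 2) -> AIFFit:
    """Fit the rise/exponential-sum model to a sampled arterial curve.

    Multi-start trust-region least squares on the tail (peak to scan end),
    parameters in log space to enforce positivity; best of a fixed list of
    16 seeded starts by residual sum of squares, ties to the lower start
    index.  Deterministic for a given curve.
    """
    if n_exp not in (1, 2, 3):
        raise ValueError("n_exp must be 1, 2 or 3")
    t, v = curve.times_s, curve.values
    if t.size < 2 * n_exp + 2:
        raise AIFFitError(f"need at least {2 * n_exp + 2} samples, got {t.size}")
    ipeak = int(np.argmax(v))
    if ipeak == t.size - 1:
        raise AIFFitError("no detectable peak: maximum at the last sample")
    peak = v[ipeak]
    if peak <= 0:
        raise AIFFitError("all-zero curve")

    pre = np.nonzero(v[: ipeak + 1] <= _ARRIVAL_FRACTION * peak)[0]
    t_arrival = float(t[pre[-1]]) if pre.size else float(t[0])

    tail_t = (t[ipeak:] - t[ipeak]) / _S_PER_MIN
    tail_v = v[ipeak:]
    scale = peak

    # seeded multi-start grid: amplitudes split the peak, rates span decades
    rng = np.random.default_rng(20250804)
    starts = []
    base_rates = np.geomspace(0.02, 2.0, n_exp) if n_exp > 1 else np.array([0.1])
    for i in range(_N_STARTS):
        jitter = rng.uniform(0.3, 3.0, size=2 * n_exp)
        a0 = np.full(n_exp, scale / n_exp) * jitter[:n_exp]
        r0 = base_rates * jitter[n_exp:]
        starts.append(np.log(np.concatenate([a0, r0])))

    best = None
    for x0 in starts:
        try:
            res = least_squares(
                lambda p: _tail_model(p, tail_t, n_exp) - tail_v,
                x0, method="trf", max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-300:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise AIFFitError(
            f"tail fit failed after {_N_STARTS} starts "
            f"(n_exp={n_exp}, {tail_v.size} tail samples)"
        )
    a = np.exp(best.x[:n_exp])
    r = np.exp(best.x[n_exp:])
    order = np.argsort(r)[::-1]  # fastest first
    rel_rms = float(np.sqrt(2.0 * best.cost / tail_v.size) / scale)
    return AIFFit(
        t_arrival_s=t_arrival,
        t_peak_s=float(t[ipeak]),
        amplitudes=a[order],
        rates_per_min=r[order],
        t_scan_end_s=float(t[-1]),
        rel_rms=rel_rms,
    )


def _int_exp(c0: float, rate: float, t0: float, t1: float) -> float:
    """Integral of c0*exp(-rate*(t-t0)) over [t0, t1] (minutes)."""
    span = t1 - t0
    if span <= 0:
        return 0.0
    if abs(rate) < 1e-15:
        return c0 * span
    return c0 * (1.0 - np.exp(-rate * span)) / rate


def _int_linear_exp(m: float, t_a: float, delta: float, t0: float, t1: float) -> float:
    """Integral of m*(t - t_a)*exp(-delta*t) over [t0, t1] (minutes)."""
    if t1 <= t0:
        return 0.0
    if abs(delta) < 1e-15:
        return m * ((t1 - t_a) ** 2 - (t0 - t_a) ** 2) / 2.0

    def anti(t: float) -> float:
        # antiderivative of (t - t_a) e^{-d t}: -e^{-d t} ((t - t_a)/d + 1/d^2)
        return -np.exp(-delta * t) * ((t - t_a) / delta + 1.0 / delta**2)

    return m * (anti(t1) - anti(t0))


def therapy_auc(
    fit: AIFFit,
    lam_diag: float,
    lam_ther: float,
    A_diag_GBq: float,
    A_ther_GBq: float,
    horizon_s: float,
    r_pop_per_min: float | None = None,
) -> float:
    """Therapy-scaled arterial AUC over [0, horizon], Bq s mL^-1.

    The measured-tracer physical decay is removed and the therapeutic decay
    applied (net factor ``exp(-(lam_ther - lam_diag) t)``, rates in min^-1),
    then the curve is scaled by the ratio of administered activities.  The
    integral is analytic piecewise (rise, tail) — no numeric quadrature.
    ``r_pop_per_min``, when given, replaces the slowest fitted rate beyond
    the measured scan window (population terminal clearance).
    """
    if A_diag_GBq <= 0 or A_ther_GBq <= 0:
        raise ValueError("administered activities must be positive")
    if horizon_s < fit.t_scan_end_s:
        raise ValueError("horizon must be at least the scan span")
    if np.any(fit.amplitudes < 0):
        raise ValueError("extrapolated curve negative: negative tail amplitude")

    delta = lam_ther - lam_diag  # min^-1
    h = horizon_s / _S_PER_MIN
    t_a = fit.t_arrival_s / _S_PER_MIN
    t_p = fit.t_peak_s / _S_PER_MIN
    t_end = fit.t_scan_end_s / _S_PER_MIN

    total = 0.0
    if t_p > t_a:
        m = fit.peak_value / (t_p - t_a)  # Bq/mL per minute
        total += _int_linear_exp(m, t_a, delta, t_a, min(t_p, h))

    slowest = int(np.argmin(fit.rates_per_min))
    for i, (a, r) in enumerate(zip(fit.amplitudes, fit.rates_per_min)):
        eff = r + delta  # decay-exchanged clearance of this term
        if i == slowest and r_pop_per_min is not None:
            # fitted rate inside the measured window, population rate beyond
            seg_end = min(t_end, h)
            total += np.exp(-delta * t_p) * _int_exp(a, eff, 0.0, seg_end - t_p)
            if h > t_end:
                c_end = a * np.exp(-r * (t_end - t_p)) * np.exp(-delta * t_end)
                total += _int_exp(c_end, r_pop_per_min + delta, 0.0, h - t_end)
        else:
            total += np.exp(-delta * t_p) * _int_exp(a, eff, 0.0, h - t_p)

    return float(total * _S_PER_MIN * (A_ther_GBq / A_diag_GBq))
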