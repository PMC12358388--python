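"""Decay-incorporated standard two-tissue compartment kinetics.

The tissue impulse response to an arterial bolus (the flow-scaled residue
function ``R(t)``) is a biexponential whose rates are the eigen-rates of the
compartmental system shifted by the physical decay constant.  Closed-form
areas under ``R(t)`` give the Logan distribution volume in the small-decay
limit and the therapy-relevant residue AUC otherwise.

All kinetic quantities are in minutes internally; half-lives are supplied in
days and converted once at the boundary (:func:`lambda_per_min_from_half_life_days`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "MacroRates",
    "FrameSchedule",
    "PURE_BLOOD",
    "NonFiniteAUCError",
    "macro_rates",
    "auc_R",
    "ldv",
    "simulate_tissue_tac",
    "effective_half_life",
    "integration_horizon",
    "lambda_per_min_from_half_life_days",
]

#: seconds per minute, used wherever frame timing (s) meets rates (1/min)
_S_PER_MIN = 60.0

#: relative threshold on the eigen discriminant below which the repeated-root
#: limiting form (a t*exp(-alpha t) term) is used instead of two exponentials
_DEGENERATE_RTOL = 1e-12


class NonFiniteAUCError(ValueError):
    """The residue-function AUC is infinite for the given rate constants."""


def lambda_per_min_from_half_life_days(half_life_days: float) -> float:
    """Convert a physical half-life in days to a decay constant in min^-1."""
    if half_life_days <= 0:
        raise ValueError("half-life must be positive")
    return np.log(2.0) / (half_life_days * 24.0 * 60.0)


@dataclass(frozen=True)
class KineticParams:
    """Microparameters of the decay-incorporated two-tissue model.

    Parameters
    ----------
    K1 : float
        Blood-to-tissue influx rate, mL min^-1 g^-1.
    k2, k3, k4 : float
        Efflux, binding and dissociation rate constants, min^-1.
    lam : float
        Radionuclide decay constant, min^-1 (0 for decay-corrected data).
    """

    K1: float
    k2: float
    k3: float
    k4: float
    lam: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def to_dict(self) -> dict[str, float]:
        return {
            "K1": self.K1,
            "k2": self.k2,
            "k3": self.k3,
            "k4": self.k4,
            "lambda_per_min": self.lam,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "KineticParams":
        return cls(
            K1=float(d["K1"]),
            k2=float(d["k2"]),
            k3=float(d["k3"]),
            k4=float(d["k4"]),
            lam=float(d.get("lambda_per_min", 0.0)),
        )


class _PureBlood:
    """Sentinel kinetic configuration: tissue curve equals the arterial curve.

    Used by tests and the phantom's artery voxels; exact (fractional blood
    volume of one) rather than an asymptotic limit of rate constants.
    """

    def __repr__(self) -> str:  # pragma: no cover
        return "PURE_BLOOD"


PURE_BLOOD = _PureBlood()


@dataclass(frozen=True)
class MacroRates:
    """Biexponential macroconstants of the residue function.

    ``R(t) = G exp(-alpha t) + H exp(-beta t) + ramp * t exp(-alpha t)``

    ``ramp`` is non-zero only in the repeated-eigenvalue degenerate case
    (then ``alpha == beta``).  Invariants: ``alpha <= beta``, ``G + H = K1``,
    ``G, H >= 0``, and both rates are at least the decay constant.
    """

    G: float
    H: float
    alpha: float
    beta: float
    ramp: float = 0.0

    def residue(self, t_min: np.ndarray | float) -> np.ndarray:
        """Evaluate R(t) at times given in minutes."""
        t = np.asarray(t_min, dtype=float)
        out = self.G * np.exp(-self.alpha * t) + self.H * np.exp(-self.beta * t)
        if self.ramp != 0.0:
            out = out + self.ramp * t * np.exp(-self.alpha * t)
        return out


def macro_rates(kp: KineticParams) -> MacroRates:
    """Macroconstants (G, H, alpha, beta) of the residue function.

    alpha and beta are the decay constant plus the two eigen-rates of the
    two-tissue system,
    ``lam + [(k2+k3+k4) -/+ sqrt((k2+k3+k4)^2 - 4 k2 k4)] / 2``;
    amplitudes follow from partial fractions of the transfer function.  The
    repeated-root case returns the analytic limiting form via ``ramp``.
    """
    s = kp.k2 + kp.k3 + kp.k4
    disc = s * s - 4.0 * kp.k2 * kp.k4
    # disc >= (k2 - k4)^2 + k3*(k3 + 2k2 + 2k4) >= 0 analytically; clip fp dust
    disc = max(disc, 0.0)
    if disc <= _DEGENERATE_RTOL * s * s:
        theta = 0.5 * s
        alpha = kp.lam + theta
        ramp = kp.K1 * (kp.k3 + kp.k4 - theta)
        return MacroRates(G=kp.K1, H=0.0, alpha=alpha, beta=alpha, ramp=ramp)
    root = np.sqrt(disc)
    theta1 = 0.5 * (s - root)
    theta2 = 0.5 * (s + root)
    G = kp.K1 * (kp.k3 + kp.k4 - theta1) / (theta2 - theta1)
    H = kp.K1 - G
    return MacroRates(G=G, H=H, alpha=kp.lam + theta1, beta=kp.lam + theta2)


def auc_R(kp: KineticParams) -> float:
    """Closed-form area under the residue function on [0, inf), mL g^-1.

    ``K1 (k4 + k3 + lam) / (k2 k4 + (k2 + k3 + k4) lam + lam^2)``

    Raises
    ------
    NonFiniteAUCError
        If the denominator vanishes (no efflux path: k4 = lam = 0 with
        k3 > 0, or all rates zero), i.e. the integral diverges.
    """
    if kp.K1 == 0.0:
        return 0.0
    denom = kp.k2 * kp.k4 + (kp.k2 + kp.k3 + kp.k4) * kp.lam + kp.lam**2
    if denom <= 0.0:
        # 0/0 one-compartment limit: k3 = k4 = lam = 0 -> K1/k2
        if kp.k3 == 0.0 and kp.k2 + kp.lam > 0.0:
            return kp.K1 / (kp.k2 + kp.lam)
        raise NonFiniteAUCError(
            f"residue AUC diverges for k2={kp.k2}, k3={kp.k3}, "
            f"k4={kp.k4}, lam={kp.lam}"
        )
    return kp.K1 * (kp.k4 + kp.k3 + kp.lam) / denom


def ldv(kp: KineticParams) -> float:
    """Logan distribution volume ``K1/k2 (1 + k3/k4)`` in mL g^-1.

    This is the small-decay (lam -> 0) limit of :func:`auc_R`; for
    week-scale half-lives the two agree to well under 1%.
    """
    if kp.k2 <= 0.0:
        raise ValueError("LDV undefined for k2 = 0")
    if kp.k3 > 0.0 and kp.k4 <= 0.0:
        raise ValueError("LDV undefined for k3 > 0 with k4 = 0 (irreversible binding)")
    binding = kp.k3 / kp.k4 if kp.k3 > 0.0 else 0.0
    return kp.K1 / kp.k2 * (1.0 + binding)


def effective_half_life(t_phys: float, t_bio: float) -> float:
    """Effective half-life from physical and biological ones (same units).

    ``1/T_eff = 1/T_phys + 1/T_bio``; always <= min of the two.
    """
    if t_phys <= 0 or t_bio <= 0:
        raise ValueError("half-lives must be positive")
    return 1.0 / (1.0 / t_phys + 1.0 / t_bio)


def integration_horizon(t_phys: float, t_bio: float, n_half_lives: float = 5.0) -> float:
    """Activity residence horizon: ``n`` effective half-lives (same units in/out)."""
    return n_half_lives * effective_half_life(t_phys, t_bio)


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames (all times in seconds)."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __init__(self, start_s, duration_s):
        start = np.asarray(start_s, dtype=float)
        dur = np.asarray(duration_s, dtype=float)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValueError("start and duration must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)

    @classmethod
    def from_durations(cls, durations_s, t0_s: float = 0.0) -> "FrameSchedule":
        dur = np.asarray(durations_s, dtype=float)
        start = t0_s + np.concatenate(([0.0], np.cumsum(dur[:-1])))
        return cls(start, dur)

    @property
    def n_frames(self) -> int:
        return int(self.start_s.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.duration_s

    @property
    def span_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])


def _frame_average(fine_t_s: np.ndarray, fine_v: np.ndarray, fs: FrameSchedule) -> np.ndarray:
    """Mean of a finely sampled curve over each frame window (trapezoid)."""
    cum = np.concatenate(([0.0], np.cumsum(0.5 * (fine_v[1:] + fine_v[:-1]) * np.diff(fine_t_s))))
    lo = np.interp(fs.start_s, fine_t_s, cum)
    hi = np.interp(fs.end_s, fine_t_s, cum)
    return (hi - lo) / fs.duration_s


def simulate_tissue_tac(
    aif_times_s: np.ndarray,
    aif_values: np.ndarray,
    kp: KineticParams | _PureBlood,
    fs: FrameSchedule,
    dt_s: float = 1.0,
) -> np.ndarray:
    """Forward-simulate a per-frame tissue TAC as ``Ca (x) R`` then frame-average.

    The arterial curve is resampled to a uniform ``dt_s`` grid spanning the
    schedule, convolved with the residue function on that grid, and averaged
    over each frame window (instantaneous sampling would be biased for the
    long late frames).  Passing :data:`PURE_BLOOD` returns the frame-averaged
    arterial curve itself.
    """
    t = np.asarray(aif_times_s, dtype=float)
    v = np.asarray(aif_values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape or t.size < 2:
        raise ValueError("aif times/values must be equal-length 1-D arrays")
    if t[-1] < fs.end_s[-1] - 1e-9 or t[0] > fs.start_s[0] + 1e-9:
        raise ValueError("arterial curve must cover the full scan span")
    grid = np.arange(fs.start_s[0], fs.end_s[-1] + 0.5 * dt_s, dt_s)
    ca = np.interp(grid, t, v)
    if isinstance(kp, _PureBlood):
        return _frame_average(grid, ca, fs)
    mr = macro_rates(kp)
    r = mr.residue((grid - grid[0]) / _S_PER_MIN)
    # trapezoid-weighted discrete convolution (endpoint terms halved);
    # plain rectangle weights bias the integral by O(dt * beta)
    full = np.convolve(ca, r)[: grid.size]
    tac = (full - 0.5 * (ca * r[0] + ca[0] * r)) * (dt_s / _S_PER_MIN)
    return _frame_average(grid, np.maximum(tac, 0.0), fs)
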