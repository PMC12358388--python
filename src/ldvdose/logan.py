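"""Voxel-wise Logan graphical analysis.

The tissue and arterial curves are transformed to Logan coordinates
(cumulative integrals normalized by the instantaneous tissue activity); the
distribution volume is the slope of the late, quasi-equilibrium portion.  A
grid of candidate equilibration delays is searched and the fit with maximum
R^2 kept per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ldvdose.kinetics import FrameSchedule

__all__ = [
    "DelayFit",
    "ParametricMaps",
    "logan_transform",
    "fit_delay_search",
    "default_delay_grid",
    "ldv_map",
]

_S_PER_MIN = 60.0

#: quasi-equilibrium delay search window, minutes
DELAY_WINDOW_MIN = (2.33, 8.0)

#: TAC positivity floor, as a fraction of the voxel's peak activity
_FLOOR_FRACTION = 1e-3


@dataclass(frozen=True)
class DelayFit:
    """Best Logan line for one curve: slope, intercept (min), R^2, delay."""

    slope: float
    intercept: float
    r2: float
    t0_min: float
    n_points: int
    two_point: bool = False


@dataclass
class ParametricMaps:
    """Voxel maps from Logan analysis, sharing one geometry.

    ``ldv`` is in mL/g when divided by density (else mL blood per mL tissue);
    ``intercept`` in minutes; ``t0_min`` the selected delay.  ``analyzed``
    marks voxels with a usable fit — everything else is NaN, never zero.
    """

    ldv: np.ndarray
    intercept: np.ndarray
    r2: np.ndarray
    t0_min: np.ndarray
    analyzed: np.ndarray
    two_point: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.ldv, self.intercept, self.r2,
                                    self.t0_min, self.analyzed)}
        if len(shapes) != 1:
            raise ValueError("parametric maps must share one geometry")
        r2v = self.r2[self.analyzed.astype(bool)]
        if r2v.size and (np.nanmin(r2v) < -1e-9 or np.nanmax(r2v) > 1 + 1e-9):
            raise ValueError("R^2 out of [0, 1] on analyzed voxels")

    def save_nifti(self, out_dir, affine: np.ndarray) -> dict[str, str]:
        """Write ldv/intercept/r2/t0_min volumes as NIfTI-1, return paths."""
        import os

        import nibabel as nib

        paths = {}
        for name, arr in (("ldv", self.ldv), ("intercept", self.intercept),
                          ("r2", self.r2), ("t0_min", self.t0_min)):
            p = os.path.join(out_dir, f"{name}.nii")
            nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), p)
            paths[name] = p
        return paths


def _cumint(times_min: np.ndarray, values: np.ndarray,
            durations_min: np.ndarray | None = None) -> np.ndarray:
    """Cumulative integral to each sample time, along the last axis.

    With ``durations_min`` the samples are treated as frame averages at frame
    mid-times, for which ``sum(v_i d_i) - v_j d_j / 2`` is the exact integral
    to mid-time j.  Without durations: trapezoid on the native grid, with the
    curve extended flat from t=0 to the first sample.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if durations_min is not None:
        vd = v * np.asarray(durations_min, dtype=float)
        return np.cumsum(vd, axis=-1) - 0.5 * vd
    dt = np.diff(t)
    seg = 0.5 * (v[..., 1:] + v[..., :-1]) * dt
    cum = np.cumsum(seg, axis=-1)
    lead = v[..., :1] * t[0]  # constant extrapolation over [0, t_0]
    return np.concatenate([lead, lead + cum], axis=-1)


def logan_transform(
    tac_times_s: np.ndarray,
    tac: np.ndarray,
    aif_times_s: np.ndarray,
    aif: np.ndarray,
    floor: float | None = None,
    frame_durations_s: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Transform one TAC/AIF pair to Logan coordinates (minutes).

    Returns ``(X, Y, valid)`` with ``X_j = int_0^{t_j} Ca / TAC(t_j)`` and
    ``Y_j = int_0^{t_j} TAC / TAC(t_j)``.  Cumulative integrals use the
    trapezoid rule on each curve's native grid (or the exact frame-average
    rule when ``frame_durations_s`` is given and both curves are
    frame-sampled); the arterial integral is interpolated to the TAC sample
    times.  Frames with TAC at or below the positivity floor are excluded
    via ``valid``.
    """
    tt = np.asarray(tac_times_s, dtype=float) / _S_PER_MIN
    tv = np.asarray(tac, dtype=float)
    at = np.asarray(aif_times_s, dtype=float) / _S_PER_MIN
    av = np.asarray(aif, dtype=float)
    if tt.shape != tv.shape or at.shape != av.shape:
        raise ValueError("times and values must match in length")
    durs = None
    if frame_durations_s is not None:
        durs = np.asarray(frame_durations_s, dtype=float) / _S_PER_MIN
    cum_tac = _cumint(tt, tv, durations_min=durs)
    if durs is not None and at.size == tt.size and np.allclose(at, tt):
        cum_aif = _cumint(at, av, durations_min=durs)
    else:
        cum_aif = np.interp(tt, at, _cumint(at, av))
    if floor is None:
        floor = max(np.finfo(float).tiny, _FLOOR_FRACTION * float(tv.max(initial=0.0)))
    valid = tv > floor
    denom = np.where(valid, tv, 1.0)
    X = np.where(valid, cum_aif / denom, np.nan)
    Y = np.where(valid, cum_tac / denom, np.nan)
    return X, Y, valid


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n = x.size
    sx, sy = x.sum(), y.sum()
    vxx = n * (x * x).sum() - sx * sx
    vxy = n * (x * y).sum() - sx * sy
    vyy = n * (y * y).sum() - sy * sy
    if vxx <= 0:
        return np.nan, np.nan, np.nan
    slope = vxy / vxx
    intercept = (sy - slope * sx) / n
    r2 = 1.0 if vyy <= 0 else min(max(vxy * vxy / (vxx * vyy), 0.0), 1.0)
    return slope, intercept, r2


def default_delay_grid(fs: FrameSchedule, window_min: tuple[float, float] = DELAY_WINDOW_MIN,
                       use_frame_mid: bool = True) -> np.ndarray:
    """Candidate delays: frame mid-times (or end-times) inside the window."""
    marks = (fs.mid_s if use_frame_mid else fs.end_s) / _S_PER_MIN
    lo, hi = window_min
    grid = marks[(marks >= lo) & (marks <= hi)]
    if grid.size == 0:
        raise ValueError("no frame marks inside the delay window")
    return grid


def fit_delay_search(
    X: np.ndarray,
    Y: np.ndarray,
    frame_mid_min: np.ndarray,
    delay_grid_min: np.ndarray,
    valid: np.ndarray | None = None,
) -> DelayFit:
    """Best Logan line over a delay grid for a single curve.

    For each candidate delay an ordinary least-squares line is fitted to the
    frames with mid-time at or after the delay; the fit with maximum R^2 is
    returned, ties broken toward the earliest delay.  A two-point fit has
    R^2 reported as 1 by convention and is flagged.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    mids = np.asarray(frame_mid_min, float)
    ok = np.isfinite(X) & np.isfinite(Y)
    if valid is not None:
        ok &= np.asarray(valid, bool)
    best: DelayFit | None = None
    for d in np.sort(np.asarray(delay_grid_min, float)):
        sel = ok & (mids >= d)
        n = int(sel.sum())
        if n < 2:
            continue
        slope, intercept, r2 = _ols(X[sel], Y[sel])
        if not np.isfinite(slope):
            continue
        fit = DelayFit(slope, intercept, r2, float(d), n, two_point=(n == 2))
        # improvement must exceed fp noise so ties go to the earliest delay
        if best is None or fit.r2 > best.r2 + 1e-12:
            best = fit
    if best is None:
        raise ValueError("voxel unanalyzable: fewer than 2 usable frames at every delay")
    return best


def ldv_map(
    study,
    aif_curve,
    mask: np.ndarray,
    density: np.ndarray,
    delay_grid_min: np.ndarray | None = None,
    divide_by_density: bool = True,
    use_frame_mid: bool = True,
) -> ParametricMaps:
    """Voxel-wise Logan analysis over a mask (vectorized).

    The dimensionless slope (mL blood per mL tissue) is divided by the local
    density to give mL/g when ``divide_by_density`` is set.  Voxels without
    two usable frames at any delay are flagged unanalyzable (NaN maps), not
    silently zeroed.
    """
    data = study.data
    mask = np.asarray(mask, dtype=bool)
    density = np.asarray(density, dtype=float)
    if mask.shape != data.shape[:-1] or density.shape != mask.shape:
        raise ValueError("study, mask and density geometries do not match")

    fs: FrameSchedule = study.schedule
    mids = fs.mid_s / _S_PER_MIN
    if delay_grid_min is None:
        delay_grid_min = default_delay_grid(fs, use_frame_mid=use_frame_mid)
    delay_grid_min = np.sort(np.asarray(delay_grid_min, float))

    durs = fs.duration_s / _S_PER_MIN
    tacs = data[mask, :].astype(float)  # (nv, nf)
    nv, nf = tacs.shape
    cum_tac = _cumint(mids, tacs, durations_min=durs)

    aif_t = np.asarray(aif_curve.times_s, float) / _S_PER_MIN
    aif_v = np.asarray(aif_curve.values, float)
    if aif_t.size == mids.size and np.allclose(aif_t, mids):
        # frame-sampled arterial curve: frame-aware integral is exact
        cum_aif = _cumint(aif_t, aif_v, durations_min=durs)
    else:
        cum_aif = np.interp(mids, aif_t, _cumint(aif_t, aif_v))

    floor = np.maximum(np.finfo(float).tiny, _FLOOR_FRACTION * tacs.max(axis=1))
    valid = tacs > floor[:, None]
    denom = np.where(valid, tacs, 1.0)
    X = cum_aif[None, :] / denom
    Y = cum_tac / denom

    best_slope = np.full(nv, np.nan)
    best_int = np.full(nv, np.nan)
    best_r2 = np.full(nv, -np.inf)
    best_t0 = np.full(nv, np.nan)
    best_two = np.zeros(nv, dtype=bool)

    for d in delay_grid_min:
        w = valid & (mids >= d)[None, :]
        n = w.sum(axis=1).astype(float)
        xw = np.where(w, X, 0.0)
        yw = np.where(w, Y, 0.0)
        sx = xw.sum(axis=1)
        sy = yw.sum(axis=1)
        vxx = n * (xw * xw).sum(axis=1) - sx * sx
        vxy = n * (xw * yw).sum(axis=1) - sx * sy
        vyy = n * (yw * yw).sum(axis=1) - sy * sy
        usable = (n >= 2) & (vxx > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(usable, vxy / vxx, np.nan)
            intercept = np.where(usable, (sy - slope * sx) / np.maximum(n, 1), np.nan)
            r2 = np.where(vyy > 0, vxy * vxy / np.where(usable, vxx * vyy, 1.0), 1.0)
        r2 = np.clip(np.where(usable, r2, -np.inf), -np.inf, 1.0)
        r2 = np.where(usable & (n == 2), 1.0, r2)  # two-point convention
        better = r2 > best_r2 + 1e-12  # ties go to the earliest delay
        best_slope = np.where(better, slope, best_slope)
        best_int = np.where(better, intercept, best_int)
        best_t0 = np.where(better, d, best_t0)
        best_two = np.where(better, n == 2, best_two)
        best_r2 = np.where(better, r2, best_r2)

    analyzed_v = np.isfinite(best_slope)
    best_r2 = np.where(analyzed_v, np.clip(best_r2, 0.0, 1.0), np.nan)

    slope_v = best_slope
    if divide_by_density:
        slope_v = slope_v / density[mask]

    def fill(vals: np.ndarray, dtype=float, empty=np.nan) -> np.ndarray:
        out = np.full(mask.shape, empty, dtype=dtype)
        out[mask] = vals
        return out

    return ParametricMaps(
        ldv=fill(slope_v),
        intercept=fill(best_int),
        r2=fill(best_r2),
        t0_min=fill(best_t0),
        analyzed=fill(analyzed_v, dtype=bool, empty=False),
        two_point=fill(best_two, dtype=bool, empty=False),
    )
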