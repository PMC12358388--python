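"""Pipeline orchestration, segmentation, report tables and cohort summaries.

Runs simulate -> AIF -> Logan -> TIA -> dose -> BED -> per-ROI statistics and
writes the report bundle (tables, DVHs, maps, provenance).  Cohort summary
rows use the sample SD (n-1) and midpoint medians; report tables round
half-up to one decimal with full-precision CSVs emitted alongside.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import yaml

from ldvdose import __version__
from ldvdose.aif import extract_aif, fit_aif, therapy_auc
from ldvdose.kinetics import integration_horizon
from ldvdose.logan import ldv_map
from ldvdose.phantom import PhantomSpec, make_phantom, simulate_study
from ldvdose.radiobiology import RadiobioParams, bed_map, dvh, lea_catcheside, roi_stats
from ldvdose.tia_dose import NuclideData, absorbed_dose, normalize_per_gbq, scale_to_cycle, tia_map

__all__ = [
    "SegmentationRule",
    "PipelineConfig",
    "PipelineError",
    "segment_tumor",
    "run_pipeline",
    "summarize_cohort",
    "round_half_up",
]

_REPORT_ROIS = ["tumor", "total_prostate", "normal_prostate", "femur_r", "femur_l"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention of the printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SegmentationRule:
    """Threshold segmentation: keep voxels >= fraction of the parent max."""

    threshold_fraction: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold fraction must be in (0, 1)")


def segment_tumor(
    uptake: np.ndarray,
    parent_roi: np.ndarray,
    rule: SegmentationRule = SegmentationRule(),
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold the uptake map inside a parent ROI.

    Returns ``(tumor_roi, normal_roi)`` where the normal ROI is the parent
    minus the segmented tumor.  An empty segmentation result is returned
    (with a warning) rather than raised.
    """
    parent = np.asarray(parent_roi, dtype=bool)
    if not parent.any():
        raise ValueError("parent ROI is empty")
    u = np.asarray(uptake, dtype=float)
    if u.shape != parent.shape:
        raise ValueError("uptake map and parent ROI must share geometry")
    cut = rule.threshold_fraction * u[parent].max()
    tumor = parent & (u >= cut)
    if not tumor.any():  # pragma: no cover - only for all-negative uptake
        import warnings

        warnings.warn("tumor segmentation is empty", stacklevel=2)
    return tumor, parent & ~tumor


@dataclass(frozen=True)
class PipelineConfig:
    """Full-pipeline configuration (phantom-driven by default).

    Activities in GBq; ``diag_decay_corrected`` states whether the dynamic
    images (and hence the extracted arterial curve) are already corrected
    for the diagnostic tracer's physical decay, in which case no decay is
    removed before applying the therapeutic nuclide's decay.
    """

    seed: int = 0
    noise_level: float = 0.0
    grid_shape: tuple[int, int, int] = (64, 64, 20)
    diagnostic_activity_GBq: float = 0.325
    therapy_activity_GBq: float = 7.4
    cycle_activity_GBq: float = 7.4
    diagnostic_nuclide: str = "f18"
    therapy_nuclide: str = "lu177"
    diag_decay_corrected: bool = True
    n_exp: int = 2
    #: population terminal clearance (min^-1) replacing the slowest fitted
    #: rate beyond the scan window; None keeps the fitted rate
    r_pop_per_min: float | None = 8.0e-4
    engine_mode: str = "local"
    delay_window_min: tuple[float, float] = (2.33, 8.0)
    segmentation: SegmentationRule = SegmentationRule()
    radiobio: RadiobioParams = RadiobioParams()
    out_dir: str = "ldvdose_out"

    def __post_init__(self) -> None:
        for name in ("diagnostic_activity_GBq", "therapy_activity_GBq", "cycle_activity_GBq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "radiobio" in d:
            d["radiobio"] = RadiobioParams(**d["radiobio"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationRule(**d["segmentation"])
        for key in ("grid_shape", "delay_window_min"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """In-memory results plus the paths of everything written."""

    config: PipelineConfig
    stats: dict[str, pd.DataFrame]
    tables: dict[str, str]
    maps: dict[str, np.ndarray]
    rois: dict[str, np.ndarray]
    auc_ther: float
    provenance: dict


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Execute the full phantom pipeline and write the report bundle.

    Stages: phantom simulation, arterial extraction/fit and therapy AUC,
    voxel-wise Logan maps, tumor segmentation, TIA, absorbed dose (per cycle
    and per GBq), BED, and per-ROI tables/DVHs.  Every run is deterministic
    given the config seed and writes a provenance sidecar.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)

    # --- simulate -----------------------------------------------------------
    spec = dataclasses.replace(
        PhantomSpec(), shape=cfg.grid_shape, seed=cfg.seed, noise_level=cfg.noise_level
    )
    try:
        phantom = make_phantom(spec)
        study = simulate_study(phantom, spec)
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    # --- aif ----------------------------------------------------------------
    try:
        nd_diag = NuclideData.from_library(cfg.diagnostic_nuclide)
        nd_ther = NuclideData.from_library(cfg.therapy_nuclide)
        curve = extract_aif(study, phantom.rois["artery"])
        fit = fit_aif(curve, n_exp=cfg.n_exp)
        lam_diag = 0.0 if cfg.diag_decay_corrected else nd_diag.lam_per_min
        terminal_rate = cfg.r_pop_per_min or float(fit.rates_per_min.min())
        t_bio_min = float(np.log(2.0) / terminal_rate)
        t_phys_min = float(np.log(2.0) / nd_ther.lam_per_min)
        horizon_s = integration_horizon(t_phys_min, t_bio_min) * 60.0
        auc_ther = therapy_auc(
            fit,
            lam_diag=lam_diag,
            lam_ther=nd_ther.lam_per_min,
            A_diag_GBq=cfg.diagnostic_activity_GBq,
            A_ther_GBq=cfg.therapy_activity_GBq,
            horizon_s=horizon_s,
            r_pop_per_min=cfg.r_pop_per_min,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'aif' failed: {exc}") from exc

    # --- logan --------------------------------------------------------------
    try:
        analyze = np.ones(phantom.labels.shape, dtype=bool)
        pm = ldv_map(study, curve, analyze, phantom.density,
                     delay_grid_min=None)
    except Exception as exc:
        raise PipelineError(f"stage 'logan' failed: {exc}") from exc

    # --- segmentation -------------------------------------------------------
    try:
        uptake = study.data[..., -4:].mean(axis=-1)  # late-frame uptake
        tumor_roi, normal_roi = segment_tumor(
            uptake, phantom.rois["prostate"], cfg.segmentation
        )
        rois = {
            "tumor": tumor_roi,
            "total_prostate": phantom.rois["prostate"],
            "normal_prostate": normal_roi,
            "femur_r": phantom.rois["femur_r"],
            "femur_l": phantom.rois["femur_l"],
        }
    except Exception as exc:
        raise PipelineError(f"stage 'segment' failed: {exc}") from exc

    # --- tia / dose / bed ---------------------------------------------------
    try:
        tia = tia_map(pm, phantom.density, study.voxel_volume_mL, auc_ther)
        dose_cycle = absorbed_dose(
            tia, phantom.density, nd_ther, mode=cfg.engine_mode,
            voxel_size_mm=spec.voxel_size_mm,
        )
        dose_per_gbq = normalize_per_gbq(dose_cycle, cfg.therapy_activity_GBq)
        dose_cycle = scale_to_cycle(dose_per_gbq, cfg.cycle_activity_GBq)
        bmap = bed_map(dose_cycle, cfg.radiobio)
    except Exception as exc:
        raise PipelineError(f"stage 'dose' failed: {exc}") from exc

    # --- report -------------------------------------------------------------
    try:
        quantity_maps = {
            "ldv_mL_per_g": pm.ldv,
            "dose_Gy_per_cycle": dose_cycle.values,
            "dose_Gy_per_GBq": dose_per_gbq.values,
            "bed_Gy": bmap.values,
        }
        stats: dict[str, pd.DataFrame] = {}
        tables: dict[str, str] = {}
        for qname, arr in quantity_maps.items():
            rows = {}
            for rname in _REPORT_ROIS:
                vals = np.nan_to_num(arr, nan=0.0)
                rows[rname] = roi_stats(vals, rois[rname])
            df = pd.DataFrame(rows)
            stats[qname] = df
            raw_path = os.path.join(cfg.out_dir, f"stats_{qname}.csv")
            df.to_csv(raw_path)
            rounded = df.map(lambda v: round_half_up(v, 1) if isinstance(v, float) else v)
            path = os.path.join(cfg.out_dir, f"table_{qname}.csv")
            rounded.to_csv(path)
            tables[qname] = path
        for rname in _REPORT_ROIS:
            edges, frac = dvh(dose_cycle.values, rois[rname])
            pd.DataFrame({"dose_Gy": edges, "volume_fraction": frac}).to_csv(
                os.path.join(cfg.out_dir, f"dvh_{rname}.csv"), index=False
            )
        provenance = {
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "auc_ther_Bq_s_per_mL": float(auc_ther),
            "lea_catcheside_G": lea_catcheside(cfg.radiobio),
            "tia_total_Bq_s": tia.total,
            "n_flagged_voxels": tia.n_flagged,
            "n_clamped_voxels": tia.n_clamped,
            "dose_engine": dose_cycle.provenance,
        }
        with open(os.path.join(cfg.out_dir, "provenance.json"), "w") as fh:
            json.dump(provenance, fh, indent=2, default=float)
    except Exception as exc:
        raise PipelineError(f"stage 'report' failed: {exc}") from exc

    return ReportBundle(
        config=cfg,
        stats=stats,
        tables=tables,
        maps=quantity_maps,
        rois=rois,
        auc_ther=auc_ther,
        provenance=provenance,
    )


def summarize_cohort(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary rows over a subjects x regions table.

    Returns mean, sample SD (n-1, NaN for a single subject), COV in percent,
    median (midpoint of central order statistics), and the range endpoints.
    """
    df = pd.DataFrame(per_subject).astype(float)
    if df.shape[0] < 1:
        raise ValueError("need at least one subject")
    mean = df.mean(axis=0)
    sd = df.std(axis=0, ddof=1)
    out = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "cov_pct": 100.0 * sd / mean,
            "median": df.median(axis=0),
            "min": df.min(axis=0),
            "max": df.max(axis=0),
        }
    ).T
    return out
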