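"""Time-integrated activity maps and the kernel/local absorbed-dose engine.

The voxel TIA is the Logan distribution volume times tissue mass times the
therapy-scaled arterial AUC.  Dose conversion offers two surrogate engines
for the external Monte Carlo stage: pure local energy deposition, or
convolution with a voxelized radial electron kernel (cross-fire), both with
explicit energy bookkeeping.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from ldvdose.logan import ParametricMaps

__all__ = [
    "NuclideData",
    "TIAMap",
    "DoseMap",
    "tia_map",
    "hu_to_density",
    "absorbed_dose",
    "normalize_per_gbq",
    "scale_to_cycle",
]

MEV_TO_J = 1.602176634e-13

#: two-segment HU -> density calibration anchors (HU, g/mL)
_HU_CAL = ((-1000.0, 0.001), (0.0, 1.0), (3000.0, 2.8))
_DENSITY_CLIP = (0.001, 3.0)


@dataclass(frozen=True)
class NuclideData:
    """Physical data for one radionuclide (bundled constants, version 1)."""

    name: str
    half_life_days: float
    mean_electron_MeV: float
    mean_photon_MeV: float = 0.0
    kernel_radii_mm: np.ndarray | None = None
    kernel_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError("half-life must be positive")
        if self.mean_electron_MeV < 0 or self.mean_photon_MeV < 0:
            raise ValueError("energies must be >= 0")

    @property
    def lam_per_day(self) -> float:
        return float(np.log(2.0) / self.half_life_days)

    @property
    def lam_per_min(self) -> float:
        return self.lam_per_day / (24.0 * 60.0)

    @classmethod
    def from_library(cls, name: str) -> "NuclideData":
        root = importlib.resources.files("ldvdose") / "data"
        lib = yaml.safe_load((root / "nuclides.yaml").read_text())
        try:
            entry = lib["nuclides"][name]
        except KeyError as exc:
            raise KeyError(f"unknown nuclide {name!r} in bundled library") from exc
        radii = weights = None
        if entry.get("kernel_csv"):
            arr = np.loadtxt(
                (root / entry["kernel_csv"]).open("r"), delimiter=",", skiprows=1
            )
            radii, weights = arr[:, 0], arr[:, 1]
        return cls(
            name=name,
            half_life_days=float(entry["half_life_days"]),
            mean_electron_MeV=float(entry["mean_electron_MeV"]),
            mean_photon_MeV=float(entry.get("mean_photon_MeV", 0.0)),
            kernel_radii_mm=radii,
            kernel_weights=weights,
        )

    def data_hash(self) -> str:
        payload = json.dumps(
            {
                "name": self.name,
                "half_life_days": self.half_life_days,
                "mean_electron_MeV": self.mean_electron_MeV,
                "mean_photon_MeV": self.mean_photon_MeV,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class TIAMap:
    """Per-voxel time-integrated activity, Bq s."""

    values: np.ndarray
    voxel_volume_mL: float
    n_flagged: int = 0
    n_clamped: int = 0

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("TIA values must be >= 0")

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class DoseMap:
    """Per-voxel absorbed dose, Gy, with engine provenance."""

    values: np.ndarray
    voxel_volume_mL: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("dose values must be >= 0")


def tia_map(
    pm: ParametricMaps,
    density: np.ndarray,
    voxel_volume_mL: float,
    auc_ther: float,
) -> TIAMap:
    """Voxel TIA = LDV (mL/g) x rho (g/mL) x voxel volume (mL) x AUC (Bq s/mL).

    Unanalyzable voxels contribute zero (counted in ``n_flagged``); negative
    fitted slopes are clamped to zero (counted in ``n_clamped``).
    """
    if auc_ther <= 0:
        raise ValueError("therapy AUC must be positive")
    density = np.asarray(density, dtype=float)
    if density.shape != pm.ldv.shape:
        raise ValueError("density and parametric maps must share geometry")
    analyzed = pm.analyzed.astype(bool)
    ldv = np.where(analyzed, pm.ldv, 0.0)
    n_clamped = int(np.sum(analyzed & (ldv < 0)))
    ldv = np.maximum(ldv, 0.0)
    values = ldv * density * voxel_volume_mL * auc_ther
    return TIAMap(
        values=values,
        voxel_volume_mL=voxel_volume_mL,
        n_flagged=int(np.sum(~analyzed)),
        n_clamped=n_clamped,
    )


def hu_to_density(ct_hu: np.ndarray) -> np.ndarray:
    """Two-segment piecewise-linear CT-number calibration, g/mL.

    Anchored at air (-1000 HU, 0.001), water (0 HU, 1.0) and a bone segment
    through (3000 HU, 2.8); output clipped to [0.001, 3.0].
    """
    hu = np.asarray(ct_hu, dtype=float)
    (h0, d0), (h1, d1), (h2, d2) = _HU_CAL
    soft = d0 + (hu - h0) * (d1 - d0) / (h1 - h0)
    bone = d1 + (hu - h1) * (d2 - d1) / (h2 - h1)
    rho = np.where(hu <= h1, soft, bone)
    return np.clip(rho, *_DENSITY_CLIP)


def _voxelize_kernel(
    radii_mm: np.ndarray,
    weights: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
) -> np.ndarray:
    """Sample the radial profile at voxel-center offsets and normalize to 1.

    Normalization makes the kernel carry exactly the nuclide's represented
    energy per decay, so total energy is conserved by construction.
    """
    r_max = float(radii_mm[-1])
    half = [max(1, int(np.ceil(r_max / s))) for s in voxel_size_mm]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, voxel_size_mm)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    r = np.sqrt(gx**2 + gy**2 + gz**2)
    k = np.interp(r, radii_mm, weights, right=0.0)
    total = k.sum()
    if total <= 0:
        raise ValueError("kernel table yields an empty voxelized kernel")
    return k / total


def absorbed_dose(
    tia: TIAMap,
    density: np.ndarray,
    nd: NuclideData,
    mode: str = "local",
    voxel_size_mm: tuple[float, float, float] = (3.27, 3.27, 3.27),
    include_photons: bool = False,
) -> DoseMap:
    """Convert a TIA map to absorbed dose, Gy.

    ``local`` deposits the mean electron energy per decay in the source
    voxel: ``D = TIA x E_e / m_voxel``.  ``kernel`` first spreads each
    voxel's decays with a voxelized radial kernel (cross-fire), then divides
    the deposited energy by the local voxel mass.  Photons are ignored unless
    ``include_photons`` (coarse: added to the kernel energy uniformly at the
    source voxel), and this is recorded in provenance.
    """
    density = np.asarray(density, dtype=float)
    if density.shape != tia.values.shape:
        raise ValueError("TIA and density maps must share geometry")
    if np.any(density <= 0):
        raise ValueError("zero or negative mass voxels in density map")

    energy_MeV = nd.mean_electron_MeV + (nd.mean_photon_MeV if include_photons else 0.0)
    mass_kg = density * tia.voxel_volume_mL * 1e-3  # g/mL * mL -> g -> kg via 1e-3
    if mode == "local":
        energy_J = tia.values * energy_MeV * MEV_TO_J
    elif mode == "kernel":
        if nd.kernel_radii_mm is None:
            raise ValueError(f"nuclide {nd.name!r} has no kernel table")
        k = _voxelize_kernel(nd.kernel_radii_mm, nd.kernel_weights, voxel_size_mm)
        spread = ndimage.convolve(tia.values, k, mode="constant", cval=0.0)
        energy_J = spread * energy_MeV * MEV_TO_J
    else:
        raise ValueError("mode must be 'local' or 'kernel'")

    dose = energy_J / mass_kg
    return DoseMap(
        values=dose,
        voxel_volume_mL=tia.voxel_volume_mL,
        provenance={
            "engine": mode,
            "nuclide": nd.name,
            "nuclide_data_hash": nd.data_hash(),
            "photons_included": bool(include_photons),
            "energy_per_decay_MeV": energy_MeV,
            "total_energy_J": float(energy_J.sum()),
            "total_tia_Bq_s": tia.total,
        },
    )


def normalize_per_gbq(dose: DoseMap, administered_GBq: float) -> DoseMap:
    """Rescale a per-cycle dose map to Gy/GBq of administered activity."""
    if administered_GBq <= 0:
        raise ValueError("administered activity must be positive")
    prov = dict(dose.provenance)
    prov["normalized_per_GBq"] = administered_GBq
    return DoseMap(dose.values / administered_GBq, dose.voxel_volume_mL, prov)


def scale_to_cycle(dose_per_gbq: DoseMap, cycle_activity_GBq: float) -> DoseMap:
    """Scale a Gy/GBq map to an administered cycle activity (exact inverse
    of :func:`normalize_per_gbq` at the same activity)."""
    if cycle_activity_GBq <= 0:
        raise ValueError("cycle activity must be positive")
    prov = dict(dose_per_gbq.provenance)
    prov["scaled_to_cycle_GBq"] = cycle_activity_GBq
    return DoseMap(dose_per_gbq.values * cycle_activity_GBq,
                   dose_per_gbq.voxel_volume_mL, prov)
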