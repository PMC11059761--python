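"""Quantitative CT gas-volume densitometry.

The reference lung gas volume is obtained from a CT volume in Hounsfield
units over a manually drawn lung mask (large airways excluded): assuming
lung tissue has the density of water, a voxel at -1000 HU is pure gas and
a voxel at 0 HU pure tissue, so its gas fraction is |HU|/1000 and

    gas volume = sum over masked voxels of gas_fraction(HU) * voxel volume.

Two compartments are reported: *total* gas over [-1000, 0] HU and
*functional* gas over [-1000, -200] HU, the latter excluding poorly and
non-aerated regions in which a large shunt fraction is assumed. Both HU
intervals are closed on both ends; voxels outside [-1000, 0] are excluded
from the sums but counted in a QC report.

A seeded phantom generator stands in for patient scans: an ellipsoidal
"lung" whose voxel HUs are drawn from a normal mixture of aeration
compartments and rescaled to a prescribed analytic gas volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

TOTAL_HU = (-1000.0, 0.0)
FUNCTIONAL_HU = (-1000.0, -200.0)

#: Default aeration compartments: (mean HU, SD HU) for normally aerated,
#: poorly aerated and non-aerated tissue.
DEFAULT_COMPARTMENTS = ((-750.0, 50.0), (-300.0, 60.0), (-50.0, 30.0))
DEFAULT_MIX = (0.7, 0.2, 0.1)


class EmptyMaskError(ValueError):
    """The lung mask selects no voxels."""


class PhantomError(ValueError):
    """The requested phantom gas volume is infeasible for the mask."""


@dataclass
class VoxelVolume:
    """HU grid with voxel dimensions [mm] and a lung mask.

    When an ``airway_mask`` is given it is subtracted from the lung mask,
    mirroring the manual exclusion of trachea and major bronchi.
    """

    hu: np.ndarray
    voxel_dims: tuple[float, float, float]
    lung_mask: np.ndarray
    airway_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        if self.hu.shape != self.lung_mask.shape:
            raise ValueError("hu and lung_mask shapes differ")
        if any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be positive")
        if self.airway_mask is not None:
            self.airway_mask = np.asarray(self.airway_mask, dtype=bool)
            if self.airway_mask.shape != self.hu.shape:
                raise ValueError("airway_mask shape differs")

    @property
    def voxel_ml(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz / 1000.0

    @property
    def effective_mask(self) -> np.ndarray:
        if self.airway_mask is None:
            return self.lung_mask
        return self.lung_mask & ~self.airway_mask


def gas_fraction(hu: float | np.ndarray) -> float | np.ndarray:
    """Per-voxel gas fraction |HU|/1000, clamped to [0, 1].

    -1000 HU (pure gas) maps to 1, 0 HU (water-density tissue) to 0;
    values outside [-1000, 0] clamp.
    """
    out = np.clip(-np.asarray(hu, dtype=float) / 1000.0, 0.0, 1.0)
    return float(out) if np.isscalar(hu) else out


def gas_volume(
    vol: VoxelVolume,
    hu_lo: float = TOTAL_HU[0],
    hu_hi: float = TOTAL_HU[1],
) -> float:
    """Gas volume [mL] of masked voxels with HU in [hu_lo, hu_hi] (closed)."""
    if hu_lo >= hu_hi:
        raise ValueError("hu_lo must be below hu_hi")
    mask = vol.effective_mask
    if not mask.any():
        raise EmptyMaskError("lung mask selects no voxels")
    hu = vol.hu[mask]
    sel = (hu >= hu_lo) & (hu <= hu_hi)
    return float(np.sum(gas_fraction(hu[sel])) * vol.voxel_ml)


def densitometry_report(vol: VoxelVolume) -> dict:
    """Total and functional gas volumes plus mask/QC bookkeeping."""
    mask = vol.effective_mask
    if not mask.any():
        raise EmptyMaskError("lung mask selects no voxels")
    hu = vol.hu[mask]
    out_of_range = int(np.sum((hu < -1000.0) | (hu > 0.0)))
    return {
        "total_ml": gas_volume(vol, *TOTAL_HU),
        "functional_ml": gas_volume(vol, *FUNCTIONAL_HU),
        "mask_ml": float(mask.sum() * vol.voxel_ml),
        "mask_voxels": int(mask.sum()),
        "excluded_voxels": out_of_range,
    }


def make_phantom(
    target_gas_ml: float,
    shape: tuple[int, int, int] = (56, 56, 44),
    voxel_dims: tuple[float, float, float] = (3.0, 3.0, 5.0),
    mix: Sequence[float] = DEFAULT_MIX,
    compartments: Sequence[tuple[float, float]] = DEFAULT_COMPARTMENTS,
    seed: int | None = None,
) -> VoxelVolume:
    """Seeded CT phantom with a known analytic gas volume.

    An ellipsoidal lung mask (semi-axes 45% of each grid dimension) is
    filled with HU values drawn from the normal mixture of aeration
    compartments, clipped to [-1000, 0], then the per-voxel gas fractions
    are rescaled iteratively until the total gas volume matches
    ``target_gas_ml`` to within one voxel's worth of gas.
    """
    if target_gas_ml <= 0:
        raise PhantomError("target_gas_ml must be positive")
    if len(mix) != len(compartments) or not np.isclose(sum(mix), 1.0):
        raise PhantomError("mix must match compartments and sum to 1")
    rng = np.random.default_rng(seed)

    nx, ny, nz = shape
    x, y, z = np.ogrid[:nx, :ny, :nz]
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ax, ay, az = 0.45 * nx, 0.45 * ny, 0.45 * nz
    mask = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    voxel_ml = voxel_dims[0] * voxel_dims[1] * voxel_dims[2] / 1000.0
    capacity_ml = mask.sum() * voxel_ml
    if target_gas_ml >= capacity_ml:
        raise PhantomError(
            f"target {target_gas_ml:.0f} mL exceeds mask gas capacity "
            f"{capacity_ml:.0f} mL"
        )

    n_mask = int(mask.sum())
    comp = rng.choice(len(mix), size=n_mask, p=np.asarray(mix, dtype=float))
    means = np.array([c[0] for c in compartments])
    sds = np.array([c[1] for c in compartments])
    hu_vals = np.clip(rng.normal(means[comp], sds[comp]), -1000.0, 0.0)

    g = -hu_vals / 1000.0
    for _ in range(60):
        current_ml = float(g.sum() * voxel_ml)
        if abs(current_ml - target_gas_ml) <= voxel_ml:
            break
        g = np.clip(g * (target_gas_ml / current_ml), 0.0, 1.0)
    else:
        raise PhantomError("could not reach target gas volume (mix too extreme)")

    hu = np.zeros(shape)
    hu[~mask] = 60.0  # soft tissue outside the lung
    hu[mask] = -1000.0 * g
    return VoxelVolume(hu=hu, voxel_dims=tuple(voxel_dims), lung_mask=mask)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_nifti(
    image_path: str, mask_path: str, airway_path: str | None = None
) -> VoxelVolume:
    """Load an HU image and mask(s) from NIfTI (or .npz array) files."""
    import nibabel as nib

    def load(path: str) -> tuple[np.ndarray, tuple[float, float, float] | None]:
        if path.endswith(".npz"):
            with np.load(path) as npz:
                arr = npz[npz.files[0]]
                dims = tuple(npz["voxel_dims"]) if "voxel_dims" in npz.files else None
            return np.asarray(arr), dims
        img = nib.load(path)
        return np.asarray(img.dataobj, dtype=float), tuple(img.header.get_zooms()[:3])

    hu, dims = load(image_path)
    mask, _ = load(mask_path)
    airway = load(airway_path)[0] if airway_path else None
    if dims is None:
        raise ValueError("voxel dimensions missing from image container")
    return VoxelVolume(
        hu=hu, voxel_dims=dims, lung_mask=mask.astype(bool),
        airway_mask=None if airway is None else airway.astype(bool),
    )


def write_report(report: dict, path: str, provenance: dict | None = None) -> None:
    payload = dict(report)
    if provenance:
        payload["provenance"] = provenance
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
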