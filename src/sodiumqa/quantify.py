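"""ROI statistics, SNR, and regression-based sodium quantification.

The calibration follows the noise-anchored scheme used for tissue sodium
concentration (TSC) mapping: circular ROIs at the centers of the four large
vials give mean intensities for the known concentrations (77, 38.5, 19.25,
9.625 mM), the pooled background magnitude mean serves as a 0 mM point, and
an unweighted ordinary-least-squares line ``intensity = slope * C +
intercept`` converts the image to a concentration map.  The background mean
on a magnitude image is Rician/Rayleigh biased; this matches scanner
practice and is documented rather than corrected.

SNR is defined as the mean intensity in the large 77 mM vial divided by the
standard deviation of the pooled background magnitude voxels (no Rician
correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantom import ROI_DIAMETERS, DigitalPhantom
from .recon import ReconImage

__all__ = [
    "ROI",
    "ROISet",
    "CalibrationFit",
    "ConcentrationMap",
    "place_rois",
    "roi_statistics",
    "measure_snr",
    "fit_calibration",
    "concentration_map",
    "estimate_vial_concentrations",
]

NOISE_ROI_DIAMETER = 0.0225  # m
#: background ROI centers as fractions of the FOV from the center, in-plane
NOISE_ROI_FRACTIONS = ((0.35, 0.35), (-0.35, 0.35), (-0.35, -0.35), (0.35, -0.35))


@dataclass(frozen=True)
class ROI:
    """A circular in-plane ROI on one axial slice."""

    label: str
    center_voxel: tuple[int, int]
    diameter: float           # m
    slice_index: int

    def mask_2d(self, shape_xy, voxel_size) -> np.ndarray:
        """Boolean in-plane mask: voxel centers within the ROI radius."""
        nx, ny = shape_xy
        ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        dx = (ix - self.center_voxel[0]) * voxel_size
        dy = (iy - self.center_voxel[1]) * voxel_size
        r = 0.5 * self.diameter
        return dx ** 2 + dy ** 2 <= r ** 2 * (1.0 + 1e-9)


@dataclass
class ROISet:
    """Vial ROIs plus the four background (noise) ROIs of one slice."""

    vial_rois: list[ROI]
    noise_rois: list[ROI]
    slice_index: int
    voxel_size: float
    grid_shape: tuple[int, int, int]

    def vial(self, label: str) -> ROI:
        for roi in self.vial_rois:
            if roi.label == label:
                return roi
        raise KeyError(label)


@dataclass
class CalibrationFit:
    """OLS line intensity = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    calibration_points: list[tuple[float, float]]  # (mM, mean intensity)


@dataclass
class ConcentrationMap:
    """Voxelwise concentration [mM]; negative values are preserved."""

    values: np.ndarray
    voxel_size: float
    provenance: str = ""


def _voxel_index(coord: float, n: int, voxel: float) -> int:
    # inverse of the voxel-center convention x = (i - n//2) * voxel
    return int(round(coord / voxel)) + n // 2


def place_rois(phantom: DigitalPhantom, image: ReconImage | None = None,
               grid_shape=None, voxel_size: float | None = None) -> ROISet:
    """Automatic ROI placement on the central axial slice of the image grid.

    One circular ROI per vial, centered at the vial center (12 mm diameter
    for large vials, 8 mm for the others), plus four 22.5 mm background ROIs
    near the corners of the FOV.  Raises if an ROI does not fit inside its
    vial footprint or a background ROI touches any vial.
    """
    if image is not None:
        grid_shape = image.grid_shape
        voxel_size = image.voxel_size
    if grid_shape is None or voxel_size is None:
        raise ValueError("provide an image or an explicit grid")
    if not phantom.vials:
        raise ValueError("phantom has no vials")
    nx, ny, nz = grid_shape
    slice_index = nz // 2  # z = 0 plane under the voxel-center convention

    vial_rois = []
    for v in phantom.vials:
        diameter = ROI_DIAMETERS[v.size_class]
        cx = _voxel_index(v.center[0], nx, voxel_size)
        cy = _voxel_index(v.center[1], ny, voxel_size)
        roi = ROI(label=v.label, center_voxel=(cx, cy), diameter=diameter,
                  slice_index=slice_index)
        # every ROI voxel center must lie inside the vial cylinder
        mask = roi.mask_2d((nx, ny), voxel_size)
        ix, iy = np.nonzero(mask)
        x = (ix - nx // 2) * voxel_size
        y = (iy - ny // 2) * voxel_size
        inside = ((x - v.center[0]) ** 2 + (y - v.center[1]) ** 2
                  <= v.radius ** 2 * (1.0 + 1e-9))
        if not mask.any() or not inside.all():
            raise ValueError(
                f"ROI for vial {v.label!r} exceeds the vial footprint "
                f"(diameter {diameter * 1e3:.0f} mm vs vial "
                f"{v.inner_diameter * 1e3:.0f} mm at voxel "
                f"{voxel_size * 1e3:.2f} mm)")
        vial_rois.append(roi)

    fov_x = nx * voxel_size
    noise_rois = []
    for i, (fx, fy) in enumerate(NOISE_ROI_FRACTIONS):
        cx = _voxel_index(fx * fov_x, nx, voxel_size)
        cy = _voxel_index(fy * fov_x, ny, voxel_size)
        roi = ROI(label=f"noise_{i}", center_voxel=(cx, cy),
                  diameter=NOISE_ROI_DIAMETER, slice_index=slice_index)
        mask = roi.mask_2d((nx, ny), voxel_size)
        ix, iy = np.nonzero(mask)
        x = (ix - nx // 2) * voxel_size
        y = (iy - ny // 2) * voxel_size
        for v in phantom.vials:
            if np.any((x - v.center[0]) ** 2 + (y - v.center[1]) ** 2
                      <= v.radius ** 2):
                raise ValueError(f"background ROI {i} overlaps vial {v.label!r}")
        noise_rois.append(roi)

    return ROISet(vial_rois=vial_rois, noise_rois=noise_rois,
                  slice_index=slice_index, voxel_size=float(voxel_size),
                  grid_shape=tuple(grid_shape))


def _roi_values(volume: np.ndarray, roi: ROI, voxel_size: float) -> np.ndarray:
    plane = volume[:, :, roi.slice_index]
    mask = roi.mask_2d(plane.shape, voxel_size)
    vals = plane[mask]
    if vals.size == 0:
        raise ValueError(f"ROI {roi.label!r} contains no voxels")
    return vals


def roi_statistics(image: ReconImage, rois: ROISet) -> pd.DataFrame:
    """Mean/SD/voxel count per ROI on the magnitude image.

    The four noise ROIs are additionally pooled into a single ``background``
    row (the sample used for the SNR denominator and the 0 mM anchor).
    """
    if tuple(image.grid_shape) != tuple(rois.grid_shape):
        raise ValueError("image grid does not match the ROI grid")
    rows = []
    for roi in rois.vial_rois + rois.noise_rois:
        vals = _roi_values(image.magnitude, roi, rois.voxel_size)
        rows.append({"label": roi.label, "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     "n_voxels": int(vals.size)})
    pooled = np.concatenate([
        _roi_values(image.magnitude, roi, rois.voxel_size)
        for roi in rois.noise_rois])
    rows.append({"label": "background", "mean": float(pooled.mean()),
                 "sd": float(pooled.std(ddof=1)), "n_voxels": int(pooled.size)})
    return pd.DataFrame(rows)


def background_values(image: ReconImage, rois: ROISet) -> np.ndarray:
    """Pooled background magnitude voxels from the four noise ROIs."""
    return np.concatenate([
        _roi_values(image.magnitude, roi, rois.voxel_size)
        for roi in rois.noise_rois])


def measure_snr(image: ReconImage, rois: ROISet,
                signal_label: str = "L_77") -> float:
    """Image SNR: mean of the signal ROI over the pooled background SD.

    Returns ``inf`` (flagged by the caller as a noiseless acquisition) when
    the background SD is zero.  No Rician correction is applied.
    """
    signal = _roi_values(image.magnitude, rois.vial(signal_label),
                         rois.voxel_size).mean()
    noise_sd = background_values(image, rois).std(ddof=1)
    if noise_sd == 0:
        return float("inf")
    return float(signal / noise_sd)


def fit_calibration(roi_table: pd.DataFrame,
                    known_concentrations: dict[str, float],
                    noise_anchor: str = "pooled") -> CalibrationFit:
    """OLS calibration line from large-vial means plus the 0 mM noise anchor.

    ``known_concentrations`` maps ROI labels to mM (the four large vials);
    the background mean is appended as a 0 mM point (``noise_anchor``:
    "pooled" uses the pooled four background ROIs, "single" the first one).
    """
    table = roi_table.set_index("label")
    concs = []
    intensities = []
    for label, c in known_concentrations.items():
        concs.append(float(c))
        intensities.append(float(table.loc[label, "mean"]))
    anchor_label = "background" if noise_anchor == "pooled" else "noise_0"
    concs.append(0.0)
    intensities.append(float(table.loc[anchor_label, "mean"]))
    if len(set(concs)) < 2:
        raise ValueError("need at least two distinct concentrations to fit")
    fit = stats.linregress(concs, intensities)
    return CalibrationFit(slope=float(fit.slope),
                          intercept=float(fit.intercept),
                          r_squared=float(fit.rvalue ** 2),
                          calibration_points=list(zip(concs, intensities)))


def concentration_map(image: ReconImage, fit: CalibrationFit) -> ConcentrationMap:
    """Invert the calibration line voxelwise: C = (I - intercept)/slope.

    Negative concentrations (noise below the intercept) are preserved; they
    are informative for the low-concentration small vials.
    """
    if fit.slope == 0:
        raise ValueError("calibration slope is zero")
    values = (image.magnitude - fit.intercept) / fit.slope
    return ConcentrationMap(values=values, voxel_size=image.voxel_size,
                            provenance=image.provenance + "|calibrated")


def estimate_vial_concentrations(cmap: ConcentrationMap,
                                 rois: ROISet) -> pd.DataFrame:
    """Per-vial ROI-mean estimated concentrations [mM]."""
    rows = []
    for roi in rois.vial_rois:
        vals = _roi_values(cmap.values, roi, rois.voxel_size)
        rows.append({"label": roi.label,
                     "estimated_mM": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     "n_voxels": int(vals.size)})
    return pd.DataFrame(rows)
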