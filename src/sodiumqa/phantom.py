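"""Digital dilution phantom for quantitative sodium MRI QA.

The physical object being modelled is a set of NaCl-filled plastic vials of
three sizes (nominally 50 / 15 / 7 mL) arranged symmetrically on a ring, with
a central pure-saline reference vial at physiological concentration (154 mM).
Each size class carries the same four concentrations obtained by sequential
two-fold dilution of saline, so the phantom spans both the concentration and
the spatial-resolution axes of a quantification experiment.

The digital version rasterizes the vial registry onto a voxel grid, producing
a ground-truth concentration volume (mM) plus per-vial labels and relaxation
parameters that the k-space simulator consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VialSpec",
    "RelaxationParams",
    "DigitalPhantom",
    "PhantomConfig",
    "SALINE_RELAXATION",
    "AGAROSE_RELAXATION",
    "dilution_series",
    "build_phantom",
    "rasterize",
]

SIZE_CLASSES = ("large", "medium", "small")

#: Inner diameter and inner length [m] per size class.  The small-vial inner
#: diameter (1 cm) and length (8.5 cm) are the manufacturer values; the large
#: and medium dimensions are standard 50 mL / 15 mL conical-tube geometry
#: chosen to match the stated fill volumes, and are config-overridable.
DEFAULT_VIAL_DIMENSIONS: dict[str, tuple[float, float]] = {
    "large": (0.028, 0.110),
    "medium": (0.015, 0.118),
    "small": (0.010, 0.085),
}

#: ROI diameters used downstream for quantification [m]: 12 mm for large
#: vials, 8 mm for the others.
ROI_DIAMETERS: dict[str, float] = {"large": 0.012, "medium": 0.008, "small": 0.008}


@dataclass(frozen=True)
class RelaxationParams:
    """Bi-exponential transverse relaxation plus longitudinal T1.

    Sodium transverse decay in tissue-like media is bi-exponential with a fast
    component of a few ms (weight ``fast_fraction``) and a slow component of
    tens of ms.  Aqueous saline is effectively mono-exponential; set
    ``fast_fraction = 0`` (then ``t2_fast`` is inert).

    All times in seconds.
    """

    t1: float
    t2_fast: float
    t2_slow: float
    fast_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2_fast <= 0 or self.t2_slow <= 0:
            raise ValueError("relaxation times must be positive")
        if self.t2_fast > self.t2_slow:
            raise ValueError("t2_fast must not exceed t2_slow")
        if not 0.0 <= self.fast_fraction <= 1.0:
            raise ValueError("fast_fraction must lie in [0, 1]")


#: Aqueous saline at 3 T: mono-exponential T2, short sodium T1.
SALINE_RELAXATION = RelaxationParams(t1=0.060, t2_fast=0.050, t2_slow=0.050,
                                     fast_fraction=0.0)

#: Agarose-doped preset mimicking tissue-like bi-exponential sodium decay.
AGAROSE_RELAXATION = RelaxationParams(t1=0.060, t2_fast=0.003, t2_slow=0.025,
                                      fast_fraction=0.6)


@dataclass(frozen=True)
class VialSpec:
    """A single cylindrical vial: geometry plus nominal concentration [mM]."""

    label: str
    size_class: str
    nominal_concentration: float
    center: tuple[float, float, float]
    inner_diameter: float
    length: float
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")
        if self.nominal_concentration < 0:
            raise ValueError("nominal_concentration must be >= 0")
        if self.inner_diameter <= 0 or self.length <= 0:
            raise ValueError("vial dimensions must be positive")
        a = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(a), 1.0, atol=1e-9):
            raise ValueError("axis must be a unit vector")

    @property
    def radius(self) -> float:
        return 0.5 * self.inner_diameter


@dataclass
class PhantomConfig:
    """Layout parameters for :func:`build_phantom`.

    The default reproduces the reference design: four concentrations from a
    four-step dilution of 154 mM saline, each present in all three vial sizes,
    the 12 ring vials evenly spaced (30 degree steps, size classes
    interleaved) on a 5 cm-radius circle, and a central small 154 mM vial.
    """

    stock_concentration: float = 154.0
    dilution_steps: int = 4
    ring_radius: float = 0.05
    fov: tuple[float, float, float] = (0.384, 0.384, 0.384)
    grid_shape: tuple[int, int, int] = (256, 256, 256)
    vial_dimensions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VIAL_DIMENSIONS))
    include_central_reference: bool = True
    relaxation: RelaxationParams = SALINE_RELAXATION
    #: explicit vial list overrides the ring layout entirely
    vials: list[VialSpec] | None = None


@dataclass
class DigitalPhantom:
    """Vial registry plus rasterized ground-truth volumes.

    ``concentration_volume`` holds mM at voxel centers (0 outside all vials);
    ``label_volume`` holds the 1-based vial index (0 = background) so the
    simulator can apply per-vial relaxation.
    """

    vials: list[VialSpec]
    relaxation_by_vial: dict[str, RelaxationParams]
    fov: tuple[float, float, float]
    grid_shape: tuple[int, int, int]
    concentration_volume: np.ndarray
    label_volume: np.ndarray

    @property
    def voxel_size(self) -> np.ndarray:
        return np.asarray(self.fov) / np.asarray(self.grid_shape)

    def vial_by_label(self, label: str) -> VialSpec:
        for v in self.vials:
            if v.label == label:
                return v
        raise KeyError(label)


def dilution_series(stock: float, steps: int) -> list[float]:
    """Concentrations from ``steps`` sequential two-fold dilutions of ``stock``.

    Returns ``[stock/2, stock/4, ..., stock/2**steps]`` (exact halving; the
    reference series 154 -> 77, 38.5, 19.25, 9.625 mM is dyadic and therefore
    floating-point exact).
    """
    if stock <= 0:
        raise ValueError("stock concentration must be positive")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    return [stock / 2 ** (k + 1) for k in range(steps)]


def _vial_label(size_class: str, concentration: float) -> str:
    prefix = size_class[0].upper()
    c = f"{concentration:g}"
    return f"{prefix}_{c}"


def _cylinders_overlap(a: VialSpec, b: VialSpec) -> bool:
    # all axes are +z by construction; overlap = xy-circle and z-extent overlap
    dxy = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
    if dxy >= a.radius + b.radius:
        return False
    dz = abs(a.center[2] - b.center[2])
    return dz < 0.5 * (a.length + b.length)


def build_phantom(config: PhantomConfig | None = None) -> DigitalPhantom:
    """Build and rasterize the digital phantom (deterministic; no RNG).

    The default configuration yields exactly 13 vials: 3 sizes x 4
    concentrations on the ring plus the central 154 mM small reference vial.
    Overlapping vials raise a ``ValueError`` naming the offending pair.
    """
    config = config or PhantomConfig()
    if config.vials is not None:
        vials = list(config.vials)
    else:
        concentrations = dilution_series(config.stock_concentration,
                                         config.dilution_steps)
        vials = []
        n_ring = len(concentrations) * len(SIZE_CLASSES)
        for m in range(n_ring):
            size = SIZE_CLASSES[m % len(SIZE_CLASSES)]
            conc = concentrations[m // len(SIZE_CLASSES)]
            angle = 2.0 * np.pi * m / n_ring
            diameter, length = config.vial_dimensions[size]
            vials.append(VialSpec(
                label=_vial_label(size, conc),
                size_class=size,
                nominal_concentration=conc,
                center=(config.ring_radius * float(np.cos(angle)),
                        config.ring_radius * float(np.sin(angle)),
                        0.0),
                inner_diameter=diameter,
                length=length,
            ))
        if config.include_central_reference:
            diameter, length = config.vial_dimensions["small"]
            vials.append(VialSpec(
                label=f"Centre_{config.stock_concentration:g}",
                size_class="small",
                nominal_concentration=config.stock_concentration,
                center=(0.0, 0.0, 0.0),
                inner_diameter=diameter,
                length=length,
            ))

    labels = [v.label for v in vials]
    if len(set(labels)) != len(labels):
        raise ValueError("vial labels must be unique")
    for i, a in enumerate(vials):
        for b in vials[i + 1:]:
            if _cylinders_overlap(a, b):
                raise ValueError(
                    f"vial layout error: {a.label!r} overlaps {b.label!r}")

    relaxation = {v.label: config.relaxation for v in vials}
    conc, label_vol = rasterize(vials, config.grid_shape, config.fov)
    return DigitalPhantom(
        vials=vials,
        relaxation_by_vial=relaxation,
        fov=tuple(config.fov),
        grid_shape=tuple(config.grid_shape),
        concentration_volume=conc,
        label_volume=label_vol,
    )


def voxel_coordinates(grid_shape, fov) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical coordinates [m] of voxel centers, phantom-centered.

    0-based indices, voxel-center sampling: index i maps to
    ``(i - n//2) * voxel_size`` along each axis, so the phantom center sits
    exactly on the voxel at index ``n//2`` (the FFT-natural convention shared
    by the reconstruction grid).
    """
    grid_shape = np.asarray(grid_shape, dtype=int)
    fov = np.asarray(fov, dtype=float)
    voxel = fov / grid_shape
    axes = [(np.arange(n) - n // 2) * v for n, v in zip(grid_shape, voxel)]
    return tuple(axes)


def rasterize(vials, grid_shape, fov) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize vials onto a voxel grid.

    A voxel takes a vial's concentration iff its center lies inside the vial
    cylinder.  Returns ``(concentration_volume [mM], label_volume)`` where
    labels are 1-based vial indices (0 = background).  Warns when the voxel
    size exceeds the smallest vial radius (geometry badly resolved).
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    fov = tuple(float(f) for f in fov)
    if vials:
        min_radius = min(v.radius for v in vials)
        if max(np.asarray(fov) / np.asarray(grid_shape)) > min_radius:
            warnings.warn(
                "voxel size exceeds the smallest vial radius; rasterization "
                "will be coarse", stacklevel=2)
    xs, ys, zs = voxel_coordinates(grid_shape, fov)
    conc = np.zeros(grid_shape, dtype=float)
    label_vol = np.zeros(grid_shape, dtype=np.int32)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    for idx, v in enumerate(vials, start=1):
        inplane = (X - v.center[0]) ** 2 + (Y - v.center[1]) ** 2 <= v.radius ** 2
        along = np.abs(zs - v.center[2]) <= 0.5 * v.length
        mask = inplane[:, :, None] & along[None, None, :]
        if not mask.any():
            raise ValueError(
                f"vial {v.label!r} rasterizes to an empty voxel set on "
                f"grid {grid_shape}")
        conc[mask] = v.nominal_concentration
        label_vol[mask] = idx
    return conc, label_vol


def with_grid(phantom: DigitalPhantom, grid_shape, fov=None) -> DigitalPhantom:
    """Re-rasterize an existing phantom on a different grid."""
    fov = tuple(fov) if fov is not None else phantom.fov
    conc, label_vol = rasterize(phantom.vials, grid_shape, fov)
    return DigitalPhantom(
        vials=list(phantom.vials),
        relaxation_by_vial=dict(phantom.relaxation_by_vial),
        fov=fov,
        grid_shape=tuple(int(n) for n in grid_shape),
        concentration_volume=conc,
        label_volume=label_vol,
    )
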