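"""Density-compensated gridding reconstruction of 3D radial k-space.

The reconstruction is the adjoint non-uniform Fourier transform: each
density-weighted sample is convolved onto an oversampled Cartesian k-space
grid with a finite-support Kaiser--Bessel kernel, the grid is inverse-FFTed,
the image is deapodized (divided by the kernel's Fourier transform) and
cropped to the nominal reconstruction grid.  An exact (brute-force) adjoint
DFT is provided for validation on small problems; the gridding path is held
to it at the 1e-3 normalized-RMS level.

Repeats are averaged in k-space before gridding, and sessions can be aligned
to a reference by integer-voxel translation maximizing the circular
cross-correlation of the magnitude images.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import i0

from .acquisition import KSpaceDataset, TrajectorySet

__all__ = [
    "ReconParams",
    "ReconImage",
    "AlignmentResult",
    "density_weights",
    "average_repeats",
    "grid_reconstruct",
    "adjoint_dft",
    "align_translation",
]


@dataclass(frozen=True)
class ReconParams:
    """Gridding reconstruction parameters.

    ``recon_resolution`` sets the output voxel size (grid shape =
    round(FOV / resolution) per axis); ``grid_oversampling`` and
    ``kernel_width`` control the gridding accuracy (defaults 2.0 and 4 give
    ~1e-3 aliasing error, the level the oracle test enforces).
    """

    recon_resolution: float = 1.5e-3
    grid_oversampling: float = 2.0
    kernel_width: int = 4
    n_segments: int = 8

    def __post_init__(self) -> None:
        if self.grid_oversampling < 1.0:
            raise ValueError("grid_oversampling must be >= 1")
        if self.kernel_width < 2:
            raise ValueError("kernel_width must be >= 2")

    def grid_shape(self, fov) -> tuple[int, int, int]:
        fov = np.broadcast_to(np.asarray(fov, dtype=float), (3,))
        return tuple(int(round(f / self.recon_resolution)) for f in fov)

    @property
    def kaiser_beta(self) -> float:
        """Beatty et al. optimal Kaiser--Bessel shape parameter."""
        w, os = self.kernel_width, self.grid_oversampling
        return float(np.pi * np.sqrt((w / os) ** 2 * (os - 0.5) ** 2 - 0.8))


@dataclass
class ReconImage:
    """Reconstructed 3D volume on the reconstruction grid."""

    magnitude: np.ndarray
    voxel_size: float
    complex_volume: np.ndarray | None = None
    provenance: str = ""

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.magnitude.shape)


@dataclass
class AlignmentResult:
    shift: tuple[int, int, int]
    aligned: "ReconImage"
    peak_coefficient: float
    low_confidence: bool


def density_weights(trajectory: TrajectorySet) -> np.ndarray:
    """Per-sample density-compensation weights, shape (n_spokes, samples).

    Analytic radial (~k^2) law: the weight of a sample is proportional to
    the k-space shell it represents, the k = 0 sample carrying the central
    Nyquist cell; normalized so the total equals the sampled ball volume.
    The profile is identical for every spoke (a broadcast view is returned).
    """
    return np.broadcast_to(trajectory.density_weights,
                           (trajectory.n_spokes, trajectory.samples_per_spoke))


def average_repeats(dataset: KSpaceDataset) -> KSpaceDataset:
    """Complex mean across repeats; noise SD drops by sqrt(n_repeats)."""
    n = dataset.n_repeats
    if n < 1:
        raise ValueError("dataset has no repeats")
    if n == 1 or np.all(dataset.samples == dataset.samples[0]):
        # identical repeats: return exactly (mean-of-n would round)
        averaged = dataset.samples[:1].copy()
    else:
        averaged = dataset.samples.mean(axis=0, keepdims=True)
    return replace(dataset, samples=averaged,
                   noise_sigma=dataset.noise_sigma / np.sqrt(n),
                   repeat_ids=(0,))


def _kaiser_kernel(du: np.ndarray, width: int, beta: float) -> np.ndarray:
    """KB interpolation kernel I0(beta*sqrt(1-(2u/W)^2)) on |u| <= W/2."""
    arg = 1.0 - (2.0 * du / width) ** 2
    out = np.zeros_like(du)
    inside = arg > 0
    out[inside] = i0(beta * np.sqrt(arg[inside]))
    return out


def _kaiser_apodization(positions: np.ndarray, grid_size: int, width: int,
                        beta: float) -> np.ndarray:
    """Fourier transform of the KB kernel at image positions (grid units)."""
    xi = positions / grid_size
    arg = (np.pi * width * xi) ** 2 - beta ** 2
    t = np.sqrt(arg.astype(complex))
    with np.errstate(invalid="ignore"):
        val = np.where(np.abs(t) < 1e-12, 1.0, np.sin(t) / t)
    return width * val.real


def _grid_samples(u: np.ndarray, values: np.ndarray, grid_size: int,
                  width: int, beta: float) -> np.ndarray:
    """Scatter complex samples onto a centered cubic grid via the KB kernel.

    ``u``: (n, 3) sample positions in oversampled-grid units (centered, i.e.
    0 is the grid center); wrap-around is circular, which is exact for the
    subsequent DFT evaluated at integer image positions.
    """
    g = grid_size
    width_range = np.arange(width)
    base = np.floor(u - width / 2.0).astype(np.int64) + 1  # (n, 3)
    # per-axis kernel values and (wrapped) indices, each (n, width)
    kern = []
    idx = []
    for ax in range(3):
        n_ax = base[:, ax, None] + width_range[None, :]
        kern.append(_kaiser_kernel(n_ax - u[:, ax, None], width, beta))
        idx.append(np.mod(n_ax + g // 2, g))
    acc_r = np.zeros(g ** 3)
    acc_i = np.zeros(g ** 3)
    use_bincount = g ** 3 <= 16 * 2 ** 20
    for ox in range(width):
        wx = kern[0][:, ox]
        ix = idx[0][:, ox] * (g * g)
        for oy in range(width):
            wxy = wx * kern[1][:, oy]
            ixy = ix + idx[1][:, oy] * g
            for oz in range(width):
                w = wxy * kern[2][:, oz]
                flat = ixy + idx[2][:, oz]
                vr = w * values.real
                vi = w * values.imag
                if use_bincount:
                    acc_r += np.bincount(flat, weights=vr, minlength=g ** 3)
                    acc_i += np.bincount(flat, weights=vi, minlength=g ** 3)
                else:
                    np.add.at(acc_r, flat, vr)
                    np.add.at(acc_i, flat, vi)
    return (acc_r + 1j * acc_i).reshape(g, g, g)


def _params_hash(params: ReconParams) -> str:
    return hashlib.sha256(repr(params).encode()).hexdigest()[:12]


def grid_reconstruct(dataset: KSpaceDataset, recon_params: ReconParams | None = None,
                     apply_density_weights: bool = True) -> ReconImage:
    """Density-compensated adjoint-NUFFT (gridding) reconstruction.

    Multi-repeat datasets are averaged in k-space first.  The output image
    approximates ``sum_j w_j S_j exp(+2 pi i k_j . x)`` on the reconstruction
    grid; its magnitude feeds quantification.
    """
    recon_params = recon_params or ReconParams()
    params = dataset.params
    shape = recon_params.grid_shape(params.fov)
    if shape[0] != shape[1] or shape[1] != shape[2]:
        raise ValueError("only isotropic FOVs/grids are supported")
    n = shape[0]
    os_factor = recon_params.grid_oversampling
    g = int(round(n * os_factor))
    width = recon_params.kernel_width
    beta = recon_params.kaiser_beta

    if dataset.n_repeats > 1:
        dataset = average_repeats(dataset)
    traj = dataset.trajectory
    samples = dataset.samples[0].ravel().astype(complex)
    if apply_density_weights:
        samples = samples * density_weights(traj).ravel()

    # sample positions in oversampled-grid units: u = k * fov * os
    k_coords = traj.k_coordinates().reshape(-1, 3)
    u = k_coords * (params.fov * os_factor)
    if np.max(np.abs(u)) > g / 2 + 1e-6:
        raise ValueError("trajectory extends beyond the oversampled grid "
                         "(recon/acquisition parameter mismatch)")
    grid = _grid_samples(u, samples, g, width, beta)

    img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))) * g ** 3
    lo = g // 2 - n // 2
    img = img[lo:lo + n, lo:lo + n, lo:lo + n]

    pos = np.arange(n) - n // 2
    apod = _kaiser_apodization(pos, g, width, beta)
    img = img / (apod[:, None, None] * apod[None, :, None] * apod[None, None, :])

    return ReconImage(
        magnitude=np.abs(img),
        complex_volume=img,
        voxel_size=params.fov / n,
        provenance=f"{dataset.session_id}|recon:{_params_hash(recon_params)}",
    )


def adjoint_dft(dataset: KSpaceDataset, recon_params: ReconParams | None = None,
                apply_density_weights: bool = True) -> ReconImage:
    """Exact (brute-force) adjoint DFT reconstruction for small problems.

    Computes ``sum_j w_j S_j exp(+2 pi i k_j . x_v)`` voxel by voxel; O(N^3
    * n_samples), intended for grids up to ~16^3 as the reference the
    gridding path is validated against.
    """
    from .phantom import voxel_coordinates

    recon_params = recon_params or ReconParams()
    params = dataset.params
    shape = recon_params.grid_shape(params.fov)
    if dataset.n_repeats > 1:
        dataset = average_repeats(dataset)
    samples = dataset.samples[0].ravel().astype(complex)
    if apply_density_weights:
        samples = samples * density_weights(dataset.trajectory).ravel()
    k_coords = dataset.trajectory.k_coordinates().reshape(-1, 3)
    xs, ys, zs = voxel_coordinates(shape, (params.fov,) * 3)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    pos = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    img = np.zeros(pos.shape[0], dtype=complex)
    chunk = 4096
    for start in range(0, pos.shape[0], chunk):
        phase = pos[start:start + chunk] @ k_coords.T
        img[start:start + chunk] = np.exp(2j * np.pi * phase) @ samples
    img = img.reshape(shape)
    return ReconImage(magnitude=np.abs(img), complex_volume=img,
                      voxel_size=params.fov / shape[0],
                      provenance=f"{dataset.session_id}|adjoint_dft")


def align_translation(moving: ReconImage, reference: ReconImage,
                      confidence_threshold: float = 0.2) -> AlignmentResult:
    """Integer-voxel translation registering ``moving`` onto ``reference``.

    Maximizes the circular cross-correlation of the magnitude images (FFT
    based) and applies the shift with ``np.roll``.  The normalized peak
    coefficient (1 for identical aligned images, near 0 for unrelated noise)
    flags degenerate inputs via ``low_confidence``.
    """
    if reference.magnitude.shape != moving.magnitude.shape:
        raise ValueError("images must share a grid shape")
    # mean-subtracted (zero-lag-normalized) correlation: a constant offset
    # must not masquerade as a correlation peak
    a = reference.magnitude - reference.magnitude.mean()
    b = moving.magnitude - moving.magnitude.mean()
    # c[d] = sum_x b(x + d) a(x): peaks at the displacement of moving vs ref
    cc = np.fft.ifftn(np.fft.fftn(b) * np.conj(np.fft.fftn(a))).real
    peak_flat = int(np.argmax(cc))
    shift = np.array(np.unravel_index(peak_flat, a.shape))
    # express as signed shifts in [-n/2, n/2)
    shift = tuple(int(s if s < n // 2 else s - n)
                  for s, n in zip(shift, a.shape))
    norm = float(np.linalg.norm(a) * np.linalg.norm(b))
    peak_coeff = float(cc.ravel()[peak_flat] / norm) if norm > 0 else 0.0
    undo = tuple(-s for s in shift)
    aligned_mag = np.roll(moving.magnitude, undo, axis=(0, 1, 2))
    aligned_cplx = (np.roll(moving.complex_volume, undo, axis=(0, 1, 2))
                    if moving.complex_volume is not None else None)
    aligned = ReconImage(magnitude=aligned_mag, complex_volume=aligned_cplx,
                         voxel_size=moving.voxel_size,
                         provenance=moving.provenance + f"|shift:{shift}")
    return AlignmentResult(shift=shift, aligned=aligned,
                           peak_coefficient=peak_coeff,
                           low_confidence=peak_coeff < confidence_threshold)
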