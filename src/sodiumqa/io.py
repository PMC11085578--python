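"""Persistence: NIfTI-1 images, HDF5 k-space containers, CSV tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acquisition import AcqParams, KSpaceDataset, TrajectorySet
from .quantify import ConcentrationMap
from .recon import ReconImage

__all__ = [
    "write_image",
    "read_image",
    "write_read_image",
    "write_concentration_map",
    "save_kspace",
    "load_kspace",
]

KSPACE_SCHEMA_VERSION = "sodiumqa-kspace-1"


def _check_nifti_path(path: Path) -> None:
    suffixes = "".join(path.suffixes[-2:])
    if not (suffixes.endswith(".nii") or suffixes.endswith(".nii.gz")):
        raise ValueError(
            f"expected a .nii or .nii.gz path, got {path.name!r}")


def write_image(image: ReconImage, path) -> None:
    """Write the magnitude volume as float32 NIfTI-1 with voxel-size header."""
    path = Path(path)
    _check_nifti_path(path)
    vox_mm = image.voxel_size * 1e3
    affine = np.diag([vox_mm, vox_mm, vox_mm, 1.0])
    img = nib.Nifti1Image(image.magnitude.astype(np.float32), affine)
    img.header.set_zooms((vox_mm,) * 3)
    img.header["descrip"] = image.provenance[:79].encode()
    nib.save(img, str(path))


def read_image(path) -> ReconImage:
    path = Path(path)
    _check_nifti_path(path)
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    data = np.asarray(img.dataobj, dtype=np.float32)
    return ReconImage(magnitude=data, voxel_size=float(zooms[0]) * 1e-3,
                      provenance=str(img.header["descrip"].tobytes(), "utf-8",
                                     "ignore").rstrip("\x00"))


def write_read_image(image: ReconImage, path) -> ReconImage:
    """Round-trip an image through NIfTI-1 (float32-exact payload)."""
    write_image(image, path)
    return read_image(path)


def write_concentration_map(cmap: ConcentrationMap, path) -> None:
    vox_mm = cmap.voxel_size * 1e3
    affine = np.diag([vox_mm, vox_mm, vox_mm, 1.0])
    img = nib.Nifti1Image(cmap.values.astype(np.float32), affine)
    img.header.set_zooms((vox_mm,) * 3)
    nib.save(img, str(Path(path)))


def save_kspace(dataset: KSpaceDataset, path) -> None:
    """Persist a k-space dataset (samples, trajectory, params, seed) to HDF5."""
    import dataclasses

    with h5py.File(path, "w") as f:
        f.attrs["schema"] = KSPACE_SCHEMA_VERSION
        f.attrs["noise_sigma"] = dataset.noise_sigma
        f.attrs["seed"] = -1 if dataset.seed is None else dataset.seed
        f.attrs["session_id"] = dataset.session_id
        f.create_dataset("samples", data=dataset.samples,
                         compression="gzip", compression_opts=1)
        f.create_dataset("repeat_ids", data=np.asarray(dataset.repeat_ids))
        t = f.create_group("trajectory")
        t.create_dataset("directions", data=dataset.trajectory.directions)
        t.create_dataset("k_radii", data=dataset.trajectory.k_radii)
        t.create_dataset("sample_times", data=dataset.trajectory.sample_times)
        t.create_dataset("density_weights",
                         data=dataset.trajectory.density_weights)
        t.attrs["kmax"] = dataset.trajectory.kmax
        p = f.create_group("params")
        for fld in dataclasses.fields(AcqParams):
            p.attrs[fld.name] = getattr(dataset.params, fld.name)


def load_kspace(path) -> KSpaceDataset:
    with h5py.File(path, "r") as f:
        schema = f.attrs.get("schema", "")
        if schema != KSPACE_SCHEMA_VERSION:
            raise ValueError(f"unsupported k-space schema {schema!r}")
        params = AcqParams(**{k: v.item() if hasattr(v, "item") else v
                              for k, v in f["params"].attrs.items()})
        t = f["trajectory"]
        trajectory = TrajectorySet(
            directions=t["directions"][...],
            k_radii=t["k_radii"][...],
            sample_times=t["sample_times"][...],
            kmax=float(t.attrs["kmax"]),
            density_weights=t["density_weights"][...])
        seed = int(f.attrs["seed"])
        return KSpaceDataset(
            samples=f["samples"][...], trajectory=trajectory, params=params,
            noise_sigma=float(f.attrs["noise_sigma"]),
            seed=None if seed < 0 else seed,
            session_id=str(f.attrs["session_id"]),
            repeat_ids=tuple(int(r) for r in f["repeat_ids"][...]))
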