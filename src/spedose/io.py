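"""Readers and writers: portable HDF5 container, CSV curves, spectrum files,
JSON contours, YAML configs, and (optional) DICOM.

The portable container is the package's "dose matrix file": a plain HDF5
layout of arrays plus attributes that round-trips grids, masks and dose
bit-exactly.  DICOM support (CT series read, RT-Dose write) requires the
optional ``pydicom`` dependency and raises a clear ImportError without it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .analysis import DepthProfile, DVHCurve
from .geometry import CTSlice, StructureMask, VoxelGrid
from .materials import Material, get_material
from .transport import DoseGrid
from .unfold import Spectrum

__all__ = [
    "save_container", "load_container",
    "write_profile_csv", "read_profile_csv",
    "write_dvh_csv", "write_dvh_table",
    "write_spectrum_file", "read_spectrum_file",
    "read_contours_json", "load_config", "config_hash",
    "read_hu_table", "read_materials_config",
    "read_dicom_ct", "write_rtdose",
]


# ---------------------------------------------------------------------------
# portable HDF5 container
# ---------------------------------------------------------------------------

def _write_material(g, mat: Material):
    g.attrs["name"] = mat.name
    g.attrs["density"] = mat.density
    g.attrs["mean_excitation_energy"] = mat.mean_excitation_energy
    g.attrs["radiation_length"] = mat.radiation_length
    g.attrs["elements"] = json.dumps(mat.composition)


def _read_material(g) -> Material:
    return Material(name=str(g.attrs["name"]),
                    composition=json.loads(g.attrs["elements"]),
                    density=float(g.attrs["density"]),
                    mean_excitation_energy=float(g.attrs["mean_excitation_energy"]),
                    radiation_length=float(g.attrs["radiation_length"]))


def save_container(path, grid: VoxelGrid, masks: dict = None,
                   dose: DoseGrid = None, meta: dict = None):
    """Write a grid (and optionally masks / dose) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        gg = f.create_group("grid")
        gg.attrs["origin"] = grid.origin
        gg.attrs["spacing"] = grid.spacing
        gg.create_dataset("material_index", data=grid.material_index,
                          compression="gzip", compression_opts=4)
        gg.create_dataset("density", data=grid.density,
                          compression="gzip", compression_opts=4)
        gm = gg.create_group("materials")
        for i, mat in enumerate(grid.materials):
            _write_material(gm.create_group(str(i)), mat)
        if masks:
            ms = f.create_group("masks")
            for name, m in masks.items():
                ms.create_dataset(name, data=m.mask, compression="gzip")
        if dose is not None:
            dg = f.create_group("dose")
            dg.create_dataset("mean", data=dose.dose_mean, compression="gzip")
            dg.create_dataset("sem", data=dose.dose_sem, compression="gzip")
            dg.attrs["histories"] = dose.histories
        if meta:
            f.attrs["meta"] = json.dumps(meta, sort_keys=True)


def load_container(path):
    """Read back (grid, masks, dose, meta); absent groups come back None/{}."""
    with h5py.File(path, "r") as f:
        gg = f["grid"]
        mats = [_read_material(gg["materials"][k])
                for k in sorted(gg["materials"], key=int)]
        grid = VoxelGrid(origin=np.array(gg.attrs["origin"]),
                         spacing=np.array(gg.attrs["spacing"]),
                         material_index=gg["material_index"][()],
                         density=gg["density"][()],
                         materials=mats)
        masks = {}
        if "masks" in f:
            for name in f["masks"]:
                masks[name] = StructureMask(name, f["masks"][name][()])
        dose = None
        if "dose" in f:
            dose = DoseGrid(dose_mean=f["dose"]["mean"][()],
                            dose_sem=f["dose"]["sem"][()],
                            histories=int(f["dose"].attrs["histories"]),
                            grid=grid)
        meta = json.loads(f.attrs["meta"]) if "meta" in f.attrs else {}
    return grid, masks, dose, meta


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def write_profile_csv(path, profile: DepthProfile):
    pd.DataFrame({"depth_cm": profile.depth,
                  "dose": profile.dose}).to_csv(path, index=False)


def read_profile_csv(path) -> DepthProfile:
    """Two-column CSV (depth_cm, dose); '#' comment lines are skipped."""
    df = pd.read_csv(path, comment="#")
    return DepthProfile(depth=df.iloc[:, 0].to_numpy(),
                        dose=df.iloc[:, 1].to_numpy())


def write_dvh_csv(path, dvh: DVHCurve):
    pd.DataFrame({"dose_gy": dvh.dose_edges,
                  "volume_fraction": dvh.volume_fraction}).to_csv(path, index=False)


def write_dvh_table(path, dvhs: dict):
    """Tidy long-format DVH table: (structure, dose_gy, volume_fraction)."""
    frames = [pd.DataFrame({"structure": name, "dose_gy": d.dose_edges,
                            "volume_fraction": d.volume_fraction})
              for name, d in dvhs.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_spectrum_file(path, spectrum: Spectrum, comment: str = ""):
    """Two-column text spectrum file (energy_MeV, weight), '#' comments."""
    with open(path, "w") as f:
        if comment:
            f.write(f"# {comment}\n")
        f.write("# energy_MeV weight\n")
        for e, w in zip(spectrum.energies, spectrum.weights):
            f.write(f"{e:.6g} {w:.10g}\n")


def read_spectrum_file(path) -> Spectrum:
    data = np.loadtxt(path, comments="#", ndmin=2)
    return Spectrum(energies=data[:, 0], weights=data[:, 1])


# ---------------------------------------------------------------------------
# contours / config
# ---------------------------------------------------------------------------

def read_contours_json(path) -> dict:
    """JSON contour fallback: {"contours": [{"slice": k, "vertices": [[x,y],...]}]}.

    Returns {slice_index: [Nx2 arrays]} as consumed by the geometry module.
    """
    with open(path) as f:
        data = json.load(f)
    out: dict = {}
    for item in data["contours"]:
        out.setdefault(int(item["slice"]), []).append(
            np.asarray(item["vertices"], dtype=float))
    return out


def read_hu_table(path) -> "HUConversionTable":
    """Plain-text HU conversion table: one bin per row.

    Row format (whitespace-separated, '#' comments):
    ``hu_low hu_high material_name density_intercept density_slope``
    with density = intercept + slope*HU in g/cm^3.  Accepts tables of any
    granularity (e.g. a full stoichiometric-calibration scheme) as long as
    bins are contiguous and the material names resolve.
    """
    from .materials import HUConversionTable
    entries = []
    with open(path) as f:
        for line in f:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            lo, hi, name, b, m = line.split()
            entries.append((float(lo), float(hi), name, (float(b), float(m))))
    return HUConversionTable(entries=entries)


def read_materials_config(path) -> dict:
    """Load extra materials from a YAML mapping and register them.

    Each entry: ``name: {composition: {element: fraction}, density: g/cm3,
    mean_excitation_energy: eV (optional)}``.  Registered materials become
    available to ``get_material`` (overriding built-ins of the same name).
    """
    from .materials import BUILTIN_MATERIALS
    with open(path) as f:
        data = yaml.safe_load(f)
    out = {}
    for name, spec in data.items():
        mat = Material(name=name, composition=spec["composition"],
                       density=float(spec["density"]),
                       mean_excitation_energy=float(
                           spec.get("mean_excitation_energy", 0.0)))
        BUILTIN_MATERIALS[name] = mat
        out[name] = mat
    return out


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping (for run provenance stamps)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# DICOM (optional dependency)
# ---------------------------------------------------------------------------

def _require_pydicom():
    try:
        import pydicom  # noqa: F401
        return pydicom
    except ImportError as err:
        raise ImportError(
            "DICOM I/O requires the optional 'pydicom' package "
            "(pip install pydicom); the HDF5 container and JSON contour "
            "formats cover the same data without it") from err


def read_dicom_ct(paths) -> list:
    """Read a DICOM CT series into CTSlice objects (requires pydicom)."""
    pydicom = _require_pydicom()
    slices = []
    for p in paths:
        ds = pydicom.dcmread(p)
        hu = ds.pixel_array.T.astype(float) * float(ds.RescaleSlope) \
            + float(ds.RescaleIntercept)
        dy, dx = (float(v) / 10.0 for v in ds.PixelSpacing)  # mm -> cm
        x0, y0, z0 = (float(v) / 10.0 for v in ds.ImagePositionPatient)
        slices.append(CTSlice(hu=hu, z_position=z0, pixel_spacing=(dx, dy),
                              origin_xy=(x0, y0)))
    slices.sort(key=lambda s: s.z_position)
    return slices


def write_rtdose(dose: DoseGrid, frame: dict, path):
    """Write a DICOM RT-Dose file (requires pydicom).

    ``frame`` must carry 'frame_of_reference_uid' (plus optional patient
    attributes).  The dose grid is stored as uint32 with a DoseGridScaling
    chosen so quantization stays below 0.1% of the maximum dose.
    """
    pydicom = _require_pydicom()
    if "frame_of_reference_uid" not in frame:
        raise ValueError("missing frame info: frame_of_reference_uid")
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import generate_uid

    grid = dose.grid
    arr = dose.dose_mean
    dmax = float(arr.max())
    scaling = dmax / (2 ** 32 - 1) if dmax > 0 else 1.0
    stored = np.round(arr / scaling).astype(np.uint32) if dmax > 0 \
        else np.zeros(arr.shape, dtype=np.uint32)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.481.2"
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = "1.2.840.10008.1.2.1"  # explicit VR little endian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.FrameOfReferenceUID = frame["frame_of_reference_uid"]
    ds.PatientID = frame.get("patient_id", "ANON")
    ds.PatientName = frame.get("patient_name", "ANON")
    # pixel data: frames along z, rows along y, cols along x; spacing in mm
    ds.Rows = arr.shape[1]
    ds.Columns = arr.shape[0]
    ds.NumberOfFrames = arr.shape[2]
    ds.PixelSpacing = [grid.spacing[1] * 10.0, grid.spacing[0] * 10.0]
    ds.GridFrameOffsetVector = list(np.arange(arr.shape[2])
                                    * grid.spacing[2] * 10.0)
    ds.ImagePositionPatient = list((grid.origin + grid.spacing / 2.0) * 10.0)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseGridScaling = scaling
    ds.PixelData = np.transpose(stored, (2, 1, 0)).tobytes()
    ds.is_little_endian = True
    ds.is_implicit_VR = False
    pydicom.dcmwrite(path, ds, write_like_original=False)
    return path
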