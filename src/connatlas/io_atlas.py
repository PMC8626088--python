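"""Volumes, annotation atlases and region hierarchies.

All 3D arrays in the pipeline share one axis convention:
``(slice, row, column) = (anterior→posterior, dorsal→ventral, left→right)``.
Voxel indices are 0-based; voxel ``i`` along an axis with spacing ``s`` and
origin ``o`` occupies the half-open interval ``[o + i*s, o + (i+1)*s)`` and its
center is ``o + (i + 0.5)*s``.  Files that carry a different memory order are
permuted to this convention at load time.

Region hierarchies are plain tables (id, acronym, parent_id,
in_analysis_set, is_injection_region).  Quantification runs over the flagged
*analysis set*; any label whose ancestry never reaches an analysis region is
pooled into a reserved "Others" bucket, and label 0 (outside the annotated
brain) maps to a reserved "non-annotated" bucket.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .errors import (
    BoundaryError,
    ConfigurationError,
    FormatError,
    GeometryError,
    LookupError_,
    ValidationError,
)

#: Reserved analysis ids for labels outside the flagged analysis set.
OTHERS_ID = -1
#: Reserved analysis id for label 0 (non-annotated space, "NA" regions).
NON_ANNOTATED_ID = -2

_FORMATS = ("tiff-stack", "nrrd", "nifti")


@dataclass
class Volume3D:
    """A 3D scalar intensity volume with physical voxel geometry."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        self.origin_um = tuple(float(v) for v in self.origin_um)
        if any(v <= 0 for v in self.voxel_size_um):
            raise GeometryError(f"voxel sizes must be positive: {self.voxel_size_um}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise GeometryError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_of(self, coordinate_um: Sequence[float]) -> tuple[int, int, int]:
        """Voxel index containing a physical point (half-open box convention)."""
        c = np.asarray(coordinate_um, dtype=float)
        idx = np.floor((c - np.array(self.origin_um)) / np.array(self.voxel_size_um))
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise BoundaryError(f"coordinate {tuple(c)} outside volume bounds")
        return tuple(int(i) for i in idx)

    def center_of(self, index: Sequence[int]) -> tuple[float, float, float]:
        """Physical center of a voxel."""
        i = np.asarray(index, dtype=float)
        c = np.array(self.origin_um) + (i + 0.5) * np.array(self.voxel_size_um)
        return tuple(float(v) for v in c)

    def same_geometry(self, other: "Volume3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_um, other.voxel_size_um)
            and np.allclose(self.origin_um, other.origin_um)
        )


class AnnotationVolume(Volume3D):
    """Integer-label parcellation volume; label 0 marks space outside the brain."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise GeometryError("annotation volume must hold integer labels")
        if self.data.min() < 0:
            raise GeometryError("annotation labels must be non-negative")


class BinaryMask(Volume3D):
    """Boolean per-voxel mask (detected signal, injection site, overrides)."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1, 255))):
                raise GeometryError(f"mask values must be 0/1 or 0/255, got {vals[:8]}")
            self.data = self.data > 0
        super().__post_init__()


@dataclass
class RegionTable:
    """Region hierarchy with analysis-set and injection flags.

    ``df`` is indexed by region id with columns ``acronym``, ``parent_id``
    (NaN at roots), ``in_analysis_set``, ``is_injection_region``.
    """

    df: pd.DataFrame
    _collapse_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"acronym", "parent_id", "in_analysis_set", "is_injection_region"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValidationError(f"region table missing columns: {sorted(missing)}")
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate region ids: {dup}")
        if (self.df.index <= 0).any():
            raise ValidationError("region ids must be positive integers")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = self.df["parent_id"]
        for rid in self.df.index:
            seen = set()
            cur = rid
            while cur is not None and not pd.isna(cur):
                if cur in seen:
                    raise ValidationError(f"cycle in parent links at region {rid}")
                seen.add(cur)
                if cur not in self.df.index:
                    break  # dangling parent treated as root
                nxt = parents.loc[cur]
                cur = None if pd.isna(nxt) else int(nxt)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self.df.index

    @property
    def analysis_ids(self) -> list[int]:
        return [int(i) for i in self.df.index[self.df["in_analysis_set"]]]

    @property
    def injection_ids(self) -> list[int]:
        return [int(i) for i in self.df.index[self.df["is_injection_region"]]]

    def acronym(self, region_id: int) -> str:
        if region_id == OTHERS_ID:
            return "Others"
        if region_id == NON_ANNOTATED_ID:
            return "NA"
        return str(self.df.loc[region_id, "acronym"])


def load_region_table(path: Union[str, Path]) -> RegionTable:
    """Load a region hierarchy from CSV or JSON and validate it.

    CSV header: ``id,acronym,parent_id,in_analysis_set,is_injection_region``
    (the injection column may be omitted and defaults to False).  JSON is a
    list of objects with the same keys.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValidationError("region table needs an 'id' column")
    if "is_injection_region" not in df.columns:
        df["is_injection_region"] = False
    df = df.set_index("id")
    for col in ("in_analysis_set", "is_injection_region"):
        df[col] = df[col].astype(bool)
    return RegionTable(df)


def write_region_table(table: RegionTable, path: Union[str, Path]) -> None:
    table.df.reset_index().rename(columns={"index": "id"}).to_csv(path, index=False)


def collapse_to_analysis(region_id: int, table: RegionTable) -> int:
    """Map an atlas label to its analysis region.

    Walks parent links upward until a region flagged ``in_analysis_set`` is
    met.  Labels with no flagged ancestor collapse to :data:`OTHERS_ID`;
    label 0 maps to :data:`NON_ANNOTATED_ID`.
    """
    if region_id == 0:
        return NON_ANNOTATED_ID
    if region_id in table._collapse_cache:
        return table._collapse_cache[region_id]
    if region_id not in table:
        raise LookupError_(f"unknown region id {region_id}")
    cur: Optional[int] = region_id
    chain = []
    result = OTHERS_ID
    while cur is not None:
        chain.append(cur)
        if bool(table.df.loc[cur, "in_analysis_set"]):
            result = cur
            break
        parent = table.df.loc[cur, "parent_id"]
        cur = None if pd.isna(parent) or int(parent) not in table else int(parent)
    for rid in chain:
        table._collapse_cache[rid] = result
    return result


def collapse_labels(labels: np.ndarray, table: RegionTable) -> np.ndarray:
    """Vectorized :func:`collapse_to_analysis` over a label array."""
    out = np.full(labels.shape, OTHERS_ID, dtype=np.int64)
    for lab in np.unique(labels):
        lab = int(lab)
        out[labels == lab] = collapse_to_analysis(lab, table)
    return out


def region_of_point(
    coordinate_um: Sequence[float], annotation: AnnotationVolume, table: RegionTable
) -> int:
    """Analysis region containing a physical point."""
    idx = annotation.voxel_of(coordinate_um)
    return collapse_to_analysis(int(annotation.data[idx]), table)


# ---------------------------------------------------------------------------
# Volume I/O


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".tif", ".tiff")):
        return "tiff-stack"
    if suffix.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    if suffix.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise FormatError(f"cannot infer format from {path.name!r}")


def read_volume(
    path: Union[str, Path],
    format: Optional[str] = None,
    voxel_size_um: Optional[Sequence[float]] = None,
) -> Volume3D:
    """Read a 3D volume from a TIFF stack, NRRD or NIfTI-1 file.

    Voxel size comes from the file header when present; TIFF stacks carry it
    only via ImageJ metadata, so ``voxel_size_um`` must be supplied when the
    header is silent.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    try:
        if fmt == "tiff-stack":
            data, header_vs = _read_tiff(path)
        elif fmt == "nrrd":
            data, header_vs, origin = _read_sitk(path)
        else:
            data, header_vs = _read_nifti(path)
    except ConnatlasErrorTuple as exc:  # pragma: no cover - defensive
        raise FormatError(f"failed to read {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"{path.name}: expected 3D data, got ndim={data.ndim}")
    vs = voxel_size_um if voxel_size_um is not None else header_vs
    if vs is None:
        raise ConfigurationError(
            f"{path.name}: no voxel size in header and none supplied"
        )
    return Volume3D(data, tuple(vs))


# read helpers raise library-specific exceptions; collapse them to FormatError
ConnatlasErrorTuple = (ValueError, OSError, RuntimeError, KeyError)


def _read_tiff(path: Path):
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        vs = None
        if tf.imagej_metadata is not None:
            meta = tf.imagej_metadata
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if "spacing" in meta and xres is not None and yres is not None:
                sx = xres.value[1] / xres.value[0]
                sy = yres.value[1] / yres.value[0]
                vs = (float(meta["spacing"]), float(sy), float(sx))
    return data, vs


def _read_sitk(path: Path):
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # (z, y, x) == (slice, row, col)
    spacing = img.GetSpacing()[::-1]
    origin = img.GetOrigin()[::-1]
    return data, tuple(spacing), tuple(origin)


def _read_nifti(path: Path):
    img = nib.load(str(path))
    # stored (col,row,slice); permute back to (slice,row,col)
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    return np.ascontiguousarray(data), tuple(float(z) for z in zooms[::-1])


def write_volume(
    volume: Volume3D, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a volume; round-trips bit-exactly for integer dtypes.

    Boolean masks are stored as 0/255 uint8.  TIFF stacks refuse dtypes the
    ImageJ flavor cannot hold losslessly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    if fmt == "tiff-stack":
        if data.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)):
            if np.issubdtype(data.dtype, np.floating):
                raise FormatError(
                    f"dtype {data.dtype} would be lossy in an ImageJ TIFF stack; "
                    "convert to float32 explicitly first"
                )
            info = np.iinfo(data.dtype)
            if info.min < 0 or info.max > np.iinfo(np.uint16).max:
                raise FormatError(f"dtype {data.dtype} not representable in TIFF stack")
            data = data.astype(np.uint16)
        sz, sy, sx = volume.voxel_size_um
        tifffile.imwrite(
            path,
            data,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        )
    elif fmt == "nrrd":
        img = sitk.GetImageFromArray(data)
        img.SetSpacing(tuple(volume.voxel_size_um[::-1]))
        img.SetOrigin(tuple(volume.origin_um[::-1]))
        sitk.WriteImage(img, str(path), useCompression=False)
    else:
        affine = np.diag(list(volume.voxel_size_um[::-1]) + [1.0])
        affine[:3, 3] = volume.origin_um[::-1]
        img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
        img.header.set_zooms(volume.voxel_size_um[::-1])
        nib.save(img, str(path))


def read_mask(
    path: Union[str, Path],
    format: Optional[str] = None,
    voxel_size_um: Optional[Sequence[float]] = None,
) -> BinaryMask:
    """Read a volume of {0,1} or {0,255} values as a boolean mask."""
    vol = read_volume(path, format=format, voxel_size_um=voxel_size_um)
    return BinaryMask(vol.data, vol.voxel_size_um, vol.origin_um)
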