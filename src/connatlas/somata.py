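"""Localization of retrogradely labeled somata and their region assignment.

The detector is a deliberately simple stand-in for dedicated soma-localization
tools: 26-connected components of the detected-signal mask are size-filtered,
oversized components are split by a watershed seeded at local intensity
maxima, each accepted component contributes its intensity-weighted centroid,
and near-duplicate centroids are merged keeping the brighter one.  Detected
somata are then mapped to analysis regions through the annotation volume,
with somata inside the injection-site mask flagged for exclusion from all
input proportions.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .errors import BoundaryError, InputError
from .io_atlas import (
    AnnotationVolume,
    BinaryMask,
    RegionTable,
    Volume3D,
    region_of_point,
)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

SOMA_COLUMNS = ["x_um", "y_um", "z_um", "volume_voxels", "intensity", "region_id", "excluded"]
# x_um/y_um/z_um follow the internal axis order (slice, row, column) in µm.


def default_size_band(soma_radius_voxels: float) -> tuple[int, int]:
    """Tolerant component-size band around an ideal sphere of radius r."""
    ideal = 4.0 / 3.0 * np.pi * soma_radius_voxels**3
    return max(1, int(round(0.2 * ideal))), int(round(5.0 * ideal))


def _component_record(
    intensity: np.ndarray, coords: np.ndarray, volume: Volume3D
) -> dict:
    w = intensity[tuple(coords.T)].astype(np.float64)
    if w.sum() <= 0:
        w = np.ones(len(coords))
    centroid_vox = (coords * w[:, None]).sum(axis=0) / w.sum()
    c_um = volume.center_of(centroid_vox)
    return {
        "x_um": c_um[0],
        "y_um": c_um[1],
        "z_um": c_um[2],
        "volume_voxels": int(len(coords)),
        "intensity": float(w.mean()),
        "region_id": -1,
        "excluded": False,
    }


def detect_somata(
    intensity: Volume3D,
    mask: BinaryMask,
    min_voxels: int,
    max_voxels: int,
    min_separation_um: float,
    split_voxels: Optional[int] = None,
) -> pd.DataFrame:
    """Detect soma candidates in a binary mask.

    Components smaller than ``min_voxels`` are dropped; components larger
    than ``split_voxels`` (default: 1.5x the geometric center of the size
    band, so touching soma pairs are caught) are split by a watershed seeded
    at local intensity maxima; centroids closer than ``min_separation_um``
    are merged, keeping the brighter one.  Returns a soma table with
    :data:`SOMA_COLUMNS` (region ids unassigned, -1).
    """
    if min_voxels < 1:
        raise InputError("min_voxels must be >= 1")
    if split_voxels is None:
        split_voxels = int(round(1.5 * math.sqrt(min_voxels * max_voxels)))
    labels, n = ndimage.label(mask.data, structure=_STRUCT26)
    records = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        size = len(coords)
        if size < min_voxels:
            continue
        if size <= min(split_voxels, max_voxels):
            records.append(_component_record(intensity.data, coords, intensity))
            continue
        # split oversized component by watershed seeded at local maxima of
        # the smoothed intensity; peak spacing = nominal soma radius derived
        # from the size band, so noise cannot fragment a single soma
        sl = tuple(
            slice(int(coords[:, a].min()), int(coords[:, a].max()) + 1)
            for a in range(3)
        )
        sub_mask = labels[sl] == lab
        sub_int = np.where(sub_mask, intensity.data[sl], 0.0)
        nominal_vox = math.sqrt(min_voxels * max_voxels)
        r_est = (3.0 * nominal_vox / (4.0 * math.pi)) ** (1.0 / 3.0)
        smoothed = ndimage.gaussian_filter(sub_int, sigma=max(1.0, r_est / 2.0))
        peaks = peak_local_max(
            smoothed,
            min_distance=max(1, int(round(r_est))),
            labels=sub_mask,
            exclude_border=False,
        )
        if len(peaks) < 2:
            records.append(_component_record(intensity.data, coords, intensity))
            continue
        markers = np.zeros(sub_mask.shape, dtype=np.int32)
        for i, p in enumerate(peaks, start=1):
            markers[tuple(p)] = i
        ws = watershed(-smoothed, markers=markers, mask=sub_mask)
        offset = np.array([s.start for s in sl])
        for w_lab in range(1, len(peaks) + 1):
            w_coords = np.argwhere(ws == w_lab) + offset
            if min_voxels <= len(w_coords):
                records.append(
                    _component_record(intensity.data, w_coords, intensity)
                )
    df = pd.DataFrame(records, columns=SOMA_COLUMNS)
    return _merge_close(df, min_separation_um)


def _merge_close(df: pd.DataFrame, min_separation_um: float) -> pd.DataFrame:
    """Greedy brightest-first merge of centroids closer than the separation.

    Processing order is by (intensity, position) rather than detection order,
    so the result is independent of component enumeration order.
    """
    if len(df) <= 1:
        return df.reset_index(drop=True)
    order = df.sort_values(
        ["intensity", "x_um", "y_um", "z_um"], ascending=[False, True, True, True]
    ).index
    kept: list[int] = []
    pts = df[["x_um", "y_um", "z_um"]].to_numpy()
    for idx in order:
        if kept and np.min(
            np.linalg.norm(pts[kept] - pts[idx], axis=1)
        ) < min_separation_um:
            continue
        kept.append(idx)
    return df.loc[sorted(kept)].reset_index(drop=True)


def assign_somata(
    somata: pd.DataFrame,
    annotation: AnnotationVolume,
    table: RegionTable,
    injection_mask: Optional[BinaryMask] = None,
) -> pd.DataFrame:
    """Assign each soma to its analysis region; flag injection-site somata.

    Somata whose center falls inside ``injection_mask`` get
    ``excluded=True`` and are dropped from input proportions downstream.
    """
    out = somata.copy()
    regions = []
    excluded = []
    for _, row in out.iterrows():
        c = (row["x_um"], row["y_um"], row["z_um"])
        try:
            regions.append(region_of_point(c, annotation, table))
        except BoundaryError as exc:
            raise BoundaryError(f"soma at {c} out of bounds") from exc
        if injection_mask is not None:
            excluded.append(bool(injection_mask.data[injection_mask.voxel_of(c)]))
        else:
            excluded.append(False)
    out["region_id"] = regions
    out["excluded"] = excluded
    return out


def apply_affine(
    coordinates: Sequence[Sequence[float]], matrix: np.ndarray
) -> np.ndarray:
    """Apply a 3x4 (or 4x4) affine ``c' = A c + t`` to a list of points."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.shape == (4, 4):
        m = m[:3]
    if m.shape != (3, 4):
        raise InputError(f"expected a 3x4 affine, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise InputError("affine matrix must be finite")
    pts = np.asarray(coordinates, dtype=np.float64)
    return pts @ m[:, :3].T + m[:, 3]


def invert_affine(matrix: np.ndarray) -> np.ndarray:
    """Inverse of a 3x4 affine; raises on a singular linear part."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.shape == (4, 4):
        m = m[:3]
    a, t = m[:, :3], m[:, 3]
    if abs(np.linalg.det(a)) < 1e-12:
        raise InputError("affine linear part is singular")
    a_inv = np.linalg.inv(a)
    return np.hstack([a_inv, (-a_inv @ t)[:, None]])


def read_soma_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SOMA_COLUMNS) - set(df.columns) - {"intensity"}
    if missing:
        raise InputError(f"soma CSV missing columns: {sorted(missing)}")
    if "intensity" not in df.columns:
        df["intensity"] = 0.0
    return df[SOMA_COLUMNS]


def write_soma_csv(somata: pd.DataFrame, path: Union[str, Path]) -> None:
    somata.to_csv(path, index=False)


def apply_overrides(
    somata: pd.DataFrame, overrides: pd.DataFrame
) -> pd.DataFrame:
    """Honor a manual accept/reject table (columns: index, accept)."""
    out = somata.copy()
    rejected = overrides.loc[~overrides["accept"].astype(bool), "index"]
    return out.drop(index=rejected).reset_index(drop=True)
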