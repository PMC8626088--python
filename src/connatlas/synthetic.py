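"""Synthetic toy brains with known ground truth.

Real inputs to the pipeline are terabyte-scale whole-brain fluorescence
volumes: anterograde tracer signal fills axon tracts radiating from an
injection site, and retrograde tracer labels the somata of presynaptic
neurons scattered across regions.  This module emulates those data at desk
scale — a toy ellipsoidal "brain" partitioned into contiguous regions,
tubular axon walks from the injection centroid into target regions, spherical
somata, a smooth per-section background gradient and Gaussian sensor noise —
and records exact ground truth (planted signal mask, per-region output
fractions, soma coordinates) so every downstream stage can be scored.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import CapacityError, InputError, SimulationError
from .io_atlas import AnnotationVolume, BinaryMask, RegionTable, Volume3D


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic brain.

    Defaults are the desk-scale conditions used throughout the test suite:
    a 100 µm cube at 1 µm isotropic resolution with 8 regions, 200 axons and
    a signal-to-noise ratio of 30 (amplitude 300 over sigma 10), comfortably
    above the SNR >= 10 regime the detection stage is designed for.
    """

    shape: Tuple[int, int, int] = (100, 100, 100)
    voxel_size_um: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_regions: int = 8
    target_fractions: Optional[Dict[int, float]] = None  # None = uniform
    axon_radius_voxels: float = 2.0
    tortuosity: float = 0.3  # step-direction jitter in [0, 1]
    n_axons: int = 200
    somata_per_region: Union[int, Dict[int, int]] = 6
    soma_radius_voxels: float = 3.0
    background_gradient: float = 20.0  # gray units across one section
    noise_sigma: float = 10.0
    signal_amplitude: float = 300.0
    injection_radius_um: float = 10.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted truth accompanying a synthetic volume."""

    soma_coordinates_um: Dict[int, List[Tuple[float, float, float]]] = field(
        default_factory=dict
    )
    true_output_fraction: Dict[int, float] = field(default_factory=dict)
    injection_mask: Optional[BinaryMask] = None
    planted_signal_mask: Optional[BinaryMask] = None
    injection_region: int = 0
    seed: int = 0

    @property
    def soma_counts(self) -> Dict[int, int]:
        return {r: len(v) for r, v in self.soma_coordinates_um.items()}


def make_toy_atlas(
    shape: Tuple[int, int, int], n_regions: int, seed: int
) -> Tuple[AnnotationVolume, RegionTable]:
    """Build an ellipsoidal toy brain partitioned into contiguous regions.

    The brain is the interior of an axis-aligned ellipsoid filling ~90% of
    the volume; it is split into ``n_regions`` Voronoi cells around seeded
    sites (convex, hence contiguous).  The region nearest the volume center
    is flagged as the injection region; all regions are in the analysis set.
    Label 0 marks space outside the ellipsoid.
    """
    if n_regions < 2:
        raise InputError("need at least 2 regions")
    if any(s < 20 for s in shape):
        raise InputError("shape must be at least (20, 20, 20)")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    center = (np.array(shape) - 1) / 2.0
    radii = 0.45 * np.array(shape)
    grid = np.indices(shape, dtype=float)
    r2 = sum(((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    inside = r2 <= 1.0
    n_inside = int(inside.sum())
    if n_regions > n_inside:
        raise CapacityError(f"{n_regions} regions > {n_inside} interior voxels")

    coords = np.argwhere(inside).astype(float)
    for _ in range(100):
        sites = coords[rng.choice(len(coords), size=n_regions, replace=False)]
        d2 = ((coords[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        if len(np.unique(assign)) == n_regions:
            break
    else:  # pragma: no cover
        raise SimulationError("could not seed non-empty Voronoi regions")

    labels = np.zeros(shape, dtype=np.int32)
    labels[tuple(np.argwhere(inside).T)] = assign + 1
    annotation = AnnotationVolume(labels)

    site_dist = np.linalg.norm(sites - center, axis=1)
    injection_label = int(site_dist.argmin()) + 1
    df = pd.DataFrame(
        {
            "acronym": [f"R{i}" for i in range(1, n_regions + 1)],
            "parent_id": [np.nan] * n_regions,
            "in_analysis_set": [True] * n_regions,
            "is_injection_region": [i + 1 == injection_label for i in range(n_regions)],
        },
        index=pd.Index(range(1, n_regions + 1), name="id"),
    )
    return annotation, RegionTable(df)


def _region_centroids(annotation: AnnotationVolume) -> Dict[int, np.ndarray]:
    labs = np.unique(annotation.data)
    labs = labs[labs > 0]
    cents = ndimage.center_of_mass(
        np.ones_like(annotation.data, dtype=np.uint8), annotation.data, labs
    )
    return {int(l): np.asarray(c) for l, c in zip(labs, cents)}


def _rasterize_tube(
    mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float
) -> None:
    """Set voxels within ``radius`` of segment p0-p1 (voxel units, in place)."""
    lo = np.maximum(np.floor(np.minimum(p0, p1) - radius).astype(int), 0)
    hi = np.minimum(
        np.ceil(np.maximum(p0, p1) + radius).astype(int) + 1, np.array(mask.shape)
    )
    if np.any(lo >= hi):
        return
    sub = np.indices(tuple(hi - lo), dtype=float)
    pts = sub.reshape(3, -1).T + lo
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.linalg.norm(pts - p0, axis=1)
    else:
        t = np.clip((pts - p0) @ d / L2, 0.0, 1.0)
        dist = np.linalg.norm(pts - (p0 + t[:, None] * d), axis=1)
    hit = (dist <= radius).reshape(tuple(hi - lo))
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= hit


def _sphere_mask(shape, center: np.ndarray, radius: float) -> np.ndarray:
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, np.array(shape))
    out = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return out
    sub = np.indices(tuple(hi - lo), dtype=float)
    d = np.sqrt(sum((sub[a] + lo[a] - center[a]) ** 2 for a in range(3)))
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = d <= radius
    return out


def injection_sphere(
    annotation: AnnotationVolume, table: RegionTable, radius_um: float
) -> BinaryMask:
    """Spherical injection-site mask around the injection-region centroid.

    Mimics the hand-segmented injection site of a real experiment.
    """
    inj = table.injection_ids[0]
    center = _region_centroids(annotation)[inj]
    radius_vox = radius_um / float(np.mean(annotation.voxel_size_um))
    return BinaryMask(
        _sphere_mask(annotation.shape, center, radius_vox),
        annotation.voxel_size_um,
        annotation.origin_um,
    )


def simulate_axons(
    annotation: AnnotationVolume, table: RegionTable, config: SimulationConfig
) -> Tuple[Volume3D, GroundTruth]:
    """Plant tubular axon tracts from the injection site into target regions.

    Each axon is a biased random walk: it starts at the injection-region
    centroid, draws a target region with probability proportional to
    ``target_fractions``, heads toward a termination point sampled inside
    that region around its centroid (Gaussian spread, so tubes arborize
    instead of bundling onto one point while the region periphery stays
    clear), and jitters its step direction by ``tortuosity``.  The walk is
    rasterized as a tube of ``axon_radius_voxels`` at ``signal_amplitude``.
    True output fractions are recounted from the planted tube voxels per
    region, excluding the injection region and renormalizing.
    """
    rng = np.random.default_rng(config.seed)
    centroids = _region_centroids(annotation)
    injection = table.injection_ids[0]
    fractions = config.target_fractions
    if fractions is None:
        targets = [r for r in table.analysis_ids if r != injection]
        fractions = {r: 1.0 / len(targets) for r in targets}
    fractions = {r: f for r, f in fractions.items() if f > 0 and r != injection}
    if not fractions:
        raise InputError("target fractions must cover at least one non-injection region")
    t_ids = sorted(fractions)
    probs = np.array([fractions[r] for r in t_ids], dtype=float)
    probs /= probs.sum()

    shape = annotation.shape
    tube = np.zeros(shape, dtype=bool)
    start = centroids[injection]
    max_steps = 4 * int(sum(shape))
    tau = float(np.clip(config.tortuosity, 0.0, 1.0))
    region_voxels = {r: np.argwhere(annotation.data == r) for r in t_ids}
    region_sigma = {
        r: np.sqrt(((v - centroids[r]) ** 2).sum(axis=1).mean()) / 3.0
        for r, v in region_voxels.items()
    }
    for _ in range(config.n_axons):
        t_region = t_ids[rng.choice(len(t_ids), p=probs)]
        vox = region_voxels[t_region]
        target = None
        for _try in range(20):
            cand = centroids[t_region] + rng.normal(
                0.0, region_sigma[t_region], size=3
            )
            ci = np.floor(cand).astype(int)
            if np.all(ci >= 0) and np.all(ci < np.array(shape)):
                if int(annotation.data[tuple(ci)]) == t_region:
                    target = cand
                    break
        if target is None:
            target = vox[rng.integers(len(vox))].astype(float)
        pos = start.copy()
        left_injection = False
        for _step in range(max_steps):
            to_target = target - pos
            dist = np.linalg.norm(to_target)
            if dist < 1.0:
                break
            jitter = rng.standard_normal(3)
            jitter /= np.linalg.norm(jitter)
            step = (1.0 - tau) * (to_target / dist) + tau * jitter
            norm = np.linalg.norm(step)
            if norm < 1e-9:
                continue
            new = np.clip(pos + step / norm, 0, np.array(shape) - 1.0)
            _rasterize_tube(tube, pos, new, config.axon_radius_voxels)
            pos = new
            if int(annotation.data[tuple(pos.astype(int))]) != injection:
                left_injection = True
        # terminate exactly on the sampled target voxel so the tube always
        # enters the target region instead of stopping at its boundary
        _rasterize_tube(tube, pos, target, config.axon_radius_voxels)
        if int(annotation.data[tuple(target.astype(int))]) != injection:
            left_injection = True
        if not left_injection:
            raise SimulationError("axon walk never left the injection region")

    tube &= annotation.data > 0  # clip tubes to the brain
    intensity = np.zeros(shape, dtype=np.float32)
    intensity[tube] = config.signal_amplitude

    labels_in_tube = annotation.data[tube]
    counts = {
        r: int(np.sum(labels_in_tube == r)) for r in table.analysis_ids if r != injection
    }
    total = sum(counts.values())
    if total == 0:
        raise SimulationError("no tube voxels outside the injection region")
    truth = GroundTruth(
        true_output_fraction={r: c / total for r, c in counts.items()},
        injection_mask=injection_sphere(annotation, table, config.injection_radius_um),
        planted_signal_mask=BinaryMask(
            tube, annotation.voxel_size_um, annotation.origin_um
        ),
        injection_region=injection,
        seed=config.seed,
    )
    vol = Volume3D(intensity, annotation.voxel_size_um, annotation.origin_um)
    return vol, truth


def simulate_somata(
    annotation: AnnotationVolume, table: RegionTable, config: SimulationConfig
) -> Tuple[Volume3D, GroundTruth]:
    """Scatter non-overlapping bright spheres (somata) inside requested regions.

    ``somata_per_region`` may be a single count applied to every non-injection
    analysis region or a dict mapping region id to count.  Sphere centers are
    drawn uniformly from the region's voxels, rejecting any placement closer
    than ``2 * soma_radius_voxels`` to an accepted soma or poking outside the
    brain.
    """
    rng = np.random.default_rng(config.seed)
    injection = table.injection_ids[0]
    if isinstance(config.somata_per_region, dict):
        requests = dict(config.somata_per_region)
    else:
        requests = {
            r: int(config.somata_per_region)
            for r in table.analysis_ids
            if r != injection
        }
    r_vox = float(config.soma_radius_voxels)
    shape = annotation.shape
    vol = np.zeros(shape, dtype=np.float32)
    accepted: List[np.ndarray] = []
    coords_per_region: Dict[int, List[Tuple[float, float, float]]] = {}
    helper = Volume3D(vol, annotation.voxel_size_um, annotation.origin_um)
    for region, n in sorted(requests.items()):
        coords_per_region[region] = []
        if n == 0:
            continue
        region_vox = np.argwhere(annotation.data == region)
        if len(region_vox) == 0:
            raise CapacityError(f"region {region} has no voxels")
        placed = 0
        for _try in range(400 * n):
            if placed == n:
                break
            center = region_vox[rng.integers(len(region_vox))].astype(float)
            if accepted and np.min(
                np.linalg.norm(np.array(accepted) - center, axis=1)
            ) < 2.0 * r_vox:
                continue
            ball = _sphere_mask(shape, center, r_vox)
            if np.any(annotation.data[ball] == 0):
                continue  # soma must stay inside the brain
            vol[ball] = config.signal_amplitude
            accepted.append(center)
            coords_per_region[region].append(helper.center_of(center))
            placed += 1
        if placed < n:
            raise CapacityError(
                f"could not place {n} somata in region {region} (placed {placed})"
            )
    total = sum(len(v) for v in coords_per_region.values())
    truth = GroundTruth(
        soma_coordinates_um=coords_per_region,
        injection_mask=injection_sphere(annotation, table, config.injection_radius_um),
        injection_region=injection,
        seed=config.seed,
    )
    truth.true_output_fraction = (
        {r: len(v) / total for r, v in coords_per_region.items()} if total else {}
    )
    return Volume3D(vol, annotation.voxel_size_um, annotation.origin_um), truth


def add_background_and_noise(
    volume: Volume3D, config: SimulationConfig, seed: Optional[int] = None
) -> Volume3D:
    """Add a smooth per-section linear gradient plus Gaussian sensor noise.

    The gradient ramps linearly across each coronal section's column axis
    from 0 to ``background_gradient`` gray units; noise is i.i.d. Gaussian
    with ``noise_sigma``; the result is clipped at 0.
    """
    if config.noise_sigma < 0:
        raise InputError("noise sigma must be non-negative")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    data = volume.data.astype(np.float64)
    ncol = data.shape[2]
    ramp = (
        np.linspace(0.0, config.background_gradient, ncol)
        if ncol > 1
        else np.zeros(1)
    )
    data = data + ramp[None, None, :]
    if config.noise_sigma > 0:
        data = data + rng.normal(0.0, config.noise_sigma, size=data.shape)
    return Volume3D(
        np.clip(data, 0, None).astype(np.float32),
        volume.voxel_size_um,
        volume.origin_um,
    )


def scatter_noise_blobs(
    mask: BinaryMask,
    n_blobs: int,
    radius_voxels: float,
    min_distance_um: float,
    seed: int,
    annotation: Optional[AnnotationVolume] = None,
    max_per_cell: int = 4,
    cell_size_um: float = 10.0,
) -> Tuple[BinaryMask, BinaryMask]:
    """Plant isolated false-positive blobs away from existing foreground.

    Emulates speckle noise that survives per-section thresholding; path
    validation is expected to remove it.  Isolation is two-fold: every blob
    center lies at least ``min_distance_um`` from real signal, and at most
    ``max_per_cell`` blobs share one density-grid cell so clustered speckle
    can never masquerade as a dense-signal corridor.  Returns (mask with
    blobs added, mask of blob voxels only).
    """
    rng = np.random.default_rng(seed)
    dist_to_fg = ndimage.distance_transform_edt(
        ~mask.data, sampling=mask.voxel_size_um
    )
    ok = dist_to_fg >= min_distance_um
    if annotation is not None:
        ok &= annotation.data > 0
    candidates = np.argwhere(ok)
    if len(candidates) < n_blobs:
        raise CapacityError("not enough space for the requested noise blobs")
    order = rng.permutation(len(candidates))
    kv = np.maximum(
        np.round(cell_size_um / np.array(mask.voxel_size_um)).astype(int), 1
    )
    per_cell: dict = {}
    blob = np.zeros(mask.shape, dtype=bool)
    placed = 0
    for i in order:
        c = candidates[i]
        cell = tuple(c // kv)
        if per_cell.get(cell, 0) >= max_per_cell:
            continue
        per_cell[cell] = per_cell.get(cell, 0) + 1
        blob |= _sphere_mask(mask.shape, c.astype(float), radius_voxels)
        placed += 1
        if placed == n_blobs:
            break
    if placed < n_blobs:
        raise CapacityError("not enough space for the requested noise blobs")
    blob &= ~mask.data
    combined = BinaryMask(mask.data | blob, mask.voxel_size_um, mask.origin_um)
    return combined, BinaryMask(blob, mask.voxel_size_um, mask.origin_um)
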