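"""Fast-marching path validation of detected signal.

Detected foreground is only trusted if it is *connected* to the injection
site through labeled tissue.  The detected mask is summarized on a coarse
grid (10 µm cells by default) as a signal-density field — the fraction of
foreground voxels per cell.  Density maps to a front speed ``F = density +
eps``, and the eikonal equation ``|∇T| F = 1`` is solved outward from the
injection cells with a multistencils fast-marching scheme (first/second-order
upwind differences on axis-aligned and edge-diagonal stencils, keeping the
smallest consistent arrival time).  Every signal-bearing cell is then
back-tracked down the arrival-time gradient; the *path confidence* is the
fraction of back-tracking points lying in foreground cells
(density above a threshold), and cells that cannot reach the injection site
or reach it with low confidence have their voxels cleared.

Arrival times are computed in cell units on the (assumed isotropic) coarse
grid; only ordering and connectivity matter downstream, not absolute times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage

from .errors import GeometryError, InputError
from .io_atlas import BinaryMask

SQRT2 = math.sqrt(2.0)

# Four orthogonal stencil frames covering the 18-neighborhood:
# the axis frame plus the three frames obtained by rotating two axes by 45°.
_STENCIL_DIRS = np.array(
    [
        [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
        [[1, 1, 0], [1, -1, 0], [0, 0, 1]],
        [[1, 0, 1], [1, 0, -1], [0, 1, 0]],
        [[0, 1, 1], [0, 1, -1], [1, 0, 0]],
    ],
    dtype=np.int64,
)
_STENCIL_H = np.array(
    [
        [1.0, 1.0, 1.0],
        [SQRT2, SQRT2, 1.0],
        [SQRT2, SQRT2, 1.0],
        [SQRT2, SQRT2, 1.0],
    ]
)
_NEIGHBOR_OFFSETS = np.unique(
    np.vstack([_STENCIL_DIRS.reshape(-1, 3), -_STENCIL_DIRS.reshape(-1, 3)]), axis=0
)


@dataclass
class ValidationParams:
    """Tunables of density-based path validation.

    The density→speed law and both thresholds are declared choices: the
    affine law ``F = density + speed_floor`` keeps empty space traversable
    (paths through it merely lower confidence), a cell counts as foreground
    above 5% signal density, and paths below 80% confidence are discarded.
    """

    foreground_density_threshold: float = 0.05
    confidence_cutoff: float = 0.8
    speed_floor: float = 1e-3
    step_size: float = 0.5  # back-tracking step, in cells
    max_steps: Optional[int] = None  # default: 10 x grid diagonal / step_size
    cell_size_um: Tuple[float, float, float] = (10.0, 10.0, 10.0)

    def __post_init__(self) -> None:
        if not 0 < self.confidence_cutoff <= 1:
            raise InputError("confidence cutoff must be in (0, 1]")
        if self.speed_floor <= 0:
            raise InputError("speed floor must be positive")
        if not 0 < self.foreground_density_threshold < 1:
            raise InputError("foreground density threshold must be in (0, 1)")


@dataclass
class DensityGrid:
    """Per-cell signal density of a voxel mask on a coarse grid."""

    density: np.ndarray  # in [0, 1]
    cell_size_um: Tuple[float, float, float]
    voxels_per_cell: Tuple[int, int, int]
    volume_shape: Tuple[int, int, int]
    origin_um: Tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class ArrivalTimeField:
    T: np.ndarray  # arrival time per cell, +inf where unreachable
    seeds: np.ndarray  # boolean per cell
    finalize_order: np.ndarray  # flat cell indices in freeze order


@dataclass
class PathTrace:
    points: np.ndarray  # (n, 3) continuous cell coordinates
    reached_seed: bool
    confidence: float = float("nan")


def _block_sum(arr: np.ndarray, kv: Sequence[int]) -> np.ndarray:
    out = arr.astype(np.float64)
    for axis in range(3):
        idx = np.arange(0, out.shape[axis], kv[axis])
        out = np.add.reduceat(out, idx, axis=axis)
    return out


def compute_density_grid(
    mask: BinaryMask, cell_size_um: Sequence[float] = (10.0, 10.0, 10.0)
) -> DensityGrid:
    """Fraction of foreground voxels per coarse cell.

    Cell edges must align with whole voxels; boundary cells use their actual
    (possibly smaller) voxel count as the denominator.
    """
    kv = []
    for a in range(3):
        ratio = cell_size_um[a] / mask.voxel_size_um[a]
        k = int(round(ratio))
        if k < 1 or abs(ratio - k) > 1e-6:
            raise GeometryError(
                f"cell size {cell_size_um[a]} not a whole multiple of voxel "
                f"size {mask.voxel_size_um[a]} on axis {a}"
            )
        kv.append(k)
    counts = _block_sum(mask.data, kv)
    totals = _block_sum(np.ones(mask.shape, dtype=np.float64), kv)
    return DensityGrid(
        density=counts / totals,
        cell_size_um=tuple(float(c) for c in cell_size_um),
        voxels_per_cell=tuple(kv),
        volume_shape=mask.shape,
        origin_um=mask.origin_um,
    )


def density_to_speed(
    grid: DensityGrid, params: ValidationParams = ValidationParams()
) -> np.ndarray:
    """Affine density→speed law ``F = density + speed_floor``."""
    return grid.density + params.speed_floor


@njit(cache=True)
def _heap_push(keys, idxs, size, key, idx):
    i = size
    keys[i] = key
    idxs[i] = idx
    while i > 0:
        parent = (i - 1) >> 1
        if keys[parent] <= keys[i]:
            break
        keys[parent], keys[i] = keys[i], keys[parent]
        idxs[parent], idxs[i] = idxs[i], idxs[parent]
        i = parent
    return size + 1


@njit(cache=True)
def _heap_pop(keys, idxs, size):
    top_key = keys[0]
    top_idx = idxs[0]
    size -= 1
    keys[0] = keys[size]
    idxs[0] = idxs[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        smallest = i
        if l < size and keys[l] < keys[smallest]:
            smallest = l
        if r < size and keys[r] < keys[smallest]:
            smallest = r
        if smallest == i:
            break
        keys[smallest], keys[i] = keys[i], keys[smallest]
        idxs[smallest], idxs[i] = idxs[i], idxs[smallest]
        i = smallest
    return top_key, top_idx, size


@njit(cache=True)
def _solve_cell(T, frozen, F, x0, x1, x2, dirs, hs, use_second):
    """Smallest consistent arrival time at one cell over all stencils."""
    n0, n1, n2 = T.shape
    inv_f2 = 1.0 / (F[x0, x1, x2] * F[x0, x1, x2])
    best_T = np.inf
    for s in range(dirs.shape[0]):
        t1 = np.empty(3)
        t2 = np.empty(3)
        avail = np.zeros(3, dtype=np.bool_)
        avail2 = np.zeros(3, dtype=np.bool_)
        for d in range(3):
            d0, d1, d2 = dirs[s, d, 0], dirs[s, d, 1], dirs[s, d, 2]
            b = np.inf
            b2 = np.inf
            has2 = False
            for sgn in (1, -1):
                y0, y1, y2 = x0 + sgn * d0, x1 + sgn * d1, x2 + sgn * d2
                if 0 <= y0 < n0 and 0 <= y1 < n1 and 0 <= y2 < n2:
                    if frozen[y0, y1, y2] and T[y0, y1, y2] < b:
                        b = T[y0, y1, y2]
                        z0, z1, z2 = y0 + sgn * d0, y1 + sgn * d1, y2 + sgn * d2
                        has2 = False
                        if 0 <= z0 < n0 and 0 <= z1 < n1 and 0 <= z2 < n2:
                            if frozen[z0, z1, z2] and T[z0, z1, z2] <= b:
                                b2 = T[z0, z1, z2]
                                has2 = True
            if b < np.inf:
                avail[d] = True
                t1[d] = b
                if has2:
                    avail2[d] = True
                    t2[d] = b2
        n_avail = 0
        for d in range(3):
            if avail[d]:
                n_avail += 1
        if n_avail == 0:
            continue
        # try second-order where possible, then first-order, then drop the
        # slowest directions until the causality condition holds
        for attempt in range(2):
            second = use_second and attempt == 0
            # sort available dirs by upwind value (ascending), max 3 entries
            order = np.empty(3, dtype=np.int64)
            m = 0
            for d in range(3):
                if avail[d]:
                    order[m] = d
                    m += 1
            for i in range(m):
                for j in range(i + 1, m):
                    if t1[order[j]] < t1[order[i]]:
                        order[i], order[j] = order[j], order[i]
            solved = False
            cand = np.inf
            for keep in range(m, 0, -1):
                a = 0.0
                bq = 0.0
                cq = -inv_f2
                tmax = 0.0
                for i in range(keep):
                    d = order[i]
                    h = hs[s, d]
                    if second and avail2[d]:
                        alpha = 1.5 / h
                        beta = (2.0 * t1[d] - 0.5 * t2[d]) / h
                    else:
                        alpha = 1.0 / h
                        beta = t1[d] / h
                    a += alpha * alpha
                    bq += -2.0 * alpha * beta
                    cq += beta * beta
                    if t1[d] > tmax:
                        tmax = t1[d]
                disc = bq * bq - 4.0 * a * cq
                if disc >= 0.0:
                    root = (-bq + math.sqrt(disc)) / (2.0 * a)
                    if root >= tmax - 1e-12:
                        cand = root
                        solved = True
                        break
            if solved:
                if cand < best_T:
                    best_T = cand
                break
            # fall through to first-order attempt
    return best_T


@njit(cache=True)
def _march(F, init_flat, init_T, dirs, hs, offsets, use_second):
    n0, n1, n2 = F.shape
    n = n0 * n1 * n2
    T = np.full((n0, n1, n2), np.inf)
    frozen = np.zeros((n0, n1, n2), dtype=np.bool_)
    cap = 40 * n + 16
    keys = np.empty(cap)
    idxs = np.empty(cap, dtype=np.int64)
    size = 0
    order_out = np.empty(n, dtype=np.int64)
    n_frozen = 0
    # pre-frozen source neighborhood, already sorted by arrival time
    for i in range(init_flat.shape[0]):
        f = init_flat[i]
        x0 = f // (n1 * n2)
        x1 = (f // n2) % n1
        x2 = f % n2
        T[x0, x1, x2] = init_T[i]
        frozen[x0, x1, x2] = True
        order_out[n_frozen] = f
        n_frozen += 1
    for i in range(init_flat.shape[0]):
        f = init_flat[i]
        x0 = f // (n1 * n2)
        x1 = (f // n2) % n1
        x2 = f % n2
        for o in range(offsets.shape[0]):
            y0 = x0 + offsets[o, 0]
            y1 = x1 + offsets[o, 1]
            y2 = x2 + offsets[o, 2]
            if 0 <= y0 < n0 and 0 <= y1 < n1 and 0 <= y2 < n2:
                if not frozen[y0, y1, y2]:
                    cand = _solve_cell(T, frozen, F, y0, y1, y2, dirs, hs, use_second)
                    if cand < T[y0, y1, y2] - 1e-12:
                        T[y0, y1, y2] = cand
                        size = _heap_push(keys, idxs, size, cand, y0 * n1 * n2 + y1 * n2 + y2)
    while size > 0:
        t, f, size = _heap_pop(keys, idxs, size)
        x0 = f // (n1 * n2)
        x1 = (f // n2) % n1
        x2 = f % n2
        if frozen[x0, x1, x2]:
            continue
        frozen[x0, x1, x2] = True
        order_out[n_frozen] = f
        n_frozen += 1
        for o in range(offsets.shape[0]):
            y0 = x0 + offsets[o, 0]
            y1 = x1 + offsets[o, 1]
            y2 = x2 + offsets[o, 2]
            if 0 <= y0 < n0 and 0 <= y1 < n1 and 0 <= y2 < n2:
                if not frozen[y0, y1, y2]:
                    cand = _solve_cell(T, frozen, F, y0, y1, y2, dirs, hs, use_second)
                    # causality clamp: a downwind cell cannot precede the front
                    if cand < t:
                        cand = t
                    if cand < T[y0, y1, y2] - 1e-12:
                        T[y0, y1, y2] = cand
                        if size >= cap:  # pragma: no cover - capacity guard
                            break
                        size = _heap_push(keys, idxs, size, cand, y0 * n1 * n2 + y1 * n2 + y2)
    return T, order_out[:n_frozen]


def msfm_time_field(
    F: np.ndarray,
    seeds: np.ndarray,
    second_order: bool = True,
    source_radius: float = 4.0,
) -> ArrivalTimeField:
    """Solve ``|∇T| F = 1`` with T=0 on seed cells by multistencils marching.

    ``seeds`` is a boolean array (or an (n,3) index array) over the grid.
    Distances are in cell units; the grid is treated as isotropic.

    Fast-marching schemes lose accuracy at the rarefaction fan around a
    source; cells within ``source_radius`` of a seed are therefore
    initialized by straight-ray integration to the nearest seed with
    trapezoidal speed averaging (exact for uniform speed) before the front
    is marched.  Set ``source_radius=0`` to disable.
    """
    F = np.asarray(F, dtype=np.float64)
    if np.any(F <= 0):
        raise InputError("speed field must be strictly positive")
    if seeds.dtype == bool:
        seed_mask = seeds.copy()
    else:
        seed_arr = np.atleast_2d(np.asarray(seeds, dtype=np.int64))
        seed_mask = np.zeros(F.shape, dtype=bool)
        seed_mask[tuple(seed_arr.T)] = True
    if not seed_mask.any():
        raise InputError("seed set is empty")
    if source_radius > 0:
        dist, nearest = ndimage.distance_transform_edt(
            ~seed_mask, return_indices=True
        )
        near = dist <= source_radius
        f_seed = F[tuple(nearest[:, near])]
        t_init = dist[near] * 2.0 / (f_seed + F[near])
    else:
        near = seed_mask
        t_init = np.zeros(int(seed_mask.sum()))
    init_idx = np.flatnonzero(near.ravel())
    order_init = np.argsort(t_init, kind="stable")
    T, order = _march(
        F,
        init_idx[order_init].astype(np.int64),
        t_init[order_init],
        _STENCIL_DIRS,
        _STENCIL_H,
        _NEIGHBOR_OFFSETS.astype(np.int64),
        second_order,
    )
    return ArrivalTimeField(T=T, seeds=seed_mask, finalize_order=order)


def _interp(Tf: np.ndarray, pos: np.ndarray) -> float:
    """Trilinear interpolation of a cell-centered field (centers at integers)."""
    n = np.array(Tf.shape)
    p = np.clip(pos, 0.0, n - 1.0 - 1e-9)
    i = np.minimum(p.astype(np.int64), n - 2)
    f = p - i
    acc = 0.0
    for c0 in (0, 1):
        for c1 in (0, 1):
            for c2 in (0, 1):
                w = (
                    (f[0] if c0 else 1 - f[0])
                    * (f[1] if c1 else 1 - f[1])
                    * (f[2] if c2 else 1 - f[2])
                )
                acc += w * Tf[i[0] + c0, i[1] + c1, i[2] + c2]
    return acc


def backtrack_path(
    field: ArrivalTimeField,
    start: Sequence[int],
    params: ValidationParams = ValidationParams(),
) -> PathTrace:
    """Descend the arrival-time gradient from a cell to the seed set.

    The gradient is taken by central differences on the trilinearly
    interpolated field with a fixed step of ``step_size`` cells.  Failure to
    make progress, or exhausting the step budget, yields
    ``reached_seed=False``.
    """
    T = field.T
    start = tuple(int(s) for s in start)
    if not np.isfinite(T[start]):
        return PathTrace(np.array([start], dtype=float), False)
    finite = T[np.isfinite(T)]
    big = float(finite.max()) * 2.0 + 10.0 if len(finite) else 1.0
    Tf = np.where(np.isfinite(T), T, big)
    shape = np.array(T.shape)
    diag = float(np.linalg.norm(shape))
    max_steps = (
        params.max_steps
        if params.max_steps is not None
        else int(math.ceil(10.0 * diag / params.step_size))
    )
    pos = np.array(start, dtype=float)
    points = [pos.copy()]
    delta = 0.5
    for _ in range(max_steps):
        cell = np.clip(np.rint(pos).astype(int), 0, shape - 1)
        if field.seeds[tuple(cell)]:
            return PathTrace(np.array(points), True)
        g = np.empty(3)
        for a in range(3):
            e = np.zeros(3)
            e[a] = delta
            g[a] = (_interp(Tf, pos + e) - _interp(Tf, pos - e)) / (2 * delta)
        norm = float(np.linalg.norm(g))
        stepped = False
        if norm > 1e-12:
            new = np.clip(pos - params.step_size * g / norm, 0.0, shape - 1.0)
            decrease = _interp(Tf, pos) - _interp(Tf, new)
            # an effective step drops T by about step * |grad T|; a much
            # smaller drop means the descent is zigzagging across a narrow
            # corridor between high-T walls instead of progressing
            if decrease > max(1e-12, 0.05 * params.step_size * norm):
                pos = new
                stepped = True
        if not stepped:
            # interpolated gradient stalls (plateaus, sharp speed contrast):
            # fall back to the steepest-descent 26-neighbor, which always
            # exists for a marched field until a seed is reached
            best = None
            best_T = Tf[tuple(cell)]
            for off in np.ndindex(3, 3, 3):
                o = np.array(off) - 1
                if not o.any():
                    continue
                nb = cell + o
                if np.any(nb < 0) or np.any(nb >= shape):
                    continue
                if Tf[tuple(nb)] < best_T:
                    best_T = Tf[tuple(nb)]
                    best = nb
            if best is None:
                break
            # walk to the neighbor center in step_size increments so
            # consecutive path points stay within one step of each other
            target = best.astype(float)
            while np.linalg.norm(target - pos) > params.step_size:
                pos = pos + params.step_size * (target - pos) / np.linalg.norm(
                    target - pos
                )
                points.append(pos.copy())
            pos = target
        points.append(pos.copy())
    cell = tuple(np.clip(np.rint(pos).astype(int), 0, shape - 1))
    return PathTrace(np.array(points), bool(field.seeds[cell]))


def path_confidence(
    path: PathTrace,
    grid: DensityGrid,
    params: ValidationParams = ValidationParams(),
    seed_cells: Optional[np.ndarray] = None,
) -> float:
    """Fraction of path points lying in foreground (dense-signal) cells.

    Cells in ``seed_cells`` (the injection site) count as foreground: the
    injection site is tracer-saturated by construction, and its detected
    density is not a meaningful connectivity signal.
    """
    if len(path.points) == 0:
        raise InputError("empty path")
    shape = np.array(grid.density.shape)
    cells = np.clip(np.rint(path.points).astype(int), 0, shape - 1)
    fg = grid.density[tuple(cells.T)] > params.foreground_density_threshold
    if seed_cells is not None:
        fg |= seed_cells[tuple(cells.T)]
    return float(np.mean(fg))


def _upsample_cells(cell_field: np.ndarray, kv, out_shape) -> np.ndarray:
    out = cell_field
    for a in range(3):
        out = np.repeat(out, kv[a], axis=a)
    return out[: out_shape[0], : out_shape[1], : out_shape[2]]


def validate_signal(
    mask: BinaryMask,
    injection: BinaryMask,
    params: ValidationParams = ValidationParams(),
    override_remove: Optional[BinaryMask] = None,
    report_path: Optional[Union[str, Path]] = None,
) -> BinaryMask:
    """Remove detected signal not connected to the injection site.

    Builds the density grid, marches from cells overlapping the injection
    mask, back-tracks every signal-bearing cell, and clears all mask voxels
    in cells that fail to reach a seed or reach it with confidence below the
    cutoff.  Cells overlapping the injection site are kept as-is (they are
    excluded from quantification separately).  ``override_remove`` voxels
    are cleared last (the stand-in for manual noise inspection).
    """
    if mask.shape != injection.shape:
        raise GeometryError("signal and injection masks must share geometry")
    if not injection.data.any():
        raise InputError("injection mask is empty")
    grid = compute_density_grid(mask, params.cell_size_um)
    inj_cells = _block_sum(injection.data, grid.voxels_per_cell) > 0
    F = density_to_speed(grid, params)
    # injection seeds are extended regions, not point sources, and the speed
    # field is heterogeneous: skip straight-ray source initialization
    field = msfm_time_field(F, inj_cells, source_radius=0.0)
    keep = inj_cells.copy()
    rows = []
    for cell in np.argwhere((grid.density > 0) & ~inj_cells):
        path = backtrack_path(field, cell, params)
        conf = (
            path_confidence(path, grid, params, seed_cells=inj_cells)
            if path.reached_seed
            else 0.0
        )
        ok = path.reached_seed and conf >= params.confidence_cutoff
        keep[tuple(cell)] = ok
        rows.append(
            {
                "cell": tuple(int(c) for c in cell),
                "reached_seed": path.reached_seed,
                "confidence": conf,
                "kept": ok,
            }
        )
    keep_vox = _upsample_cells(keep, grid.voxels_per_cell, mask.shape)
    out = mask.data & keep_vox
    if override_remove is not None:
        out = out & ~override_remove.data
    if report_path is not None:
        pd.DataFrame(rows).to_csv(report_path, index=False)
    return BinaryMask(out, mask.voxel_size_um, mask.origin_um)
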