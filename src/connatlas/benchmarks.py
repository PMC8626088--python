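"""Self-contained recovery studies on synthetic ground truth.

Each study builds a toy brain at the standard desk-scale conditions
(100 µm cube at 1 µm isotropic, 8 regions, 200 axons or 6 somata per region,
SNR 30), runs the full detection → validation → quantification chain, and
scores it against the planted truth.  Used by the acceptance checks and by
the reproduction script; the functions are deterministic given their seed.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import DetectionParams, detect_volume
from .marching import ValidationParams, validate_signal
from .quantify import quantify_inputs, quantify_outputs
from .somata import assign_somata, default_size_band, detect_somata
from .synthetic import (
    SimulationConfig,
    add_background_and_noise,
    make_toy_atlas,
    scatter_noise_blobs,
    simulate_axons,
    simulate_somata,
)


def study_detection_params(config: SimulationConfig) -> DetectionParams:
    """Detection settings for the synthetic study.

    The Yen clip floor is predetermined from the nominal tracer amplitude
    (one third of it), the synthetic analog of a dataset-specific
    predetermined threshold range.
    """
    return DetectionParams(yen_clip_min=config.signal_amplitude / 3.0)


def study_axon_world(seed: int):
    """One synthetic axon study: atlas, config, noisy volume and truth.

    The projection profile is selective — four of the seven non-injection
    regions receive axons (fractions 0.4/0.3/0.2/0.1), as in real tracing
    data — which leaves genuinely empty territory where isolated speckle
    noise can be planted.
    """
    annotation, table = make_toy_atlas((100, 100, 100), 8, seed=seed)
    targets = sorted(
        r for r in table.analysis_ids if r not in table.injection_ids
    )[:4]
    fractions = dict(zip(targets, (0.4, 0.3, 0.2, 0.1)))
    cfg = SimulationConfig(seed=seed, target_fractions=fractions)
    vol, truth = simulate_axons(annotation, table, cfg)
    noisy = add_background_and_noise(vol, cfg)
    return annotation, table, cfg, noisy, truth


def output_recovery_study(seed: int, n_noise_blobs: int = 100) -> Dict[str, float]:
    """Detect, validate and quantify one axon volume against planted truth.

    Returns voxel F1 of detection, the fraction of planted isolated noise
    removed and of true (detected) tube voxels retained by path validation,
    and the per-region output-fraction recovery (max absolute error and
    Pearson r vs the planted fractions, injection region excluded).
    """
    annotation, table, cfg, noisy, truth = study_axon_world(seed)
    mask = detect_volume(noisy, study_detection_params(cfg))

    planted = truth.planted_signal_mask.data
    tp = int((mask.data & planted).sum())
    precision = tp / max(int(mask.data.sum()), 1)
    recall = tp / int(planted.sum())
    f1 = 2 * precision * recall / max(precision + recall, 1e-12)

    combined, blobs = scatter_noise_blobs(
        mask, n_noise_blobs, 1.2, 25.0, seed=seed + 10_000, annotation=annotation
    )
    validated = validate_signal(combined, truth.injection_mask, ValidationParams())
    noise_removed = 1.0 - (validated.data & blobs.data).sum() / max(
        int(blobs.data.sum()), 1
    )
    true_detected = mask.data & planted
    tube_retained = (validated.data & true_detected).sum() / int(true_detected.sum())

    profile = quantify_outputs(validated, annotation, table, truth.injection_mask)
    est = {
        r: v for r, v in profile.proportion.items() if r != truth.injection_region
    }
    total = sum(est.values())
    est = {r: v / total for r, v in est.items()}
    regions = sorted(truth.true_output_fraction)
    tv = np.array([truth.true_output_fraction[r] for r in regions])
    ev = np.array([est.get(r, 0.0) for r in regions])
    return {
        "detection_f1": f1,
        "noise_removed": float(noise_removed),
        "tube_retained": float(tube_retained),
        "fraction_max_abs_err": float(np.abs(tv - ev).max()),
        "fraction_pearson_r": float(np.corrcoef(tv, ev)[0, 1]),
    }


def soma_recovery_study(seed: int) -> Dict[str, float]:
    """Detect and assign somata in one volume; score vs planted coordinates.

    Matching is a Hungarian assignment with match radius = soma radius.
    """
    annotation, table = make_toy_atlas((100, 100, 100), 8, seed=seed)
    cfg = SimulationConfig(seed=seed)
    vol, truth = simulate_somata(annotation, table, cfg)
    noisy = add_background_and_noise(vol, cfg)
    mask = detect_volume(noisy, study_detection_params(cfg))
    mn, mx = default_size_band(cfg.soma_radius_voxels)
    somas = detect_somata(noisy, mask, mn, mx, cfg.soma_radius_voxels)
    somas = assign_somata(somas, annotation, table, truth.injection_mask)

    planted = np.array(
        [c for cs in truth.soma_coordinates_um.values() for c in cs]
    )
    detected = somas[["x_um", "y_um", "z_um"]].to_numpy()
    if len(detected) == 0:
        return {"recall": 0.0, "precision": 0.0, "proportion_max_abs_err": 1.0}
    D = np.linalg.norm(planted[:, None, :] - detected[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(D)
    matched = int((D[ri, ci] <= cfg.soma_radius_voxels).sum())
    profile = quantify_inputs(somas, table)
    true_prop = {
        r: len(cs) / len(planted) for r, cs in truth.soma_coordinates_um.items()
    }
    max_err = max(
        abs(profile.proportion.get(r, 0.0) - p) for r, p in true_prop.items()
    )
    return {
        "recall": matched / len(planted),
        "precision": matched / len(detected),
        "proportion_max_abs_err": float(max_err),
    }


def msfm_euclidean_benchmark(n: int = 41) -> float:
    """Max relative error of arrival times vs exact Euclidean distance.

    Uniform speed, point seed at the grid center, measured at cells at least
    5 cells from the seed.
    """
    from .marching import msfm_time_field

    F = np.ones((n, n, n))
    seeds = np.zeros((n, n, n), dtype=bool)
    c = n // 2
    seeds[c, c, c] = True
    field = msfm_time_field(F, seeds)
    g = np.indices((n, n, n)).astype(float)
    dist = np.sqrt(((g - c) ** 2).sum(axis=0))
    far = dist >= 5
    return float((np.abs(field.T[far] - dist[far]) / dist[far]).max())
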