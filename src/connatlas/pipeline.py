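"""Config-driven end-to-end runs: simulate → detect → validate → quantify → stats.

A run is described by one JSON/YAML config (see :func:`default_config`) and
executes on a synthetic study: a toy atlas shared by all samples, one axon
(output) volume and one soma (input) volume per sample, group-specific
projection-target profiles so the group structure is recoverable by the
statistics stage.  Every intermediate artifact is written under the output
directory, and a manifest records inputs, parameters, software version,
per-stage artifact checksums and wall-clock times.  All randomness descends
from one root seed, split deterministically per (stage, group, sample), so
re-running an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detection import DetectionParams, detect_volume
from .errors import ConfigurationError, DependencyError
from .io_atlas import (
    AnnotationVolume,
    BinaryMask,
    load_region_table,
    read_mask,
    read_volume,
    write_region_table,
    write_volume,
)
from .marching import ValidationParams, validate_signal
from .quantify import (
    ConnectivityProfile,
    output_input_ratio,
    quantify_inputs,
    quantify_outputs,
    ratio_table,
    write_profiles_csv,
)
from .somata import assign_somata, detect_somata, default_size_band, write_soma_csv
from .stats import GroupMatrix, anova_tukey_all, bootstrap_support, correlation_matrix
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    add_background_and_noise,
    injection_sphere,
    make_toy_atlas,
    simulate_axons,
    simulate_somata,
)

STAGES = ["simulate", "detect", "validate", "quantify", "stats"]

_STAGE_TAG = {s: i for i, s in enumerate(STAGES)}


def derive_seed(root: int, *indices: int) -> int:
    """Deterministic child seed below 2^31 from a root seed and index path."""
    ss = np.random.SeedSequence([int(root), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


def default_config(out_dir: str = "runs/demo", seed: int = 0) -> Dict:
    """Demo study: 2 groups × 2 samples on a 60³ toy brain with 6 regions."""
    return {
        "seed": seed,
        "output_dir": out_dir,
        "simulate": {
            "shape": [60, 60, 60],
            "n_regions": 6,
            "groups": ["G1", "G2"],
            "samples_per_group": 2,
            "n_axons": 120,
            "axon_radius_voxels": 2.0,
            "tortuosity": 0.3,
            "somata_per_region": 4,
            "soma_radius_voxels": 2.5,
            "signal_amplitude": 300.0,
            "noise_sigma": 10.0,
            "background_gradient": 20.0,
            "injection_radius_um": 8.0,
        },
        "detection": {},
        "validation": {"confidence_cutoff": 0.8, "foreground_density_threshold": 0.05},
        "stats": {"n_boot": 200, "alpha": 0.05},
    }


def load_config(path) -> Dict:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: Dict) -> None:
    if "output_dir" not in cfg:
        raise ConfigurationError("config needs output_dir")
    needs_seed = "simulate" in cfg or cfg.get("stats", {}).get("n_boot", 0) > 0
    if needs_seed and "seed" not in cfg:
        raise ConfigurationError("config needs a root seed for stochastic stages")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _group_fractions(region_ids: List[int], group_index: int) -> Dict[int, float]:
    """Group-specific target-fraction profile.

    Each group concentrates 70% of its projections on a group-specific half
    of the target regions, so groups are distinguishable but overlapping.
    """
    k = len(region_ids)
    half = max(1, k // 2)
    favored = [region_ids[(group_index * half + i) % k] for i in range(half)]
    w = {r: (3.0 if r in favored else 1.0) for r in region_ids}
    total = sum(w.values())
    return {r: v / total for r, v in w.items()}


class PipelineRun:
    """Stateful runner over one config; stages write into ``output_dir``."""

    def __init__(self, config: Dict):
        validate_config(config)
        self.cfg = config
        self.out = Path(config["output_dir"])
        self.manifest_path = self.out / "manifest.json"

    # -- helpers -----------------------------------------------------------

    def _samples(self):
        sim = self.cfg["simulate"]
        for gi, group in enumerate(sim["groups"]):
            for si in range(sim["samples_per_group"]):
                yield gi, group, si, f"{group}_s{si}"

    def _require(self, path: Path, producer: str) -> Path:
        if not path.exists():
            raise DependencyError(
                f"missing artifact {path}; run the '{producer}' stage first"
            )
        return path

    def _record(self, stage: str, artifacts: List[Path], elapsed: float) -> None:
        manifest = {}
        if self.manifest_path.exists():
            manifest = json.loads(self.manifest_path.read_text())
        manifest.setdefault("version", __version__)
        manifest["config"] = self.cfg
        manifest.setdefault("stages", {})
        manifest["stages"][stage] = {
            "artifacts": {
                str(p.relative_to(self.out)): _sha256(p) for p in artifacts
            },
            "wall_clock_s": round(elapsed, 3),
        }
        self.manifest_path.write_text(json.dumps(manifest, indent=2))

    # -- stages ------------------------------------------------------------

    def simulate(self) -> List[Path]:
        t0 = time.time()
        sim = self.cfg["simulate"]
        seed = self.cfg["seed"]
        atlas_dir = self.out / "atlas"
        sim_dir = self.out / "sim"
        atlas_dir.mkdir(parents=True, exist_ok=True)
        sim_dir.mkdir(parents=True, exist_ok=True)
        annotation, table = make_toy_atlas(
            tuple(sim["shape"]), sim["n_regions"], derive_seed(seed, 0, 0)
        )
        write_volume(annotation, atlas_dir / "annotation.nrrd")
        write_region_table(table, atlas_dir / "regions.csv")
        injection = injection_sphere(annotation, table, sim.get("injection_radius_um", 8.0))
        write_volume(injection, atlas_dir / "injection.nrrd")
        artifacts = [
            atlas_dir / "annotation.nrrd",
            atlas_dir / "regions.csv",
            atlas_dir / "injection.nrrd",
        ]
        target_ids = [r for r in table.analysis_ids if r not in table.injection_ids]
        for gi, group, si, name in self._samples():
            s_seed = derive_seed(seed, _STAGE_TAG["simulate"], gi, si)
            # input strength varies by region and group (a flat soma count
            # would make every input profile identical and uninformative)
            in_frac = _group_fractions(target_ids, gi + 1)
            n_soma = sim.get("somata_per_region", 4) * len(target_ids)
            soma_counts = {
                r: max(1, int(round(n_soma * f))) for r, f in in_frac.items()
            }
            cfg = SimulationConfig(
                shape=tuple(sim["shape"]),
                n_regions=sim["n_regions"],
                target_fractions=_group_fractions(target_ids, gi),
                n_axons=sim.get("n_axons", 120),
                axon_radius_voxels=sim.get("axon_radius_voxels", 2.0),
                tortuosity=sim.get("tortuosity", 0.3),
                somata_per_region=soma_counts,
                soma_radius_voxels=sim.get("soma_radius_voxels", 2.5),
                signal_amplitude=sim.get("signal_amplitude", 300.0),
                noise_sigma=sim.get("noise_sigma", 10.0),
                background_gradient=sim.get("background_gradient", 20.0),
                injection_radius_um=sim.get("injection_radius_um", 8.0),
                seed=s_seed,
            )
            axons, truth_out = simulate_axons(annotation, table, cfg)
            axons = add_background_and_noise(axons, cfg, derive_seed(s_seed, 1))
            somata, truth_in = simulate_somata(annotation, table, cfg)
            somata = add_background_and_noise(somata, cfg, derive_seed(s_seed, 2))
            write_volume(axons, sim_dir / f"{name}_axons.nrrd")
            write_volume(somata, sim_dir / f"{name}_somata.nrrd")
            write_volume(
                truth_out.planted_signal_mask, sim_dir / f"{name}_planted_mask.nrrd"
            )
            truth_json = {
                "true_output_fraction": {
                    str(k): v for k, v in truth_out.true_output_fraction.items()
                },
                "soma_counts": {str(k): v for k, v in truth_in.soma_counts.items()},
                "injection_region": truth_out.injection_region,
                "seed": s_seed,
            }
            (sim_dir / f"{name}_truth.json").write_text(json.dumps(truth_json, indent=2))
            soma_rows = [
                {"region": r, "x_um": c[0], "y_um": c[1], "z_um": c[2]}
                for r, cs in truth_in.soma_coordinates_um.items()
                for c in cs
            ]
            pd.DataFrame(
                soma_rows, columns=["region", "x_um", "y_um", "z_um"]
            ).to_csv(sim_dir / f"{name}_true_somata.csv", index=False)
            artifacts += [
                sim_dir / f"{name}_axons.nrrd",
                sim_dir / f"{name}_somata.nrrd",
                sim_dir / f"{name}_planted_mask.nrrd",
                sim_dir / f"{name}_truth.json",
                sim_dir / f"{name}_true_somata.csv",
            ]
        self._record("simulate", artifacts, time.time() - t0)
        return artifacts

    def detect(self) -> List[Path]:
        t0 = time.time()
        det_dir = self.out / "detect"
        det_dir.mkdir(parents=True, exist_ok=True)
        params = DetectionParams(**self.cfg.get("detection", {}))
        artifacts = []
        for _gi, _group, _si, name in self._samples():
            for kind in ("axons", "somata"):
                vol = read_volume(
                    self._require(self.out / "sim" / f"{name}_{kind}.nrrd", "simulate")
                )
                mask = detect_volume(
                    vol, params, log_path=det_dir / f"{name}_{kind}_thresholds.csv"
                )
                write_volume(mask, det_dir / f"{name}_{kind}_mask.nrrd")
                artifacts += [
                    det_dir / f"{name}_{kind}_mask.nrrd",
                    det_dir / f"{name}_{kind}_thresholds.csv",
                ]
        self._record("detect", artifacts, time.time() - t0)
        return artifacts

    def validate(self) -> List[Path]:
        t0 = time.time()
        val_dir = self.out / "validate"
        val_dir.mkdir(parents=True, exist_ok=True)
        params = ValidationParams(**self.cfg.get("validation", {}))
        injection = read_mask(self._require(self.out / "atlas" / "injection.nrrd", "simulate"))
        artifacts = []
        for _gi, _group, _si, name in self._samples():
            mask = read_mask(
                self._require(self.out / "detect" / f"{name}_axons_mask.nrrd", "detect")
            )
            validated = validate_signal(
                mask,
                injection,
                params,
                report_path=val_dir / f"{name}_validation_report.csv",
            )
            write_volume(validated, val_dir / f"{name}_validated.nrrd")
            artifacts += [
                val_dir / f"{name}_validated.nrrd",
                val_dir / f"{name}_validation_report.csv",
            ]
        self._record("validate", artifacts, time.time() - t0)
        return artifacts

    def quantify(self) -> List[Path]:
        t0 = time.time()
        q_dir = self.out / "quantify"
        q_dir.mkdir(parents=True, exist_ok=True)
        annotation_v = read_volume(
            self._require(self.out / "atlas" / "annotation.nrrd", "simulate")
        )
        annotation = AnnotationVolume(
            annotation_v.data.astype(np.int32),
            annotation_v.voxel_size_um,
            annotation_v.origin_um,
        )
        table = load_region_table(self.out / "atlas" / "regions.csv")
        injection = read_mask(self.out / "atlas" / "injection.nrrd")
        sim = self.cfg["simulate"]
        soma_radius = sim.get("soma_radius_voxels", 2.5)
        min_v, max_v = default_size_band(soma_radius)
        out_profiles: List[ConnectivityProfile] = []
        in_profiles: List[ConnectivityProfile] = []
        artifacts = []
        for _gi, group, _si, name in self._samples():
            validated = read_mask(
                self._require(self.out / "validate" / f"{name}_validated.nrrd", "validate")
            )
            out_profiles.append(
                quantify_outputs(
                    validated, annotation, table, injection, sample=name, group=group
                )
            )
            soma_mask = read_mask(
                self._require(self.out / "detect" / f"{name}_somata_mask.nrrd", "detect")
            )
            soma_vol = read_volume(self.out / "sim" / f"{name}_somata.nrrd")
            somas = detect_somata(soma_vol, soma_mask, min_v, max_v, soma_radius)
            somas = assign_somata(somas, annotation, table, injection)
            write_soma_csv(somas, q_dir / f"{name}_somata.csv")
            in_profiles.append(
                quantify_inputs(somas, table, sample=name, group=group)
            )
            artifacts.append(q_dir / f"{name}_somata.csv")
        write_profiles_csv(out_profiles + in_profiles, q_dir / "profiles.csv")
        artifacts.append(q_dir / "profiles.csv")
        # per-group mean profiles -> output/input ratio table
        for group in sim["groups"]:
            o = _mean_profile([p for p in out_profiles if p.group == group])
            i = _mean_profile([p for p in in_profiles if p.group == group])
            regions = sorted(set(o.proportion) | set(i.proportion))
            for prof in (o, i):
                for r in regions:
                    prof.proportion.setdefault(r, 0.0)
            ratio_table(output_input_ratio(o, i), table).to_csv(
                q_dir / f"ratios_{group}.csv", index=False
            )
            artifacts.append(q_dir / f"ratios_{group}.csv")
        self._record("quantify", artifacts, time.time() - t0)
        return artifacts

    def stats(self) -> List[Path]:
        t0 = time.time()
        s_dir = self.out / "stats"
        s_dir.mkdir(parents=True, exist_ok=True)
        prof_path = self._require(self.out / "quantify" / "profiles.csv", "quantify")
        df = pd.read_csv(prof_path)
        st = self.cfg.get("stats", {})
        artifacts = []
        for modality in ("output", "input"):
            sub = df[df["modality"] == modality]
            wide = sub.pivot_table(
                index="sample", columns="region", values="proportion", fill_value=0.0
            )
            groups = sub.drop_duplicates("sample").set_index("sample")["group"]
            M = GroupMatrix(wide, groups.reindex(wide.index))
            correlation_matrix(M).to_csv(s_dir / f"correlation_{modality}.csv")
            anova_tukey_all(M, st.get("alpha", 0.05)).to_csv(
                s_dir / f"anova_{modality}.csv", index=False
            )
            artifacts += [
                s_dir / f"correlation_{modality}.csv",
                s_dir / f"anova_{modality}.csv",
            ]
            if M.n_samples >= 3 and st.get("n_boot", 0) >= 100:
                tree = bootstrap_support(
                    M,
                    n_boot=st["n_boot"],
                    seed=derive_seed(self.cfg["seed"], _STAGE_TAG["stats"]),
                )
                tree.to_json(s_dir / f"cluster_{modality}.json")
                artifacts.append(s_dir / f"cluster_{modality}.json")
        self._record("stats", artifacts, time.time() - t0)
        return artifacts

    # -- entry points ------------------------------------------------------

    def run_stage(self, stage: str) -> List[Path]:
        if stage not in STAGES:
            raise ConfigurationError(f"unknown stage {stage!r}; one of {STAGES}")
        return getattr(self, stage)()

    def run_all(self) -> Dict:
        for stage in STAGES:
            self.run_stage(stage)
        return json.loads(self.manifest_path.read_text())


def _mean_profile(profiles: List[ConnectivityProfile]) -> ConnectivityProfile:
    regions = sorted({r for p in profiles for r in p.regions})
    mean = {
        r: float(np.mean([p.proportion.get(r, 0.0) for p in profiles]))
        for r in regions
    }
    total = sum(mean.values())
    return ConnectivityProfile(
        sample="mean",
        modality=profiles[0].modality,
        group=profiles[0].group,
        raw=mean,
        proportion={r: v / total for r, v in mean.items()},
    )
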