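"""Per-region connectivity profiles, ratios and profile similarity.

Outputs are quantified as validated projection-signal volume per analysis
region, normalized by total signal volume with the injection site excluded
from numerator and denominator alike; inputs as the per-region count of
detected somata normalized by the total count, excluding somata inside the
injection site.  At 1 µm isotropic resolution a voxel count *is* a volume in
µm³.  Reciprocity per region is the output/input proportion ratio, bucketed
as input-biased (< 0.25), balanced (0.25–4, boundaries inclusive) or
output-biased (> 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateProfileError, GeometryError, InputError
from .io_atlas import (
    NON_ANNOTATED_ID,
    OTHERS_ID,
    AnnotationVolume,
    BinaryMask,
    RegionTable,
    collapse_to_analysis,
)

RATIO_BALANCED_LOW = 0.25
RATIO_BALANCED_HIGH = 4.0


@dataclass
class ConnectivityProfile:
    """Normalized per-region proportions for one sample and modality."""

    sample: str
    modality: str  # "input" | "output"
    group: str
    raw: Dict[int, float] = field(default_factory=dict)
    proportion: Dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in ("input", "output"):
            raise InputError(f"modality must be input/output, got {self.modality!r}")

    @property
    def regions(self) -> List[int]:
        return sorted(self.proportion)

    def vector(self, regions: Optional[List[int]] = None) -> np.ndarray:
        regions = self.regions if regions is None else regions
        return np.array([self.proportion.get(r, 0.0) for r in regions])

    def to_frame(self) -> pd.DataFrame:
        regs = self.regions
        return pd.DataFrame(
            {
                "sample": self.sample,
                "group": self.group,
                "modality": self.modality,
                "region": regs,
                "raw": [self.raw.get(r, 0.0) for r in regs],
                "proportion": [self.proportion[r] for r in regs],
            }
        )


def write_profiles_csv(
    profiles: List[ConnectivityProfile], path: Union[str, Path]
) -> None:
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, index=False
    )


def _normalize(raw: Dict[int, float]) -> Dict[int, float]:
    total = float(sum(raw.values()))
    if total <= 0:
        raise DegenerateProfileError(
            "no signal/somata outside the injection site to normalize"
        )
    return {r: v / total for r, v in raw.items()}


def quantify_outputs(
    validated_mask: BinaryMask,
    annotation: AnnotationVolume,
    table: RegionTable,
    injection_mask: BinaryMask,
    sample: str = "sample",
    group: str = "group",
) -> ConnectivityProfile:
    """Per-region proportions of validated projection-signal volume.

    Voxels inside the injection mask are excluded before counting; every
    remaining foreground voxel is attributed to the analysis region of its
    atlas label (Others / non-annotated included).
    """
    for other in (annotation, injection_mask):
        if validated_mask.shape != other.shape:
            raise GeometryError("mask, annotation and injection geometry differ")
    counted = validated_mask.data & ~injection_mask.data
    labels = annotation.data[counted]
    raw: Dict[int, float] = {}
    for lab, cnt in zip(*np.unique(labels, return_counts=True)):
        analysis = collapse_to_analysis(int(lab), table)
        raw[analysis] = raw.get(analysis, 0.0) + float(cnt)
    return ConnectivityProfile(
        sample=sample, modality="output", group=group, raw=raw,
        proportion=_normalize(raw),
    )


def quantify_inputs(
    somata: pd.DataFrame,
    table: RegionTable,
    sample: str = "sample",
    group: str = "group",
) -> ConnectivityProfile:
    """Per-region proportions of input-neuron counts.

    Somata flagged ``excluded`` (inside the injection site) are dropped from
    numerator and denominator.
    """
    kept = somata.loc[~somata["excluded"].astype(bool)]
    raw = {
        int(r): float(c) for r, c in kept["region_id"].value_counts().items()
    }
    return ConnectivityProfile(
        sample=sample, modality="input", group=group, raw=raw,
        proportion=_normalize(raw),
    )


@dataclass
class RatioRecord:
    region: int
    output_proportion: float
    input_proportion: float
    ratio: float  # may be +inf
    category: str  # input-biased | balanced | output-biased | undefined


def categorize_ratio(ratio: float) -> str:
    """Bucket an output/input ratio; NaN means both proportions were zero."""
    if math.isnan(ratio):
        return "undefined"
    if ratio < RATIO_BALANCED_LOW:
        return "input-biased"
    if ratio > RATIO_BALANCED_HIGH:
        return "output-biased"
    return "balanced"


def output_input_ratio(
    output_profile: ConnectivityProfile, input_profile: ConnectivityProfile
) -> List[RatioRecord]:
    """Per-region reciprocity of outputs to inputs.

    Zero input with nonzero output maps to +inf (output-biased); zero of
    both is undefined.  Both profiles must cover the same region set.
    """
    if set(output_profile.regions) != set(input_profile.regions):
        raise InputError("profiles cover different region sets")
    records = []
    for region in output_profile.regions:
        o = output_profile.proportion[region]
        i = input_profile.proportion[region]
        if i == 0:
            ratio = float("nan") if o == 0 else float("inf")
        else:
            ratio = o / i
        records.append(RatioRecord(region, o, i, ratio, categorize_ratio(ratio)))
    return records


def ratio_table(
    records: List[RatioRecord], table: Optional[RegionTable] = None
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "region": [r.region for r in records],
            "output_proportion": [r.output_proportion for r in records],
            "input_proportion": [r.input_proportion for r in records],
            "ratio": [r.ratio for r in records],
            "category": [r.category for r in records],
        }
    )
    if table is not None:
        df.insert(1, "acronym", [table.acronym(r.region) for r in records])
    return df


def profile_similarity(
    p: ConnectivityProfile, q: ConnectivityProfile
) -> float:
    """Pearson correlation between two profiles over their common region set."""
    if set(p.regions) != set(q.regions):
        raise InputError("profiles cover different region sets")
    regions = p.regions
    if len(regions) < 3:
        raise InputError("need at least 3 regions for a correlation")
    a, b = p.vector(regions), q.vector(regions)
    if np.std(a) == 0 or np.std(b) == 0:
        raise InputError("zero-variance profile: correlation undefined")
    return float(sstats.pearsonr(a, b).statistic)
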