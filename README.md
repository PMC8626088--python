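# connatlas

Quantification of whole-brain neuronal connectivity from tracer-labeled 3D
fluorescence volumes registered to a hierarchical brain atlas.

Viral tracing experiments label two complementary things: the **outputs** of
a genetically targeted neuron population (anterograde tracer filling its
axons throughout the brain) and its **inputs** (retrograde trans-synaptic
tracer lighting up the somata of presynaptic neurons).  Imaged at
micron-scale resolution and registered to a common coordinate atlas, one
brain becomes a multi-terabyte volume in which labeled signal must be
separated from background, spurious detections must be discarded, and what
remains must be aggregated into per-region connectivity profiles that can be
compared across animals and neuron groups.  `connatlas` implements that
computational arm as a tested, reusable library and pipeline, together with
a synthetic-data generator that plants axon tracts, somata, background and
sensor noise with exact ground truth, so every stage is verifiable at desk
scale.

## The method

**Detection.** Each coronal section `I` is processed independently: a
background field `B` is estimated by clipping the section at its median and
running ten passes of a 9×9 uniform-mean filter; the section is background
subtracted (`max(I − B, 0)`) and smoothed with a 5×5 Gaussian; the smoothed
section is binarized at the per-pixel threshold

```
T(p) = max(m · B(p), t),      t = clip(t_Yen, [t_min, t_max])
```

where `t_Yen` maximizes Yen's maximum-correlation criterion on the section
histogram, the clip range is predetermined per dataset, and `m = 4` guards
against residual background.

**Path validation.** The detected mask is reduced to a signal-density grid
(10 µm cells; density = fraction of foreground voxels per cell).  Density
maps to a front speed `F = density + ε`, and the eikonal equation
`|∇T| · F = 1` is solved outward from the injection site with a
multistencils fast-marching solver (second-order upwind differences on
axis-aligned and edge-diagonal stencils).  Every signal-bearing cell is
back-tracked down `∇T`; the **path confidence** is the fraction of
back-tracking points in foreground cells (density > 0.05), and cells that
cannot reach the injection site or reach it with confidence < 0.8 have
their voxels removed as unconnected noise.

**Quantification.** Outputs: validated signal volume per analysis region,
normalized over the whole brain with the hand-segmented injection site
excluded from numerator and denominator.  Inputs: detected somata
(connected components + watershed splitting + centroid merging) assigned to
regions through the annotation volume, with injection-site somata excluded,
normalized to proportions.  Per-region reciprocity is the output/input
ratio, bucketed as input-biased (< 0.25), balanced (0.25–4) or
output-biased (> 4).

**Statistics.** Pearson correlation between profiles, per-region one-way
ANOVA with Tukey HSD multiple comparisons, and hierarchical clustering
(correlation distance, average linkage) with multiscale-bootstrap support
values (BP, and approximately-unbiased AU from the probit fit across
resample scales).

## Worked example

Build a synthetic brain (100 µm cube at 1 µm, 8 regions, 200 axons into a
selective 0.4/0.3/0.2/0.1 target profile), run detection → validation →
quantification, and compare against the planted truth:

```python
from connatlas.benchmarks import study_axon_world, study_detection_params
from connatlas.detection import detect_volume
from connatlas.marching import validate_signal
from connatlas.quantify import quantify_outputs

annotation, table, cfg, volume, truth = study_axon_world(seed=1)
mask = detect_volume(volume, study_detection_params(cfg))
validated = validate_signal(mask, truth.injection_mask)
profile = quantify_outputs(validated, annotation, table, truth.injection_mask)

est = {r: v for r, v in profile.proportion.items() if r != truth.injection_region}
total = sum(est.values())
print("region  estimated  planted")
for region in sorted(truth.true_output_fraction):
    print(f"{table.acronym(region):>6}  {est.get(region, 0.0)/total:9.3f}  "
          f"{truth.true_output_fraction[region]:7.3f}")
```

prints

```
region  estimated  planted
    R1      0.138    0.147
    R3      0.340    0.338
    R4      0.364    0.358
    R5      0.151    0.150
    R6      0.000    0.000
    R7      0.000    0.000
    R8      0.007    0.007
```

— the four target regions' output fractions are recovered to within about
0.01 absolute, and the non-target regions stay at essentially zero.  The
recovery benchmarks additionally plant isolated speckle noise and score how
much of it path validation removes.

## Command-line pipeline

A config-driven runner executes synthetic generation → detection →
validation → quantification → statistics, writing every intermediate
artifact and a manifest with parameter echo and per-artifact checksums:

```sh
connatlas init-config --out demo.json --seed 0
connatlas run-all --config demo.json
```

Stage subcommands (`simulate`, `detect`, `validate`, `quantify`, `stats`)
run one stage at a time and fail with a named dependency error when an
upstream artifact is missing.  Identical configs reproduce byte-identical
outputs.

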