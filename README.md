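# vesselperm

Quantification of microvascular wall permeability from time-lapse
fluorescence imaging of perfused microvessels-on-a-chip, for groups
studying vessel stabilization by perivascular cells (pericytes) in
organotypic microfluidic models — e.g. comparing vessels supported by
tumor-derived versus matched normal mesenchymal cells.

In the assay, endothelial microvessel networks self-assemble in a
circular chamber (diameter 2.4 mm) and are perfused with fluorescent
70 kDa RITC-dextran; the chamber is imaged every 10 s for up to 10 min.
Tracer leaking across the vessel wall raises the intensity around each
vessel, and for a cylindrical segment of radius *r* the permeability
coefficient is

```
P = (1/ΔI) · (dI/dt) · (r/2)
```

with ΔI the initial intensity increase when dye fills the lumen and
dI/dt the subsequent slow rise of the segment window's mean intensity
(P in µm/s for r in µm, t in s). Five to seven segments are evaluated
per chip and two to six chips per sample; the package aggregates
segments → chips → samples and runs the assay's statistical battery
(Wilcoxon signed-rank for matched samples, Mann-Whitney otherwise,
Student's t, one-way ANOVA + Newman-Keuls — exact small-sample p-values
by full enumeration). Companion readouts are included: mean intensity
over a 1.5 mm × 1.5 mm region, geometric mean fluorescence intensity
(MFI) of flow-cytometry event tables, and 2^−ΔΔCT relative expression
against 3 reference genes and a calibrator sample.

Because no raw clinical stacks are distributed with the assay, the
package ships a first-class synthetic phantom generator
(`vesselperm.phantom`) that renders ground-truthed perfusion
experiments — tube geometry, dye arrival, fill, wall leak, bleaching,
noise — so the entire estimation chain is testable against known true
permeability. See `docs/methods.md` for the model and all numerical
conventions.

## Worked example

Simulate one "tumor-like" chip (6 segments, true P = 0.15 µm/s,
1% noise), segment it, and estimate permeability per segment:

```python
from vesselperm import (
    PhantomConfig, simulate_experiment, choose_reference_frames,
    segment_lumen, extract_segments, analyze_stack, aggregate,
)

cfg = PhantomConfig(
    chamber_diameter_um=1600, pixel_size_um=4.0, n_segments=6,
    true_permeability_um_s=0.15, noise_sd=1.0, seed=42,
)
stack, truth = simulate_experiment(cfg)
mask = segment_lumen(stack, choose_reference_frames(stack))
segments = extract_segments(mask, stack.pixel_size_um, chip_id="chip0")
records = analyze_stack(stack, segments, sample_id="pt1", condition="tumor")
print(records[["segment_id", "radius_um", "delta_i", "slope", "p_um_s"]].round(4))
print(aggregate(records, "chip")[["chip_id", "p_um_s", "n_segments"]].round(4))
```

prints

```
  segment_id  radius_um  delta_i   slope  p_um_s
0     seg000    28.4631  53.1837  0.5407  0.1447
1     seg001    14.0000  35.3300  0.7287  0.1444
2     seg002    23.2982  48.9782  0.5767  0.1372
3     seg003    12.4222  35.6544  0.7485  0.1304
4     seg004    22.0000  46.0825  0.5952  0.1421
5     seg005    23.2982  47.7820  0.5698  0.1389
  chip_id  p_um_s  n_segments
0   chip0  0.1396  6
```

Each row is one cylindrical segment: its estimated radius (µm), fill
step ΔI (intensity units), leak slope dI/dt (intensity/s), and
P = slope/ΔI·r/2 (µm/s). The chip value is the mean of its segments —
here 0.1396 µm/s against a ground truth of 0.15, a 7% error dominated
by the half-pixel radius quantization at 4 µm/px. Group comparison then
takes one such value per chip:

```python
from vesselperm import compare_groups
result = compare_groups(chip_table, value="p_um_s", group="condition")
# -> Mann-Whitney U (asymptotic) or Wilcoxon signed-rank if every
#    observation belongs to a complete matched pair
```

The same pipeline is scriptable from a shell: `vesselperm simulate`,
`segment`, `estimate`, `aggregate`, `compare`, `mfi`, `rq`,
`region-mean` (see `vesselperm --help`).

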