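# hypoxmap

Dual-modality widefield imaging analysis of the mouse cortex under acute
hypoxia: cortical **hemodynamics** (∆HbO, ∆HbR, ∆HbT, sO2 from intrinsic
optical imaging) and **calcium-based resting-state connectivity** (GCaMP
∆F/F seed correlations), analysed within the same acquisition, together
with a forward simulator that makes every pipeline stage verifiable against
known ground truth without animal data.

## Who this is for

Labs doing mesoscale widefield imaging with time-interlaced multicolor
illumination (blue fluorescence excitation plus green/amber/red
reflectance) who want a tested, reproducible implementation of the standard
analysis chain — channel demultiplexing, co-registration, hemodynamic
correction, modified Beer-Lambert spectroscopy, ∆F/F normalisation,
seed-based connectivity and the associated nonparametric statistics — and a
way to validate it end to end on synthetic acquisitions with recoverable
parameters.

## The model

**Spectroscopy.** Reflectance changes at wavelength λ report hemoglobin
concentration changes through the modified Beer-Lambert law,

```
−log(R_λ(t) / R_λ(0)) = D_λ · (ε_HbO(λ)·∆HbO + ε_HbR(λ)·∆HbR)
```

with molar extinction coefficients ε (cm⁻¹·M⁻¹) and differential
pathlength factors D_λ (cm). The 3-channel (535/590/620 nm), 2-species
system is solved per pixel by least squares. With baseline concentrations
HbO₀ = 60 µM and HbR₀ = 40 µM, oxygen saturation is
sO2 = (HbO₀+∆HbO)/(HbT₀+∆HbT), exactly 60 % at baseline.

**Fluorescence.** Blood absorbs both the excitation and emission light, so
the calcium signal is contaminated by hemodynamics. Because the three
reflectance channels are driven by the same two hemoglobin species, a
per-pixel linear regression of the fluorescence trace on the reflectance
traces removes the contamination without assuming pathlengths or baselines.
∆F/F is then the 0.3–3 Hz band-pass of the corrected trace divided by its
< 0.3 Hz baseline (zero-phase Butterworth filters).

**Connectivity.** Eight seeds (left/right Motor, Somatosensory,
Retrosplenial, Visual; 3-pixel-radius disks at region centroids) are
correlated pairwise over matched analysis windows (hypoxia minutes
12.5–17.5 vs normoxia 2.5–7.5), Fisher z-transformed, and the per-subject
∆z is tested with an **exact** Wilcoxon signed-rank test (the n = 8
two-sided floor is 2/2⁸ = 0.0078125) under Benjamini–Hochberg FDR;
within- vs between-macrocluster (anterior = Mot+Sen, posterior = Ret+Vis)
mean changes are compared with paired t-tests.

## Worked example

A desk-scale run (48×48 px, 6-minute acquisition with a 1:1:2
normoxia/hypoxia/normoxia timeline emulating an 8 % O2 challenge):

```python
import hypoxmap as hm
import pandas as pd

scenario = hm.ScenarioConfig(image_shape=(48, 48), duration_s=360.0, rng_seed=7)
config = hm.RunConfig(
    output_dir="demo_run",
    scenario=scenario,
    hypoxia_window_min=(2.0, 2.9),   # scaled to the 6-minute demo
    normoxia_window_min=(0.3, 1.2),
    edge_margin_px=2,
    rng_seed=7,
)
manifest = hm.run_pipeline(config)

traces = pd.read_csv("demo_run/whole_brain_traces.csv")
pairs = pd.read_csv("demo_run/seed_pairs.csv")
```

which prints (via the snippet in `scripts/` or your own summary):

```
whole-brain dHbR: baseline +0.00 uM -> hypoxia +19.38 uM
whole-brain sO2:  baseline 60.0% -> hypoxia 52.7%

gcamp seed-pair correlations
window   hypoxia  normoxia
between    0.126     0.487
within     0.809     0.801
```

Reading this: during the hypoxia epoch deoxyhemoglobin rises to a ~20 µM
plateau and oxygen saturation drops from its 60 % baseline toward the low
50s; the calcium connectivity between anterior and posterior macroclusters
collapses (0.49 → 0.13, the generator's configured 0.5 → 0.1 drop) while
within-cluster connectivity is preserved (~0.8). `hm.make_figures(manifest)`
renders the trace, matrix-heatmap and seed-map figures.

The same pipeline runs on real fixtures (`multi-page TIFF + YAML sidecar +
atlas`) via `RunConfig(input_path=...)`, or from the shell:

```
hypoxmap simulate --out fixture_dir --seed 1 --oxygen 8 --shape 96
hypoxmap run --config run.yaml
hypoxmap figures --manifest demo_run/manifest.json
```

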