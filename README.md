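# infarct3d

Multiscale 3D morphometry of **bile infarcts** — the fields of necrotic
hepatocytes that form under obstructive cholestasis — as seen by
propagation-based X-ray phase-contrast CT of mouse liver.

Obstructive biliary disease (modelled by bile-duct ligation, BDL) floods
the liver with bile; infarcts appear around the portal tracts within a
day, grow and fuse over the following week, migrate toward the central
veins, and develop ~3 µm **infarct–sinusoidal microchannels** thought to
leak bile acids directly into the blood. Quantifying that evolution in 3D
needs a chain of tools that this package provides as a library with a thin
CLI, for image-analysis researchers and methods developers who want each
piece testable and reusable:

- **`infarct3d.phantom`** — seeded synthetic liver volumes at the two
  experimental scales (3.25 µm "lobe", 0.65 µm "submicron") with vessel
  trees, zone-weighted lesions, fused clusters, microchannels and full
  ground truth;
- **`infarct3d.recon`** — a miniature parallel-beam phase-contrast CT
  simulator (Fresnel propagation of the complex transmission of a
  δ/β phantom), flat/dark correction, single-distance phase–attenuation
  duality retrieval (spectral filter `1/(1 + πλD(δ/β)|f|²)` then −log) and
  filtered back-projection;
- **`infarct3d.segmentation`** — guarded-Otsu dark-lesion thresholding,
  deterministic seeded region growing for vessels, connected components
  with physical size filtering;
- **`infarct3d.zonation`** — the 3D hepatic-acinus model: the parenchyma
  is split into three *equal-volume* zones by distance to the central-vein
  tree (zone III pericentral, zone I periportal), lesions labelled by
  largest-share overlap;
- **`infarct3d.morphometry`** — per-lesion volume V, anti-aliased surface
  area A, sphericity **Ψ = π¹ᐟ³(6V)²ᐟ³/A**, watershed-based
  individual/confluent classification, microchannel detection and calibre
  estimation;
- **`infarct3d.stats_report`** — the Shapiro–Wilk-gated two-branch
  comparison (Welch t / Mann–Whitney U) and figure-style summary tables.

## Worked example

Generate a day-7 lobe-scale phantom, segment it, zonate it and measure it
(also available as `examples/04_full_analysis.py`):

```python
import numpy as np
from infarct3d import (lobe_preset, generate_phantom, SegmentationConfig,
                       segment_infarcts_threshold, label_components,
                       measure_infarcts, summarize_lobe)

params = lobe_preset("7", grid=128, seed=1)        # day-7 preset, 3.25 µm voxels
truth, zones, volume = generate_phantom(params)

cfg = SegmentationConfig()                          # auto threshold, 26-conn
mask = segment_infarcts_threshold(volume, cfg, vessel_mask=truth.vessel_mask)
labeled, table = label_components(mask, params.voxel_size_um, cfg)
records = measure_infarcts(labeled, params.voxel_size_um, zones)
lobe_um3 = (truth.parenchyma_mask.sum() + truth.infarct_mask.sum()) * 3.25 ** 3
s = summarize_lobe(records, lobe_um3, zones)

print(f"{s.n_infarcts} infarcts, total {s.total_volume_um3:.3g} µm³ "
      f"({100 * s.volume_ratio:.2f} % of the lobe)")
print(f"confluent fraction {100 * s.confluent_fraction:.1f} %")
print("zone count fractions:",
      {z: round(s.per_zone[z]['count_fraction'], 2) for z in (1, 2, 3)})
print("median sphericity:",
      round(float(np.median([r.psi for r in records if not r.border])), 3))
```

prints

```
40 infarcts, total 1.35e+06 µm³ (2.01 % of the lobe)
confluent fraction 22.5 %
zone count fractions: {1: 0.23, 2: 0.4, 3: 0.38}
median sphericity: 0.79
```

— forty lesions were planted by the preset and all forty are recovered;
the classifier calls 22.5 % of them confluent (this seed drew 30 % as
fused clusters; the day-7 preset expectation is 25 %); more than three
quarters of the lesions sit in zones II–III (pooled over seeds, zone III
holds the largest share — the day-7 signature of pericentral migration);
and the median sphericity is well below 1, reflecting the rough day-7
lesion surfaces.

The same pipeline runs from the shell:

```bash
infarct3d run --preset 7 --scale lobe --grid 128 --seed 1 --out run7
infarct3d simulate --preset 1 --scale submicron --grid 160 --seed 2 --out ph1
```

See `examples/` for one short script per capability (phantom generation,
CT round trip, zonation geometry, full lobe analysis, microchannel
detection, group statistics).

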