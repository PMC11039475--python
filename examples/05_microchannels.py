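"""Detect infarct–sinusoidal microchannels on a submicron phantom.

At 0.65 µm voxels the generator tunnels ~3.4 µm channels from each lesion
to the nearest hepatic sinusoid (Poisson counts, day-7 mean 5.47).  The
detector restricts the dark lumen mask to a shell around each lesion and
counts the connected lumen pieces bridging lesion and sinusoid.
"""

import numpy as np

from infarct3d import detect_microchannels, generate_phantom, submicron_preset

params = submicron_preset("7", grid=128, seed=5, n_infarcts=8)
truth, zones, volume = generate_phantom(params)

g = params.gray_levels
lumen = np.asarray(volume.data) < (g["channel"] + g["infarct"]) / 2.0
det = detect_microchannels(
    truth.infarct_components(), truth.sinusoid_mask, lumen,
    truth.voxel_size_um, exclude_mask=truth.portal_mask | truth.central_mask)

ct = truth.component_table().set_index("cluster_id")
print("lesion  planted  detected  mean calibre (µm)")
for _, row in det.iterrows():
    cid = int(row.infarct_id)
    print(f"{cid:6d}  {int(ct.loc[cid, 'n_channels']):7d}"
          f"  {int(row.n_channels):8d}  {row.diam_mean_um:8.2f}")
print(f"pooled mean channels/lesion: detected {det.n_channels.mean():.2f}, "
      f"planted {ct.n_channels.mean():.2f} (generator diameter 3.41 µm; "
      "in-situ calibre of very short channels reads low by ~1 voxel)")
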