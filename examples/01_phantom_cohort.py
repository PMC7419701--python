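"""Generate a phantom atlas and a resting-state run, and censor motion spikes.

The atlas plants disjoint spherical parcels grouped into networks; voxels of a
network share one low-frequency latent signal. Frames carrying an injected
whole-brain intensity spike are caught by the 0.5 % frame-to-frame RMS
criterion.
"""

import numpy as np

import langmap

atlas = langmap.make_phantom_atlas(grid_shape=(24, 24, 24), n_networks=6,
                                   rois_per_network=4, seed=1)
print(f"atlas: {len(atlas.roi_ids)} parcels in {atlas.n_networks} networks on "
      f"{atlas.labels.shape} grid")
print(f"Broca-analog parcel center (voxels): {atlas.centers[atlas.broca_roi]}")
print(f"Wernicke-analog parcel center (voxels): {atlas.centers[atlas.wernicke_roi]}")

protocol = langmap.AcquisitionProtocol()  # TR 2.2 s, 160-frame rest runs
run = langmap.simulate_rest_run(atlas, protocol, snr=5.0,
                                spike_frames={40, 90}, seed=2)
censor = langmap.censor_frames(run)
print(f"run: {run.n_frames} frames, spikes injected at {sorted(run.motion_spike_frames)}")
print(f"censored frames: {sorted(censor.excluded_frames)}")
print("-> the spike frame and its successor are both excluded: each transition")
print("   into and out of the spike exceeds 0.5 % of the whole-brain mean.")

# within- vs between-network parcel correlation (the structure the classifier learns)
ts = langmap.extract_roi_timeseries(run.data, atlas, censor.keep)
ids = atlas.roi_ids
within, between = [], []
for i in range(len(ids)):
    for j in range(i + 1, len(ids)):
        r = np.corrcoef(ts[ids[i]], ts[ids[j]])[0, 1]
        same = atlas.network_of_roi[ids[i]] == atlas.network_of_roi[ids[j]]
        (within if same else between).append(r)
print(f"mean parcel correlation: within-network {np.mean(within):.3f}, "
      f"between-network {np.mean(between):.3f}")
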