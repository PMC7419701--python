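"""Fit the block-design GLM comparator on a phantom word-generation run.

Five 10-frame task blocks alternate with rest over 100 frames; the regressor
is the boxcar convolved with a gamma-variate hemodynamic kernel peaking near
5 s. The activation map is smoothed at 10 mm and masked — no clustering, no
thresholding.
"""

import numpy as np

import langmap
from langmap.design import five_block_design
from langmap.task_glm import build_design_matrix, fit_glm, postprocess_activation

atlas = langmap.make_phantom_atlas(seed=1)
protocol = langmap.AcquisitionProtocol(tr=2.2, n_frames_per_run=100, n_runs=1)
design = five_block_design(100, 10)
print(f"design: blocks at frames {design.block_onsets}, "
      f"{int(design.boxcar(100).sum())} task frames of 100")

run = langmap.simulate_task_run(atlas, protocol, design,
                                atlas.language_rois, amplitude=1.0,
                                snr=5.0, seed=4)
out, censor = langmap.preprocess_run(run, wm_mask=atlas.wm_mask,
                                     csf_mask=atlas.csf_mask)
amap = fit_glm(out, build_design_matrix(design, protocol), censor, design)
amap = postprocess_activation(amap, fwhm_mm=10.0, mask=atlas.brain_mask)

t_resp = amap.tstat[atlas.roi_mask(atlas.broca_roi)].mean()
t_bg = amap.tstat[(atlas.labels == 0) & atlas.brain_mask].mean()
print(f"mean t statistic: responsive Broca-analog parcel {t_resp:.2f}, "
      f"background {t_bg:.2f}")
print("-> the task response stands far above the null background even after")
print("   the identical rest/task preprocessing chain")

# exact amplitude recovery in the confound-free regime
clean = langmap.simulate_task_run(atlas, protocol, design, [atlas.broca_roi],
                                  amplitude=1.0, snr=np.inf,
                                  drift_amplitude=0.0, seed=0,
                                  include_spontaneous=False)
exact = fit_glm(clean, build_design_matrix(design, protocol))
err = np.abs(exact.beta[atlas.roi_mask(atlas.broca_roi)] - 1.0).max()
print(f"noise-free beta recovery error: {err:.2e} (least squares is exact)")
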