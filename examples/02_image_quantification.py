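"""Render a synthetic microscopy stack from the kinetic model, quantify it
back into a nuclear/cytoplasmic time course, and refit the kinetics."""

import numpy as np

from nucleoflux import (
    CellSimSpec,
    FrameGeometry,
    TransportParams,
    build_timecourse,
    fit_recovery,
    gen_frames,
)

truth = TransportParams.from_accumulation(K_e=1.87, k=4.94e-3, v=1.0)
spec = CellSimSpec(params=truth, activation_duration=0.0, noise_cv=0.0, seed=7)
geometry = FrameGeometry(shape=(96, 96), background=10.0, gain=200.0)

stack, masks, ground_truth = gen_frames(spec, geometry)
print(f"stack: {stack.frames.shape[0]} frames of {stack.frames.shape[1:]} px")

# background region = everything outside the cell mask
tc = build_timecourse(stack, masks, background_region=~masks.cell)
res = fit_recovery(tc, v_policy="free")
print(f"fitted K_e = {res.params.K_e:.3f} (mask-sum truth "
      f"{ground_truth['ratio'][-1]:.3f}), k = {res.params.k*1e3:.2f} ks^-1")

rec = tc.phase == "recovery"
keep = rec & (ground_truth["ratio"] > 0.1)
rel = (tc.ratio[keep] - ground_truth["ratio"][keep]) / ground_truth["ratio"][keep]
print(f"quantification error vs noiseless truth: {np.sqrt(np.mean(rel**2))*100:.2f}% RMS")
print("the fitted K_e is the plateau of the summed-intensity N/C ratio; the")
print("volume factor v absorbs the nucleus/cytoplasm area difference")
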