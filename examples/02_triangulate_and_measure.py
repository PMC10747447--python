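"""Triangulate 2D keypoints to 3D and extract the joint-angle trace.

Runs the markerless half of the pipeline on a noiseless session so the
recovered trace can be compared against the generator's ground truth.
"""
import numpy as np

from mvkin import SimulationConfig, simulate_paired_session, triangulate_series
from mvkin.kinematics import angle_trace_from_skeleton

config = SimulationConfig(seed=0, repetitions=1, pixel_sigma_px=0.0,
                          reference_noise_sigma_deg=0.0)
(bundle,) = simulate_paired_session(config)

skel = triangulate_series(bundle.rig, bundle.views)
print(f"reconstructed {skel.n_frames} frames x {len(skel.keypoints)} keypoints")
print(f"max reprojection residual: {np.nanmax(skel.residual_px):.2e} px")

trace = angle_trace_from_skeleton(skel, bundle.task)
err = np.nanmax(np.abs(trace.values - bundle.truth_camera.values))
print(f"recovered side-bend peak: {np.nanmax(trace.values):.3f} deg")
print(f"max |recovered - truth|:  {err:.2e} deg")
# With zero pixel noise the linear triangulation is exact to numerical
# precision, so the angle trace reproduces the ground truth to ~1e-12 deg.
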