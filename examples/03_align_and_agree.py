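"""Time-normalize a trace pair and compute the agreement battery.

The 12 Hz markerless trace and the 100 Hz reference trace are cut to the
max-min section of the reference, resampled to 100 frames, and compared
with ICC(2,1) + 95% CI, method-error CV, SEM, and MDC95.
"""
from mvkin import SimulationConfig, simulate_paired_session
from mvkin.pipeline import process_bundle
from mvkin.reliability import reliability_report

config = SimulationConfig(seed=42, repetitions=1)
(bundle,) = simulate_paired_session(config)
outcome = process_bundle(bundle)

pair = outcome.pair
print(f"aligned frames: {pair.n_frames} per system (normalized movement time)")

(row,) = reliability_report([pair])
print(f"M = {row.m:.2f} deg, SD = {row.sd:.2f} deg (pooled over both systems)")
print(f"ICC(2,1) = {row.icc:.3f}  95% CI [{row.ci_low:.3f}, {row.ci_high:.3f}]  ({row.band})")
print(f"CV = {row.cv_pct:.2f} %   SEM = {row.sem_deg:.2f} deg   MDC95 = {row.mdc95_deg:.2f} deg")
# ICC near 1 with a tight CI means the markerless system tracks the
# reference almost frame-for-frame; SEM/MDC95 translate the residual
# disagreement into degrees a clinician can interpret.
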