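"""Simulate a dual-site piezo recording and convert voltage back to force.

Builds a synthetic subject, generates 10 s of two-channel piezo voltage
(the distal sensor lags the proximal by spacing / PWV), converts channel
1 back to the blood-propagation force waveform by integration, and
checks the reconstruction against the generator's ground truth.
"""

import numpy as np

from piezobp import (
    CohortSpec,
    NoiseSpec,
    VoltageSeries,
    piezo_to_force,
    sample_cohort,
    synth_dual_piezo,
)

subject = sample_cohort(CohortSpec(), n=1, seed=7)[0]
print(f"subject: {subject.sex}, age {subject.age:.0f}, "
      f"true BP {subject.sbp:.1f}/{subject.dbp:.1f} mmHg, PWV {subject.pwv:.1f} m/s")

for label, noise in (("noise-free", NoiseSpec()), ("1% white noise", NoiseSpec(white_sd=0.01))):
    rec = synth_dual_piezo(subject, noise=noise, duration=10.0)
    force = piezo_to_force(VoltageSeries(rec.ch1, rec.fs)).values
    truth = rec.truth["force_ch1"]
    err = (force - force.mean()) - (truth - truth.mean())
    rel_rmse = np.sqrt(np.mean(err**2)) / np.std(truth)
    print(f"{label:>14}: voltage->force reconstruction relative RMSE {rel_rmse:.2e}")

print(f"recording: {rec.ch1.size} samples/channel at {rec.fs:.0f} Hz, "
      f"spacing {rec.spacing_m * 1000:.0f} mm")
print(f"ground-truth transit time: {rec.truth['delta_t'] * 1e3:.3f} ms "
      "(= spacing / PWV)")
print("(the noise-free round trip sits at the quadrature floor, ~1e-4; with "
      "noise the residual simply reflects the injected noise level, which the "
      "downstream band-pass removes)")
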