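"""Exact versus differentiable dose-volume histograms.

The exact DVH counts the fraction of a structure's voxels receiving at
least each threshold dose — a step function of the dose, with zero gradient
almost everywhere. The sigmoid relaxation replaces the hard count with a
logistic ramp of steepness m, which makes the curve differentiable in the
dose and therefore usable as a training objective. As m grows the relaxed
curve converges to the exact one.
"""

import numpy as np

from hdaunet.dvh import DVHSpec, approx_dvh, exact_dvh
from hdaunet.phantom import PhantomSpec, generate_cohort

case = generate_cohort(PhantomSpec(seed=3), 1)[0]
ptv = case.structures["PTV"]
dose = case.reference_dose

print("PTV DVH at selected thresholds (volume fraction receiving >= d):")
print(f"{'d (Gy)':>8}{'exact':>9}{'m=1':>9}{'m=10':>9}{'m=1000':>9}")
sel = [0.0, 40.0, 60.0, 65.0, 68.0, 70.0, 72.0]
spec = DVHSpec(thresholds=np.array(sel))
curves = {
    "exact": exact_dvh(dose, ptv, spec),
    "m=1": approx_dvh(dose, ptv, DVHSpec(thresholds=np.array(sel), steepness=1.0)),
    "m=10": approx_dvh(dose, ptv, DVHSpec(thresholds=np.array(sel), steepness=10.0)),
    "m=1000": approx_dvh(dose, ptv, DVHSpec(thresholds=np.array(sel), steepness=1000.0)),
}
for i, d in enumerate(sel):
    print(f"{d:8.0f}" + "".join(f"{curves[k][i]:9.3f}" for k in curves))

full = DVHSpec()
gap = np.abs(
    approx_dvh(dose, ptv, DVHSpec(steepness=1000.0)) - exact_dvh(dose, ptv, full)
).max()
print(f"\nmax |relaxed - exact| over the full 0-80 Gy grid at m=1000: {gap:.2e}")
print("Near the prescription (70 Gy) the curve drops steeply: nearly the whole")
print("PTV receives ~95-100% of the prescription, almost nothing receives more.")
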