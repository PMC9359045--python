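"""Compare training objectives with the statistical machinery of the suite.

Trains the same tiny architecture twice — once with plain MSE and once with
the combined MSE + DVH objective — on one phantom cohort and compares the
held-out plan metrics with a two-tailed Student's t-test, the same
comparison used to decide whether one planning method significantly
outperforms another.
"""

import numpy as np

from hdaunet.dvh import DVHSpec, exact_dvh
from hdaunet.metrics import compare_methods
from hdaunet.models import ArchConfig
from hdaunet.phantom import PhantomSpec, generate_cohort
from hdaunet.train import SplitSpec, TrainConfig, predict, split_cohort, train

spec = PhantomSpec(grid_shape=(16, 16, 16), seed=100, n_oars=3,
                   ptv_radius_range=(4.0, 6.0), oar_radius_range=(2.0, 3.0),
                   oar_sparing=0.5)
cohort = generate_cohort(spec, 20)
by_id = {c.case_id: c for c in cohort}
split = SplitSpec(seed=0)
_, _, test_ids = split_cohort(list(by_id), split)
arch = ArchConfig("hda", in_channels=1 + 6, levels=3, growth_rate=4, ag_features=8)


def curve_errors(run):
    errs = []
    for cid in test_ids:
        case = by_id[cid]
        pred = predict(run, case)
        errs.append(np.mean([
            np.abs(exact_dvh(case.reference_dose, case.structures[n], DVHSpec())
                   - exact_dvh(pred, case.structures[n], DVHSpec())).mean()
            for n in case.structures.nonempty()
        ]))
    return np.array(errs)


scores = {}
for loss in ("mse", "mse_dvh"):
    cfg = TrainConfig(arch=arch, epochs=12, seed=0, loss=loss)
    scores[loss] = curve_errors(train(cohort, cfg, split))
    print(f"{loss:>8}: per-case DVH-curve errors {np.round(scores[loss], 3)} "
          f"(mean {scores[loss].mean():.3f})")

p = compare_methods(scores["mse"], scores["mse_dvh"])
print(f"\ntwo-tailed t-test p-value: {p:.3f}")
print("A small p-value would indicate the two objectives differ significantly on")
print("this cohort; at desk scale the direction (lower error with the DVH term)")
print("matters more than significance, which needs larger test sets.")
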