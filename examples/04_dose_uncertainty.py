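"""Full pipeline: per-organ dose-mapping uncertainty on one case.

Runs phantom -> rigid -> ensemble -> gate -> dose mapping -> statistics,
then prints the three uncertainty products for each organ at risk: the
DVH-metric mean +- SD, a few DVH-curve points, and the voxel-wise SD
range.  Serial organs are summarised by D0.1cm3 (hot-spot surrogate),
parallel organs by mean dose.
"""

import numpy as np

from redose_uq import CaseInputs, PhantomSpec, RunConfig, generate_phantom, run_case

case = generate_phantom(
    PhantomSpec(seed=23, size=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                scenario="smooth_deformation", amplitude_mm=5.0)
)
result = run_case(CaseInputs.from_phantom(case), RunConfig(grid="six"))

for rep in result.reports:
    print(f"\n{rep.oar_name} ({rep.organ_class}): "
          f"{rep.n_plausible}/{rep.n_configs} registrations plausible")
    if not rep.mappable:
        print("  not mappable:", rep.flags)
        continue
    m = rep.metric
    sd = "undefined" if m.sd_gy is None else f"{m.sd_gy:.3f} Gy"
    print(f"  {m.metric_kind}: {m.mean_gy:.2f} Gy +- {sd} over the plausible ensemble")
    curve = rep.dvh_ensemble[0]
    for dose in (5.0, 20.0, 40.0):
        print(f"  V({dose:.0f} Gy) = {100 * curve.volume_at_dose(dose):.1f}% "
              f"({curve.config_label})")
    sd_vals = rep.voxel_sd.sd.values[rep.voxel_sd.defined]
    print(f"  voxel-wise dose SD inside organ: {sd_vals.min():.3f}..{sd_vals.max():.3f} Gy")
    print(f"  out-of-field-of-view voxel fraction: {rep.invalid_voxel_fraction:.3f}")

print("\nThe SD numbers are registration-choice uncertainty: how much the"
      "\nmapped dose depends on which plausible registration produced it.")
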