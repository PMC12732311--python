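"""Run the six-configuration registration ensemble on one phantom.

Registers the prior scan to the reirradiation scan with all six members
of the first protocol grid (CC/MI x 1/3/5 resolution levels) and compares
each estimated field against the analytic truth.  The spread of endpoint
errors across members is exactly the registration variability the
uncertainty products downstream quantify.
"""

import numpy as np

from redose_uq import (
    PhantomSpec,
    RunConfig,
    generate_phantom,
    rigid_register,
    run_ensemble,
)

case = generate_phantom(
    PhantomSpec(seed=3, size=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                scenario="smooth_deformation", amplitude_mm=6.0)
)
rigid = rigid_register(case.reirradiation_volume, case.prior_volume)
print(f"rigid stage: rotation {np.round(np.rad2deg(rigid.rotation), 3)} deg, "
      f"translation {np.round(rigid.translation, 3)} mm (true: identity)")

results = run_ensemble(
    case.reirradiation_volume, case.prior_volume, RunConfig(grid="six").configs(),
    rigid=rigid,
)

pre = case.true_field.magnitude().mean()
print(f"\nzero-field baseline: {pre:.3f} mm mean displacement")
print(f"{'config':8s} {'mean|u| mm':>11s} {'EPE mm':>8s} {'improved':>9s}")
for res in results:
    epe = np.linalg.norm(
        res.field.displacement - case.true_field.displacement, axis=-1
    ).mean()
    print(f"{res.config.label:8s} {res.field.magnitude().mean():11.3f} "
          f"{epe:8.3f} {str(epe < pre):>9s}")
print("\nEPE = mean endpoint error vs the analytic true field; every member"
      "\nshould land below the zero-field baseline.")
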