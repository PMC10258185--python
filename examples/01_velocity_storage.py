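"""Velocity storage: yaw-velocity perception during constant-rate rotation.

Builds a 30 deg/s earth-vertical yaw rotation (EVAR) and runs the three
spatial-orientation models.  The semicircular canals alone would decay with
their 5.7 s time constant; central feedback stretches the perceptual decay.
"""

import numpy as np

from vsom import (
    MSOMParams,
    PFMParams,
    SVMParams,
    fit_time_constant,
    make_paradigm,
    msom_simulate,
    pfm_simulate,
    svm_simulate,
)

stim = make_paradigm("EVAR", rate=30.0, duration=150.0)

percepts = {
    "SVM": svm_simulate(stim, SVMParams.preset("perception"))[0],
    "MSOM": msom_simulate(stim, MSOMParams.preset("perception"))[0],
    "PFM": pfm_simulate(stim, PFMParams.preset("perception"), seed=0)[0],
}

print("EVAR at 30 deg/s, perception-tuned models")
for name, percept in percepts.items():
    yaw = np.degrees(percept.yaw_velocity_percept())
    fit = fit_time_constant(stim.t, yaw, form="decay", window=(3.0, 140.0))
    print(
        f"  {name:4s}: peak percept {yaw.max():5.1f} deg/s, "
        f"decay time constant {1 / fit.b:5.1f} s"
    )

print(
    "\nThe SVM and MSOM hit the experimentally observed 18.7 s exactly\n"
    "(tau_ssc * (1 + K_w) = 5.7 * 3.28); the particle filter's constant is\n"
    "an emergent property of its priors and decays more slowly, with a\n"
    "sub-unity gain caused by the canal noise it needs to function."
)
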