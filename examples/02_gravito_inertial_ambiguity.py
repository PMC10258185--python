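"""How each model resolves the gravito-inertial ambiguity.

Sweeps small sinusoidal lateral accelerations and measures how much of the
input leaks into the gravity estimate (the somatogravic effect): a sustained
push is indistinguishable from a tilt, but a fast oscillation is not.  The
break frequency of this low-pass leak differs between models.
"""

import numpy as np

from vsom import MSOMParams, SVMParams, freq_response, msom_lateral_tf, svm_conflict_tf

freqs = np.logspace(np.log10(0.01), np.log10(2.0), 30)

for model in ("svm", "msom"):
    resp = freq_response(
        model, "perception", input_axis="y", output_quantity="g_hat",
        freqs=freqs, amplitude=0.1,
    )
    print(f"{model.upper():4s}: gravity-estimate break frequency "
          f"{resp.break_frequency():.3f} Hz")

print("\nClosed-form cross-checks:")
p = SVMParams.preset("perception")
print(f"  SVM resonance sqrt(K_gc/tau_lp)/2pi = "
      f"{np.sqrt(p.K_gc_xy / p.tau_lp_xy) / (2 * np.pi):.3f} Hz")
m = MSOMParams.preset("perception")
print(f"  MSOM corner K_f/((1-K_a) 2pi)       = "
      f"{m.K_f / ((1 - m.K_a) * 2 * np.pi):.3f} Hz")

print(
    "\nBelow its break frequency a sustained lateral acceleration tilts the\n"
    "model's subjective vertical (perceived as tilt, not translation).  The\n"
    "SVM breaks at ~0.2 Hz, the observer model at ~0.6 Hz -- a structural\n"
    "difference that propagates into their sickness predictions."
)
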