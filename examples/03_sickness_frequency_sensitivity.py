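"""Frequency sensitivity of predicted motion sickness to vertical motion.

Drives the SVM with vertical sinusoids of fixed peak acceleration and
averages the weighted conflict magnitude per frequency.  Humans are most
easily made sick by vertical oscillation near 0.16-0.2 Hz; the gravity
conflict of the SVM reproduces that band-pass shape.
"""

from vsom import sickness_sensitivity

for preset in ("perception", "sickness"):
    resp = sickness_sensitivity("svm", preset, axis="vertical")
    print(f"SVM ({preset:10s}): peak sensitivity at "
          f"{resp.peak_frequency():.3f} Hz")

resp_msom = sickness_sensitivity("msom", "perception", axis="vertical")
flatness = resp_msom.gain.max() / resp_msom.gain.min()
print(f"MSOM: max/min sensitivity ratio across the grid = {flatness:.3f}")

print(
    "\nThe SVM's conflict peaks near the empirically sickening band because\n"
    "its gravity-estimate magnitude may vary; the observer model fixes\n"
    "|g_hat| = 9.81, so its vertical conflict gain 1/(1-K_a) is flat in\n"
    "frequency and cannot reproduce the band-pass sensitivity."
)
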