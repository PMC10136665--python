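"""Tonic/phasic decomposition of a synthetic skin-conductance record.

Synthesizes 3 minutes of conductance: a constant tonic level, three
stimulus-locked responses (Bateman kernel), drift, and sensor noise; then
low-pass filters at 5 Hz and runs the continuous decomposition. The
recovered tonic level and the driver peak times should match the ground
truth printed alongside.
"""

import numpy as np

from odorans import decompose_cda, lowpass_gsr, synthesize_gsr

TONIC = 1.8          # uS
EVENTS = [(40.0, 0.30), (90.0, 0.15), (140.0, 0.25)]  # (onset s, amplitude uS)

rec = synthesize_gsr(TONIC, drift_sd=0.03, events=EVENTS, fs=51.2,
                     noise_sd=0.01, seed=5, duration=180)
dec = decompose_cda(lowpass_gsr(rec))

true_phasic = rec.meta["phasic"]
print(f"converged in {dec.iterations} alternations, "
      f"residual RMS {dec.residual_rms:.4f} uS")
print(f"tonic mean  : recovered {dec.tonic.mean():.3f} uS, true {TONIC:.3f} uS")
print(f"phasic corr : {np.corrcoef(true_phasic, dec.phasic_model)[0, 1]:.3f} "
      "(recovered vs true fast component)")

t = dec.times
for onset, amp in EVENTS:
    m = (t >= onset) & (t <= onset + 5.0)
    peak_t = t[m][np.argmax(dec.driver[m])]
    print(f"event at {onset:5.1f} s (amp {amp:.2f} uS): "
          f"driver peak at {peak_t:6.1f} s")
print()
print("The driver is the nonnegative neural activation rate whose")
print("convolution with the sudomotor impulse response reproduces the")
print("phasic trace; its peaks localise each stimulus response.")
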