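"""Generate a pressed-sensor recording and estimate heart rate per window.

A 30 s inductive stream (20 Hz, 72 bpm, 4 s breath period, coil pressed
to the chest) is synthesized, then the five-step chain runs on 15 s
windows hopping by 5 s: offset removal, 1 Hz low-pass respiration
extraction, delay alignment, difference, autocorrelation period pick.
"""

from inducardio import estimate_heart_rate
from inducardio.synth import InductiveScenario, gen_inductive

scenario = InductiveScenario(hr_bpm=72.0, resp_period_s=4.0, pressed=True, seed=11)
stream = gen_inductive(scenario)
print(f"simulated {len(stream)} samples at {stream.fs:g} Hz (true rate {scenario.hr_bpm:g} bpm)")

for est in estimate_heart_rate(stream, window_s=15.0, hop_s=5.0):
    t0, t1 = est.window
    if est.valid:
        print(f"  window {t0:5.1f}-{t1:5.1f} s: T = {est.period_samples:2d} samples "
              f"-> {est.bpm:6.1f} bpm")
    else:
        print(f"  window {t0:5.1f}-{t1:5.1f} s: invalid ({est.method_note})")

# Each window reports the cardiac period T found in the autocorrelation of
# the respiration-free difference signal; bpm = 60/T * fs.  At fs = 20 Hz a
# true 72 bpm lands on T = 17 -> 70.6 bpm, inside the +/-10 bpm admitted error.
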