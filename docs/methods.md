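# Methods

## Sensing model

The sensing element is a planar spiral coil in the fabric over the cardiac
apex, the chest region where the heart's mechanical activity is most
visible. Its inductance follows the current-sheet approximation
`L = K1·μ0·N²·D_avg / (1 + K2·φ)` with layout coefficients (square
2.34/2.75, hexagonal 2.33/3.82, octagonal and circular 2.25/3.55 —
overridable per coil). All computation is in SI units; the formula is often
quoted with nH/mm unit conventions, which we deliberately avoid in favour
of dimensional correctness, providing unit-converting helpers instead.

Chest tissue is predominantly water and therefore weakly diamagnetic:
displacement toward the coil *lowers* L. We model the transduction to first
order, `L(t) = L0 − k·x(t)`, with defaults `L0 = 3.3 µH` and
`k = 10 nH/mm`; no functional form for the true displacement–inductance
relation is available, and over sub-millimetre cardiac and few-millimetre
respiratory excursions a linear expansion is adequate. The converter
digitizes a ±100 nH full scale around `L0` into 16 bits (round-half-even),
making one LSB ≈ 0.3 µm of equivalent displacement — negligible against
both components. The converter's native words are 28-bit; only the top 16
bits are kept, which the quantizer reflects.

## Processing chain

Per analysis window (default 15 s, hop 5 s, at fs = 20 Hz):

1. offset removal (mean subtraction);
2. respiration extraction with a 7th-order Butterworth low-pass, 1 Hz
   cutoff, run causally as its ARMA difference equation (direct-form
   transposed II);
3. delay estimation between raw and filtered signal by cross-correlation
   (lag of the maximum) and AMDF (lag of the minimum), each candidate
   scored by the mean absolute residual of the aligned subtraction, smaller
   residual wins, ties to the correlation lag; the aligned difference
   `d[n] = s[n] − s*[n+offset]` is the cardiac estimate;
4. raw autocorrelation of `d`, restricted to lags `[Tmin, Tmax]` =
   `[round(60/bpm_max·fs), round(60/bpm_min·fs)]` (6–30 samples for
   40–200 bpm at 20 Hz); the period is the highest local maximum
   (`C[k] > C[k−1]` and `C[k] ≥ C[k+1]`), equal peaks resolving to the
   smaller lag (higher rate), windows without an in-band peak flagged
   invalid rather than raising so a recording always yields a report;
5. `bpm = 60/T·fs`.

Two numerical choices matter and are deliberate deviations from the naive
reading of the chain:

- **Filter state initialization.** Inside the windowed pipeline the filter
  starts from the steady state matching the window's first sample
  (`scipy.signal.lfilter_zi`), not from zero. A zero state turns the
  window's initial respiration displacement into a step response roughly
  16× the cardiac amplitude that corrupts the whole window's
  autocorrelation. The public `apply_filter` defaults to zero initial
  conditions (the plain difference equation, which the brute-force oracle
  test checks exactly) and exposes `initial="steady"`.
- **Absolute values in AMDF and residual scoring.** AMDF is by definition
  a sum of absolute differences, and the alignment-selection residuals are
  mean *absolute* residuals — signed sums can cancel to zero for both
  candidates and make the selection meaningless.

The difference `d` retains a small respiration residual: the filter's group
delay at a 0.25 Hz breath fundamental is 14.53 samples, and alignment is
restricted to integer lags (sub-sample delay estimation is out of scope),
so up to half a sample of fractional misalignment survives — about 4% of
the respiration amplitude. The local-maximum peak rule makes the period
pick robust to this residual because its autocorrelation varies smoothly
(period ≈ 80 samples, far above Tmax = 30); the residual slightly tilts the
lag band toward smaller lags, which in practice favours the fundamental
over multi-beat subharmonics.

Respiration rate uses the same autocorrelation machinery on the low-pass
output with a 6–30 breaths/min band, plus two guards: the in-band peak must
carry ≥ 10% of the signal energy (otherwise "breath hold", no rate), and at
least half of the spectral energy must lie inside the band (otherwise the
content is residual cardiac leakage and the window is flagged out-of-band).

## Synthetic data

The generator emulates the acquisition scenarios the processing chain is
designed for; defaults are the study conditions and are not tuned per run:

- **Respiration**: quasi-periodic chest displacement, default 2 mm
  amplitude, 3–5 s period (default 4 s) with ±3% per-cycle period jitter.
  The cycle shape is a phase-warped ("skewed") cosine, inhalation faster
  than exhalation — quiet-breathing chest motion is smooth and
  near-sinusoidal, and the waveform's harmonics decay fast, which matters
  because harmonics above the 1 Hz cutoff pass straight into the cardiac
  difference signal. Breath holds zero the waveform over an interval with
  ≤ 1 s cosine ramps outside it.
- **Cardiac**: one Gaussian bump per beat (apex impulse), default 0.25 mm
  peak and σ = 45 ms (≈ 0.27 s effective width, the duration of the
  systolic outward thrust); the width must stay below the beat period.
- **Noise**: additive uniform noise whose level encodes the wearing
  condition — cardiac/noise amplitude ratio 5 when the coil is pressed
  against the chest, 0.8 when worn loose ("unpressed"), matching the
  qualitative observation that heart periodicity is plainly visible only
  when pressed.
- **ECG**: a P–QRS–T train of Gaussian lobes at 200 Hz with known R-peak
  indices as ground truth, optional sub-0.5 Hz baseline wander and uniform
  noise; template offsets compress when the beat period drops below 0.8 s.

What the generator does **not** emulate: heart-rate variability and
arrhythmic morphologies, motion/muscle artifacts (the device targets repose
and sleep only), electrode-contact noise structure, and any amplitude
calibration of counts per µH per millimetre — the transduction constants
are documented free parameters. Passing tests therefore demonstrate the
algorithm's correctness and its noise behaviour under the modelled
conditions, not clinical performance on worn hardware.

## Validation chain

ECG conditioning mirrors the acquisition amplifier: 1 Hz high-pass (2nd
order), 35 Hz low-pass (4th order), Q = 30 notch at 50 Hz, all causal,
requiring fs ≥ 200 Hz. Baseline estimation cascades median filters at
200 ms and 600 ms scales (edge mode "nearest", so a constant input returns
itself). QRS detection is a derivative–squaring–150 ms moving-window
integration front end with Pan–Tompkins-style adaptive signal/noise
thresholds, a 200 ms refractory period (rejects tall T waves), and a
search-back with halved threshold when an RR gap exceeds 1.66× the running
median RR; R positions are refined to the signal maximum near each envelope
peak, and QRS duration is the span of |x| above 15% of the R amplitude
within ±100 ms. The specific thresholds are conventional defaults, not
device-measured values.

Agreement between chains is summarized by Bland–Altman statistics: bias
(mean paired difference), sample SD (n−1), and bias ± 1.96·SD limits of
agreement. Screening alerts use strict thresholds — tachycardia > 130 bpm,
bradycardia < 40 bpm, rhythm variation (max−min)/mean > 20% over a run of
complexes, ≤ 9 missed QRS per recording acceptable, median QRS duration
> 120 ms (even-length medians average the central pair). The ±10 bpm
admitted rate error is metadata in every report and deliberately does not
widen the alert thresholds, since the two tolerances have different roles.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded per
scenario, with independent substreams per component so, e.g., the noise
draw does not perturb the breath-cycle jitter. Test and acceptance runs use
30 s recordings (600 inductive samples, 6000 ECG samples), a 4 × 3 rate ×
breath-period recovery grid, and 20-seed Monte-Carlo batteries; the whole
suite completes in a few seconds.

## Known limitations

- Rate resolution is quantized to integer autocorrelation lags: at 20 Hz
  the representable rates near 70 bpm are ~4 bpm apart and ~29 bpm apart at
  the 200 bpm band edge; the ±10 bpm admitted error absorbs this except at
  the extreme top of the band.
- At rates below ~60 bpm the cardiac fundamental lies under the 1 Hz
  cutoff and is partially removed with the respiration; detection then
  relies on the harmonics that survive in `d`.
- Under the loose-wear noise level (cardiac/noise = 0.8), 12 s windows
  recover the rate in roughly 85% of cases and 3 s windows in ~36% —
  long windows are required for noisy recordings, and occasional windows
  remain wrong even at 12 s.
- The QRS stage assumes positive R deflections (lead I-like polarity) and
  performs no beat classification or P/T delineation beyond what detection
  needs.
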