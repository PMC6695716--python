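# inducardio

Cardiorespiratory signal processing for a **single wearable inductive chest
sensor**. A planar spiral coil woven into clothing over the cardiac apex sees
chest-wall motion as inductance change (tissue is mostly water, hence weakly
diamagnetic: approach lowers L). An inductance-to-digital converter samples
the coil at 20 Hz into 16-bit counts, and that *one* stream carries both
respiration and the mechanical heart beat. This package separates the two,
estimates both rates, and validates the heart rate against a reference
single-lead ECG.

It is written for researchers prototyping textile-based vital-sign monitors:
everything runs from Python (or a thin CLI), and a synthetic-data module
stands in for the hardware so the full chain is testable end to end.

## The method

For a raw stream `s` with sampling rate `fs = 20 Hz`, per analysis window:

1. **Offset removal** — `s_n = s_n − mean(s)`.
2. **Respiration extraction** — a 7th-order Butterworth low-pass with 1 Hz
   cutoff, applied causally through its ARMA difference equation, gives
   `s* ≈ s_B` (the breathing component). The recursive part delays `s*`.
3. **Delay alignment** — the lag is estimated twice, by cross-correlation
   `C_XY[k] = Σ s[n]·s*[n+k]` (argmax) and by the average magnitude
   difference function `D_XY[k] = Σ |s[n] − s*[n+k]|` (argmin); the candidate
   with the smaller mean absolute aligned residual wins. The aligned
   difference `d[n] = s[n] − s*[n+offset]` removes respiration and keeps the
   cardiac component `s_H`.
4. **Period estimation** — the highest local maximum of the autocorrelation
   `C_XX[k] = Σ d[n]·d[n+k]` within `T ∈ [Tmin, Tmax]`, where
   `Tmin = round(60/200·fs) = 6` and `Tmax = round(60/40·fs) = 30` samples
   bound the 40–200 bpm band.
5. **Rate** — `bpm = 60/T · fs`.

The same autocorrelation machinery over a 6–30 breaths/min band applied to
`s*` yields the respiration rate. A reference ECG chain (1 Hz HPF / 35 Hz
LPF / 50 Hz notch conditioning, two-scale median-filter baseline removal,
derivative-energy QRS detection with refractory and search-back rules)
provides RR-derived rates for validation via Bland–Altman statistics
(bias ± 1.96·SD limits of agreement), plus rule-based screening alerts
(tachycardia > 130 bpm, bradycardia < 40 bpm, > 20% rhythm variation,
≤ 9 missed QRS acceptable, median QRS duration > 120 ms).

## Worked example

```bash
python examples/01_simulate_and_estimate.py
```

```
simulated 600 samples at 20 Hz (true rate 72 bpm)
  window   0.0- 15.0 s: T = 17 samples ->   70.6 bpm
  window   5.0- 20.0 s: T = 17 samples ->   70.6 bpm
  window  10.0- 25.0 s: T = 17 samples ->   70.6 bpm
  window  15.0- 30.0 s: T = 17 samples ->   70.6 bpm
```

A 30 s pressed-sensor recording at a true 72 bpm is synthesized and the
five-step chain runs on 15 s windows. The cardiac period is found at
T = 17 samples in every window; 60/17·20 = 70.6 bpm, i.e. the true rate up
to the integer-lag quantization of the autocorrelation (the admitted
measurement error for this class of monitor is ±10 bpm). The other examples
cover respiration and breath-hold (`02`), the ECG/QRS reference chain
(`03`), Bland–Altman validation and alerts (`04` — bias −1.42 bpm on
matched synthetic chains, no alert fires), and the device's RestingECG XML
dialect with CRC-32 verification (`05`).

The same workflows are available from the shell:

```bash
inducardio simulate --hr 72 --seed 11 --out stream.txt
inducardio extract --input stream.txt --out report.csv
inducardio validate --inductive stream.txt --ecg ecg.csv --out val --plot
inducardio parse-xml src/inducardio/data/example_resting_ecg.xml
```

## Layout

- `src/inducardio/signals.py` — `Signal` container, offset removal,
  normalization, Butterworth design, ARMA filtering
- `src/inducardio/sensor.py` — spiral-coil inductance model and 16-bit
  quantization
- `src/inducardio/synth.py` — synthetic inductive streams and ECG
- `src/inducardio/separation.py` — cross-correlation/AMDF delay estimation
- `src/inducardio/rate.py` — autocorrelation period pick, windowed pipeline
- `src/inducardio/ecg.py` — ECG conditioning, baseline, QRS detection
- `src/inducardio/alerts.py` — screening alert rules
- `src/inducardio/agreement.py` — Bland–Altman statistics and plot
- `src/inducardio/io_formats.py` — text streams, RestingECG XML, CRC-32,
  filename convention
- `src/inducardio/cli.py` — `inducardio` command-line front end

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
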