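# icpulse

Automated monitoring of the **P2/P1 subpeak-amplitude ratio** on
intracranial-pressure (ICP) signals.

ICP is monitored invasively in intensive care after brain injury. Each
cardiac cycle imprints a pulse on the signal in which up to three subpeaks
— P1 (percussion), P2 (tidal) and P3 (dicrotic) — may be visible. The ratio
of the relative amplitudes of P2 and P1 tracks cerebral compliance: a
P2/P1 ratio above 1 is read as a sign of reduced pressure–volume reserve.
Because the subpeaks are often indistinct or buried in artifacts, computing
this ratio continuously from the raw signal alone requires an automated
pipeline. `icpulse` implements one, end to end:

1. **Pulse extraction** — zero-phase 4th-order Butterworth band-pass
   (0.3–20 Hz), multiscale trough detection (bounded-scale AMPD/Scholkmann
   variant, characteristic duration L = 500 ms), beat segmentation, and
   min–max normalization of every beat to a 180-point frame.
2. **Pulse selection** — a binary sequence classifier (1-D CNN,
   bidirectional LSTM, or LSTM-FCN) trained with binary cross-entropy keeps
   only pulses on which both P1 and P2 are visible ("calculable" pulses).
   The operating threshold is placed at the Youden point of the ROC curve
   (argmax TPR − FPR).
3. **Subpeak designation** — a network (bidirectional LSTM or 1-D U-Net)
   regresses, per pulse x with labeled positions p1, p2, the score vector
   y_x(t) = ½·(exp(−(t−p1)²/2σ²) + exp(−(t−p2)²/2σ²)) under an MSE loss.
   At inference the two subpeaks are taken either among the local maxima of
   the pulse curvature κ(x) = x″/(1+x′²)^{3/2} (candidates scored by the
   network) or directly at the two best network maxima; the P2/P1 ratio is
   the quotient of the normalized amplitudes at the two designated samples.
4. **Postprocessing** — per-pulse ratios are smoothed over a trailing
   100-pulse window: values outside the 95 % normal confidence band are
   discarded and the mean of the rest is displayed, provided at least 50
   window values are non-missing.

Patient ICP recordings are confidential, so the package ships a synthetic
generator (`icpulse.simulate`) producing 100 Hz records with known
per-beat ground truth — subpeak positions, ratios, calculability flags,
respiratory modulation, baseline drift, noise and artifact beats — on which
every stage is trained and validated. The neural networks run on a small
self-contained numpy engine (`icpulse.nn`) with hand-written
backpropagation, verified against finite differences.

## Worked example

```python
import numpy as np
from icpulse import (PulseSelector, SubpeakDesignator, RecordConfig,
                     generate_record, generate_pulse_dataset,
                     run_framework, roc_auc, youden_threshold)
from icpulse.pipeline import PipelineConfig

# labeled synthetic pulses (10 % without a calculable ratio)
X, lab = generate_pulse_dataset(2500, seed=101, noncalculable_fraction=0.10)
sel = PulseSelector(kind="lstm", epochs=20, pos_weight="balanced",
                    random_state=7).fit(X, lab["calculable"])

Xd, labd = generate_pulse_dataset(1500, seed=201, noncalculable_fraction=0.0,
                                  noise_sd=0.02)
des = SubpeakDesignator(kind="lstm", mode="curvature", target_sigma=2.0,
                        epochs=30, random_state=0).fit(
                            Xd, labd[["p1", "p2"]].to_numpy())

# a 2-minute noisy record with ground truth
signal, truth = generate_record(RecordConfig(
    duration_s=120, heart_rate_bpm=70, hr_jitter=0.03, noise_sd=0.2,
    resp_amp=1.0, drift_amp=1.0, seed=2))
out = run_framework(signal, 100.0, sel, des, PipelineConfig(threshold=0.5))
print(f"pulses: {len(out.per_pulse)}")
print(f"ratio-associated: {100 * out.ratio_associated_fraction:.1f}%")
print(f"displayed time:  {100 * out.displayed_fraction:.1f}%")
```

prints (exact values depend on the seeds):

```
pulses: 138
ratio-associated: 100.0%
displayed time:  28.3%
```

138 beats were segmented from the 2-minute record; every one passed
selection and received a P2/P1 ratio (the record contains no artifact
beats). The smoothed display series is nevertheless non-missing for only
28.3 % of pulses: the trailing 100-pulse window cannot display anything
for the first ~99 beats of such a short record — the display delay
inherent to the causal smoother (about a minute at 70 bpm). On long
recordings the displayed fraction approaches the ratio-associated
fraction.

The same pipeline is scriptable from the shell:

```sh
icpulse simulate-record --duration 600 --seed 7 --out rec.csv --truth truth.csv
icpulse preprocess --record rec.csv --out pulses.csv
icpulse simulate-pulses --n-pulses 2500 --seed 101 --pulses X.csv --labels y.csv
icpulse train-select --pulses X.csv --labels y.csv --kind lstm --out sel.npz
icpulse train-designate --pulses X.csv --labels y.csv --kind lstm --out des.npz
icpulse run --record rec.csv --selector sel.npz --designator des.npz --out out.csv
icpulse evaluate --truth truth.csv --pred out.csv
```

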