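# myofat

Differential estimation of subcutaneous (SAT) and intermuscular (IMAT)
adipose fractions from through-transmission ultrasound signal trains.

Separating the two fat depots matters clinically — intermuscular fat
(myosteatosis) predicts metabolic and functional decline in ways
subcutaneous fat does not — but today it requires MRI or CT. This package
implements, end to end, a portable-ultrasound alternative evaluated on a
model system: a 5x5 grid of muscle-mimicking phantoms with SAT and IMAT
varying independently from 0 to 50% in 12.5% steps, each insonified 15
times in through-transmission with two tone bursts (0.8 and 2.2 MHz) and a
0.5–2.5 MHz sweep.

Because no measurement data are published for this protocol, the package
includes a calibrated synthetic-signal generator as a first-class module:
bulk velocity follows the empirical law C = 1589 − 155.9·AT m/s (AT the
total adipose fraction, AT = SAT + IMAT(1 − SAT/100), a unit fraction
here), and per-frequency attenuation surfaces are calibrated so the
extracted features reproduce the reference experiment's grid statistics.

From each signal train six evaluation criteria are extracted:

* **Cr1** — speed of sound from the first-zero-crossing arrival time,
  C = L/(t − Δt);
* **Cr2, Cr3** — attenuation at 0.8 / 2.2 MHz, α = 20 log₁₀(I₀/I₁)/L (dB/cm);
* **Cr4** — the ratio Cr2/Cr3;
* **Cr5** — direct-pass sweep intensity (relative units);
* **Cr6** — direct-to-triple-pass sweep intensity ratio.

Two estimators map criteria to (SAT, IMAT):

* **Decision rules (PR/DR)** — per-criterion min–max envelope surfaces
  over the training grid, densified 5→17 nodes per axis with Akima
  splines; a measured value slices a feasible region from each criterion's
  envelope volume, the six regions are intersected, and the estimate is
  the intersection's center of mass.
* **Gated network (ANN)** — a three-layer gated regression network
  (128/64/128 units, dropout 0.2, Adam, MSE, early stopping), the
  feed-forward equivalent of a recurrent network run on length-one
  sequences.

Accuracy is reported at object level across five train/test splits with
R, R², SSE and SEE = √(SSE/(n−2)), plus mean ± SD absolute errors and
5x5 error-topology maps.

## Worked example

```python
import numpy as np
from myofat import (RunConfig, run_experiment, total_fat_fraction)

res = run_experiment(RunConfig(seed=1, run_ann=False))

# criterion discriminability (individuality indices)
print(res["individuality"].round(3))

# decision-rule accuracy, five-split average
table = res["comparison"]
avg = table[(table.split == "average") & (table.method == "pr")]
print(avg[["target", "SEE", "MAE"]].round(2))
```

prints (seed 1):

```
            M     SD.m   CV.m    SD.o   CV.o     II     RII
cr1  1520.814   29.775  0.020   1.283  0.001  0.043  23.151
cr2     0.132    0.027  0.208   0.012  0.087  0.416   2.404
cr3     0.744    0.140  0.188   0.056  0.075  0.398   2.513
cr4     0.182    0.044  0.244   0.012  0.068  0.281   3.565
cr5     0.232    0.100  0.432   0.030  0.131  0.304   3.288
cr6   595.405  293.623  0.493  99.399  0.171  0.346   2.892

 target  SEE  MAE
   imat 2.94 2.40
    sat 3.00 2.32
```

Reading this: ultrasound velocity (cr1) varies 2.0% across the grid but
only 0.1% between repeated measurements of one phantom — an RII of 23,
making it the dominant criterion; the intensity-based criteria
individually discriminate far less (RII 2–4) and contribute jointly. The
decision-rule estimator then recovers both fat fractions with a standard
error of about 3% of fat fraction at object level. Velocity correlates
with total fat as C ≈ 1589 − 156·AT m/s (r ≈ −0.999) on the synthetic
grid, matching the calibration law.

A command-line interface covers the same pipeline stage by stage
(`myofat simulate | extract | fit | estimate | ann-train | ann-predict |
evaluate | run`); `myofat run --seed 1 --out results/` writes records,
surfaces, metrics and error maps in one go.

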