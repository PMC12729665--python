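# Methods

## Problem

Subcutaneous adipose tissue (SAT) and intermuscular adipose tissue (IMAT)
are distinct fat depots with different clinical meaning: IMAT infiltration
(myosteatosis) predicts metabolic and functional decline, while SAT is
largely an energy store. `myofat` re-implements, against synthetic data, a
through-transmission quantitative-ultrasound protocol for estimating the
two depots separately in a simplified limb model: a 5x5 grid of tissue
phantoms in which SAT (percent of the whole volume) and IMAT (percent of
the muscle compartment) vary independently from 0 to 50% in 12.5% steps,
each phantom measured 15 times (375 signal trains).

A signal train holds three received waveforms per pass: two-cycle tone
bursts at 0.8 and 2.2 MHz under a half-period sine envelope and a
0.5-2.5 MHz linear sweep, sampled at 125 Msps over a path of L = 80 mm.
The sweep is strong enough that its second reflection (a triple pass
through the object) is also usable.

## Evaluation criteria

Six scalar features are extracted per train:

| criterion | meaning | estimator |
|---|---|---|
| Cr1 | speed of sound, m/s | C = L/(t - dt), t = first zero crossing after a 20%-of-peak threshold, linearly interpolated |
| Cr2 | attenuation at 0.8 MHz, dB/cm | alpha = 20 log10(I0/I1)/L |
| Cr3 | attenuation at 2.2 MHz, dB/cm | same |
| Cr4 | attenuation ratio | Cr2/Cr3 |
| Cr5 | sweep intensity, rel. units | direct-window intensity / zero-distance intensity |
| Cr6 | direct/triple-pass intensity ratio | I_direct / I_triple |

Intensities are rectified window sums (sum of |amplitude| over a half-open
sample window). A signed sum of a zero-mean burst would cancel toward
zero, so the rectified reading of "signal intensity" is used; this is the
one deliberate deviation from a literal signed sum. Windows are anchored
at the detected arrival onset with a fixed length of three excitation
durations. The triple-pass window is placed by propagating the direct
onset (t3 = onset + 2 x transit time), which is exact for a single
through path. Cr5 is normalised by the zero-distance intensity I0 so that
its scale is instrument-independent; it remains "relative units".

The timing offset dt has two parts: the physical transducer offset
(0 in simulation, carried through the data model for real data) and the
detector's systematic lag between waveform onset and the first
post-threshold zero crossing. The latter is calibrated operationally by
running the detector on the clean excitation itself ("zero distance"),
which cancels the bias exactly. Cr1 is taken from the 0.8 MHz burst
(lowest attenuation, most robust first arrival); this is configurable.

## Synthetic phantom model

No experimental data accompany the protocol, so the generator is the
study's stand-in and its defaults are the study conditions. It is a
phenomenological 1-D model, not a wave simulation:

* **Velocity.** C = 1589 - 155.9 * AT m/s with AT the total adipose
  fraction as a unit fraction, AT = SAT + IMAT (1 - SAT/100); this is the
  empirical linear law observed in the reference experiment, and the only
  quantitative velocity model available. The direct arrival is the
  excitation delayed to L/C and the triple pass to 3L/C, with replicas
  evaluated in continuous time (no integer-sample quantisation).
* **Attenuation.** Per-waveform attenuation surfaces are linear in SAT and
  IMAT percent, `alpha = base + a_s*SAT + a_i*IMAT` (dB/cm), applied as
  amplitude factors 10^(-alpha L/20). The triple-pass replica carries its
  own reflected-path surface over the extra 2L plus two 12 dB reflection
  losses. Between-object gradient norms are solved in closed form from the
  reference whole-dataset and within-object SDs (between-SD =
  sqrt(SD_m^2 - SD_o^2), divided by the per-axis grid SD of 17.68%).
  Gradient *directions* are not pinned by those moments; they are chosen
  to reproduce the reference's multidirectional trends: the 0.8 MHz and
  sweep attenuations respond mostly to SAT (homogeneous oil layers,
  low-frequency absorption) and the 2.2 MHz and reflected-path
  attenuations mostly to IMAT (scattering by dispersed inclusions grows
  with frequency). All coefficients are positive, so every surface is
  non-decreasing in both depots.
* **Within-object noise.** Injected at the acoustic-parameter level so the
  extracted criteria inherit the reference within-object CVs: velocity
  noise 1.31 m/s; multiplicative attenuation noise with CV 9.4% (0.8 MHz)
  and 7.9% (2.2 MHz); additive sweep/triple noise 0.158 / 0.093 dB/cm.
  Because one pass acquires all three waveforms under a single acoustic
  contact, coupling loss is modelled as a shared factor carrying ~65-70%
  of the burst/sweep noise variance (it cancels in the direct/triple
  ratio, whose noise is independent). The shared factor reproduces the
  reference attenuation-ratio within-object CV of 7.2%, which is smaller
  than independent noises could give. A small additive waveform noise
  floor (1e-7 of the excitation amplitude) is configurable separately.
* **Randomness.** One root seed; each record draws from a substream keyed
  by (phantom id, repeat index), so subsetting phantoms or repeats never
  changes an individual record.

With these defaults the full-grid extracted statistics come out within a
few percent of the calibration surface on every criterion (velocity mean
1520.8 / SD 29.8 m/s against 1520.0 / 30.3). One knowing miss: the
attenuation-ratio whole-dataset CV lands near 0.24 instead of 0.184 —
with linear surfaces, spreading the gradient directions (needed for the
decomposition to be identifiable at all) necessarily widens the ratio's
between-object spread. We accept the overshoot rather than give up
identifiability.

What the generator does **not** emulate: diffraction, refraction and
phase distortion at layer boundaries, frequency-dependent dispersion,
transducer impulse responses, the non-monotone local extremes of the real
criterion surfaces, and any anatomical irregularity. Passing tests
therefore show that the estimators recover parameters under the reference
experiment's first- and second-moment structure, not that they would
perform identically on physical data.

## Decision-rule estimator

For each criterion the training records at every grid node give envelope
minima and maxima; the two piecewise-linear surfaces over the 5x5 grid
form a min-max decision volume. Akima splines (tensor-product, rows then
columns) insert three nodes per interval, densifying each axis from 5 to
17 nodes; densified nodes stay inside the original span, so no
extrapolation occurs. A measured value selects the region where it lies
between the envelopes; regions for all six criteria are intersected and
the estimate is the area centroid of the result.

Geometry is computed by marching squares on the two level sets
{value >= min} and {value <= max}, evaluated on a raster refined 8x from
the densified grid (bilinear between nodes), polygonised with even-odd
ring assembly and intersected exactly with shapely. A relative envelope
pad of 1e-6 keeps zero-noise (degenerate) envelopes sliceable as thin
bands, which is what makes noise-free recovery exact to well under the
densified cell size. When the six-way intersection is empty the estimator
falls back to the maximum-cardinality criterion subset with a non-empty
intersection, ties broken by smallest area; multi-component regions use
the area-weighted centroid of the union. Objects measured several times
are estimated per signal and averaged.

## Gated network regressor

The baseline regressor maps the six criteria to (SAT, IMAT). The
reference architecture is three recurrent layers of 128/64/128 units on
sequences of length one with dropout 0.2 between layers. At one time step
with zero initial states the recurrent cell collapses to a gated
feed-forward layer, h = sigm(W_o x) * tanh(sigm(W_i x) * tanh(W_g x)) —
the forget gate multiplies a zero cell state and vanishes — so the
network is implemented directly in numpy in that equivalent form (the
model description carries this flag). Glorot-uniform init, linear output
head.

Training minimises MSE on min-max-normalised features and targets
(normalisation fitted on the training portion only; predictions
denormalised to percent), Adam with batch 16 for up to 1500 epochs,
validation split 20% of the training block. Two choices were genuinely
open and are resolved as follows:

* **Step size.** A fixed rate left per-cluster biases of ~2% unconverged;
  the default is a step schedule 3e-3 / 1e-3 / 3e-4 / 1e-4 switching at
  epochs 500/800/1100.
* **Early stopping.** The safeguard exists to stop *overfitting*; on this
  data the validation loss of a 60-sample set plateaus noisily long
  before convergence, and stopping on any 150-epoch plateau roughly
  doubled the error. The patience counter (150 epochs) therefore runs
  only while validation loss is more than 10% above the best seen;
  the lowest-validation-loss weights are restored in any case.

Seeded runs are reproducible on one platform; bitwise cross-platform
reproducibility is not guaranteed (BLAS reduction order).

## Evaluation protocol

Five train/test partitions: splits 1-3 hold out repeats (1,2,3), (6,7,8),
(11,12,13) of every object; splits 4-5 hold out three random repeats per
object (seeded). Both estimators see identical partitions. Accuracy is
object-level (signal estimates averaged per phantom, n = 25): Pearson R,
R^2 = 1 - SSE/SStot, SSE, SEE = sqrt(SSE/(n-2)) — the n-2 convention is
validated by the printed worked example sqrt(595.7/23) = 5.09 — and mean
+/- SD of |error|. Criterion discriminability is summarised by the
individuality index II = CV.o/CV.m and its reciprocal RII. Error
topology maps show per-object |error| over the 5x5 grid.

## Numerical choices and degenerate inputs

* Arrival detection threshold 20% of peak; first zero crossing strictly
  after exceedance; linear interpolation between bracketing samples;
  all-zero or sub-threshold waveforms raise a no-arrival error.
* Regions with area below 1e-9 %^2 count as empty; an object whose every
  single-criterion region is empty raises an unrecognizable-object error.
* Akima densification can undershoot so that min > max between nodes;
  such cells simply produce empty slices (no clamping).
* A grid with a single level per axis yields a degenerate constant
  surface: fitting warns, and slicing returns the full domain or nothing.
* Record CSVs are written with 12 significant digits, making
  write-read-write cycles byte-stable.

## Problem sizes

Default experiment sizes are the study conditions themselves: 25
phantoms x 15 repeats, five splits, network training to at most 1500
epochs. The whole pipeline (simulation, extraction, both estimators on
all splits) is a few minutes of one CPU; nothing is scaled down.

## Known limitations

* The generator's criterion surfaces are linear; the real ones are
  non-monotone with local extremes. Decision-rule accuracy here
  (five-split SEE ~3%) is accordingly somewhat better than the reference
  experiment's ~6%, while remaining under its bounds.
* The network's object-level IMAT error converges to ~0.9% on this
  synthetic data versus the reference average 0.65% (its per-split spread
  is 0.40-1.20%). A Gaussian posterior-mean benchmark on identical data
  reaches ~0.5%, so the residual gap is a property of smooth MSE
  regression on moderately overlapping clusters, not of the data.
* Cr4 is not invariant under a global amplitude scale (a gain change
  shifts both dB attenuations additively); Cr1 and Cr6 are invariant and
  Cr5 scales linearly.
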