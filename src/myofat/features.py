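"""Extraction of the six evaluation criteria Cr1--Cr6 from a signal train.

Cr1  ultrasound velocity, m/s, from the first-zero-crossing arrival time of
     the 0.8 MHz burst: C = L / (t - dt).
Cr2  attenuation at 0.8 MHz, dB/cm: alpha = 20*log10(I0/I1) / L.
Cr3  attenuation at 2.2 MHz, dB/cm, same estimator.
Cr4  attenuation ratio Cr2/Cr3, dimensionless.
Cr5  direct-pass sweep intensity relative to the zero-distance intensity.
Cr6  ratio of sweep intensities, direct pass over second reflection
     (triple pass), dimensionless.

Intensities are rectified window sums (sum of absolute amplitudes over a
half-open sample window); a raw signed sum of a zero-mean burst would cancel
to near zero, so the rectified reading of "signal intensity" is used
throughout.  Windows are anchored at the detected (or propagated) arrival
onset with a fixed length of three excitation durations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import (
    ExcitationSpec,
    SignalTrain,
    default_excitations,
    synth_excitation,
)

__all__ = [
    "CriterionVector",
    "CalibrationRecord",
    "WindowSpec",
    "NoArrivalError",
    "detect_arrival_time",
    "compute_velocity",
    "window_intensity",
    "compute_attenuation",
    "extract_criteria",
    "spectrum",
    "CRITERION_COLUMNS",
]

CRITERION_COLUMNS = ["cr1", "cr2", "cr3", "cr4", "cr5", "cr6"]

#: analysis window length as a multiple of the excitation duration
WINDOW_LENGTH_FACTOR = 3.0

#: arrival pre-trigger threshold as a fraction of the peak amplitude
DEFAULT_THRESHOLD = 0.2


class NoArrivalError(ValueError):
    """No arrival could be detected (all-zero or below-threshold waveform)."""


@dataclass(frozen=True)
class WindowSpec:
    """Half-open sample window [start, end) on a waveform."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError("window must satisfy 0 <= start < end")

    def validate(self, n_samples: int) -> None:
        if self.end > n_samples:
            raise ValueError(
                f"window [{self.start}, {self.end}) exceeds waveform "
                f"length {n_samples}")


@dataclass(frozen=True)
class CriterionVector:
    """The six extracted features of one signal train."""

    cr1: float
    cr2: float
    cr3: float
    cr4: float
    cr5: float
    cr6: float
    phantom_id: str = ""
    repeat_index: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.cr1, self.cr2, self.cr3,
                         self.cr4, self.cr5, self.cr6])


@dataclass
class CalibrationRecord:
    """Zero-distance intensities and timing offsets per excitation kind.

    ``detection_offset_us`` is the operational part of Eq.-1-style dt: the
    lag between waveform onset and the first post-threshold zero crossing,
    measured on the clean excitation itself, so the estimator cancels the
    detector's systematic bias.  ``transducer_offset_us`` is the physical
    instrument offset (0 in simulation).
    """

    zero_distance_intensity: dict[str, float]
    detection_offset_us: dict[str, float]
    window_samples: dict[str, int]
    transducer_offset_us: float = 0.0
    sample_rate_msps: float = 125.0
    threshold_fraction: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        for k, v in self.zero_distance_intensity.items():
            if v <= 0:
                raise ValueError(f"zero-distance intensity for {k!r} must be > 0")

    @classmethod
    def from_excitations(cls,
                         excitations: tuple[ExcitationSpec, ...] | None = None,
                         transducer_offset_us: float = 0.0,
                         threshold_fraction: float = DEFAULT_THRESHOLD,
                         ) -> "CalibrationRecord":
        """Operational calibration: measure I0 and the detection offset on
        the clean excitation waveforms ("zero distance")."""
        excitations = excitations or default_excitations()
        i0: dict[str, float] = {}
        off: dict[str, float] = {}
        nwin: dict[str, int] = {}
        fs = excitations[0].sample_rate_msps
        for ex in excitations:
            clean = synth_excitation(ex)
            n = int(round(WINDOW_LENGTH_FACTOR * ex.duration_us * fs))
            padded = np.zeros(n)
            padded[:clean.size] = clean[:n]
            i0[ex.label] = window_intensity(padded, WindowSpec(0, n))
            off[ex.label] = detect_arrival_time(clean, fs, threshold_fraction)
            nwin[ex.label] = n
        return cls(zero_distance_intensity=i0, detection_offset_us=off,
                   window_samples=nwin, transducer_offset_us=transducer_offset_us,
                   sample_rate_msps=fs, threshold_fraction=threshold_fraction)


def detect_arrival_time(waveform: np.ndarray,
                        sample_rate_msps: float,
                        threshold_fraction: float = DEFAULT_THRESHOLD) -> float:
    """Arrival time (us) at the first zero crossing after threshold crossing.

    The reference point is the first zero crossing that follows the first
    sample whose absolute amplitude exceeds ``threshold_fraction`` times the
    peak; the crossing instant is linearly interpolated between the
    bracketing samples.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise NoArrivalError("empty waveform")
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold fraction must lie in (0, 1)")
    peak = np.max(np.abs(w))
    if peak == 0.0:
        raise NoArrivalError("all-zero waveform")
    above = np.flatnonzero(np.abs(w) > threshold_fraction * peak)
    if above.size == 0:
        raise NoArrivalError("no sample exceeds the detection threshold")
    k0 = int(above[0])
    seg = w[k0:]
    sign_change = np.flatnonzero(seg[:-1] * seg[1:] <= 0.0)
    if sign_change.size == 0:
        raise NoArrivalError("no zero crossing after threshold exceedance")
    k = k0 + int(sign_change[0])
    a, b = w[k], w[k + 1]
    frac = 0.0 if a == b else a / (a - b)
    return (k + frac) / sample_rate_msps


def compute_velocity(path_length_mm: float, t_us: float, dt_us: float = 0.0) -> float:
    """Cr1: C = L / (t - dt), returned in m/s."""
    if path_length_mm <= 0:
        raise ValueError("path length must be positive")
    if t_us <= dt_us:
        raise ValueError("arrival time must exceed the transducer offset")
    return path_length_mm / (t_us - dt_us) * 1000.0


def window_intensity(waveform: np.ndarray, window: WindowSpec) -> float:
    """Rectified signal intensity: sum of |amplitude| over [start, end)."""
    w = np.asarray(waveform, dtype=float)
    window.validate(w.size)
    return float(np.sum(np.abs(w[window.start:window.end])))


def compute_attenuation(i0: float, i1: float, path_length_cm: float) -> float:
    """Attenuation alpha = 20*log10(I0/I1) / L in dB/cm."""
    if i0 <= 0 or i1 <= 0:
        raise ValueError("intensities must be positive")
    if path_length_cm <= 0:
        raise ValueError("path length must be positive")
    return 20.0 * np.log10(i0 / i1) / path_length_cm


def _arrival_window(t_detect_us: float, offset_us: float, n_window: int,
                    fs: float, n_samples: int) -> WindowSpec:
    onset_us = t_detect_us - offset_us
    start = max(0, int(round(onset_us * fs)))
    end = min(n_samples, start + n_window)
    return WindowSpec(start, end)


def extract_criteria(train: SignalTrain,
                     calib: CalibrationRecord | None = None,
                     velocity_source: str = "burst_08") -> CriterionVector:
    """Extract Cr1--Cr6 from one signal train.

    Velocity uses the 0.8 MHz burst by default (lowest attenuation, most
    robust first arrival).  The sweep triple-pass window is placed by
    propagating the detected direct onset: t3 = onset + 2*(onset - dt),
    which is exact for a single through path.
    """
    calib = calib or CalibrationRecord.from_excitations(
        transducer_offset_us=train.transducer_offset_us)
    fs = train.sample_rate_msps
    thr = calib.threshold_fraction
    L_cm = train.path_length_mm / 10.0
    dt_phys = calib.transducer_offset_us

    waves = {"burst_08": train.waveform_08, "burst_22": train.waveform_22,
             "sweep": train.waveform_sweep}

    # --- Cr1 ---------------------------------------------------------------
    t_det = detect_arrival_time(waves[velocity_source], fs, thr)
    dt_total = dt_phys + calib.detection_offset_us[velocity_source]
    cr1 = compute_velocity(train.path_length_mm, t_det, dt_total)

    # --- Cr2, Cr3 ----------------------------------------------------------
    atts = {}
    for label, wf in (("burst_08", train.waveform_08),
                      ("burst_22", train.waveform_22)):
        t = detect_arrival_time(wf, fs, thr)
        win = _arrival_window(t, calib.detection_offset_us[label],
                              calib.window_samples[label], fs, wf.size)
        i1 = window_intensity(wf, win)
        atts[label] = compute_attenuation(
            calib.zero_distance_intensity[label], i1, L_cm)
    cr2, cr3 = atts["burst_08"], atts["burst_22"]
    if cr3 == 0:
        raise ValueError("Cr3 is zero; attenuation ratio Cr4 is undefined")
    cr4 = cr2 / cr3

    # --- Cr5, Cr6 ----------------------------------------------------------
    wf = train.waveform_sweep
    t_sw = detect_arrival_time(wf, fs, thr)
    onset_us = t_sw - calib.detection_offset_us["sweep"]
    prop_us = onset_us - dt_phys
    n_win = calib.window_samples["sweep"]
    win_d = _arrival_window(t_sw, calib.detection_offset_us["sweep"],
                            n_win, fs, wf.size)
    onset3_us = onset_us + 2.0 * prop_us
    start3 = int(round(onset3_us * fs))
    win_3 = WindowSpec(start3, min(wf.size, start3 + n_win))
    i_direct = window_intensity(wf, win_d)
    i_triple = window_intensity(wf, win_3)
    if i_triple <= 0:
        raise ValueError("triple-pass intensity is zero; Cr6 undefined")
    cr5 = i_direct / calib.zero_distance_intensity["sweep"]
    cr6 = i_direct / i_triple

    return CriterionVector(cr1=cr1, cr2=cr2, cr3=cr3, cr4=cr4, cr5=cr5,
                           cr6=cr6, phantom_id=train.phantom_id,
                           repeat_index=train.repeat_index)


def spectrum(waveform: np.ndarray,
             sample_rate_msps: float = 125.0) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrum (freq axis in MHz); QC/plotting helper."""
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise ValueError("empty waveform")
    mag = np.abs(np.fft.rfft(w))
    freq = np.fft.rfftfreq(w.size, d=1.0 / sample_rate_msps)
    return freq, mag
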