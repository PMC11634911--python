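"""R-peak detection, MED envelope construction and beat segmentation.

The segmentation strategy works entirely from non-invasive channels:

1. R peaks and the step's heart rate are detected from the ECG.
2. The phonocardiogram (MIC) is up- and down-enveloped; the difference
   between the two envelopes is the MED signal (Microphone Envelope
   Difference, in mmHg).
3. The MED signal is band-pass filtered around the detected HR fundamental
   (zero-phase, so minima timing is preserved).
4. For each RR interval, the deepest local minimum of the filtered MED
   within a fraction of the cycle approximates the systole/diastole
   boundary — without using the invasive LVP channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.signal
from scipy.ndimage import maximum_filter1d, minimum_filter1d, uniform_filter1d

from .signal_io import SignalRecord

logger = logging.getLogger(__name__)

#: refractory period between R peaks (s); allows rates up to 250 bpm
REFRACTORY = 0.240
#: beats shorter than this are physiologically implausible and flagged
MIN_RR = 0.250
#: boundary search window as fractions of the RR interval after the R peak
BOUNDARY_WINDOW = (0.2, 0.6)
HR_RANGE = (30.0, 250.0)


class InsufficientDataError(ValueError):
    """Not enough signal or too few beats for the requested operation."""


class NoStableSegmentError(ValueError):
    """No window satisfies the hemodynamic stability rule."""

    def __init__(self, best_duration: float):
        self.best_duration = best_duration
        super().__init__(
            f"no stable window found; best achievable duration {best_duration:.1f} s")


@dataclass
class MedSignal:
    """Envelopes and the (raw and HR-bandpassed) envelope difference."""

    upper: np.ndarray
    lower: np.ndarray
    med_raw: np.ndarray
    med_filtered: np.ndarray
    method: str
    passband: tuple[float, float]


@dataclass
class BeatSegmentation:
    """R peaks plus per-beat systole/diastole boundaries.

    Beat ``i`` spans samples ``[r_peaks[i], r_peaks[i+1])``; its systole is
    ``[r_peaks[i], boundaries[i])`` and diastole ``[boundaries[i],
    r_peaks[i+1])``. Invalid beats carry a reason code and ``boundaries[i]
    == -1``.
    """

    r_peaks: np.ndarray
    hr: float
    boundaries: np.ndarray
    valid: np.ndarray
    reasons: list[str]

    @property
    def n_beats(self) -> int:
        return len(self.r_peaks) - 1

    def valid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.valid)

    def to_frame(self, sampling_rate: float):
        """Segmentation export table (one row per beat)."""
        import pandas as pd
        fs = sampling_rate
        return pd.DataFrame({
            "beat_index": np.arange(self.n_beats),
            "r_onset_s": self.r_peaks[:-1] / fs,
            "boundary_s": np.where(self.boundaries >= 0, self.boundaries / fs, np.nan),
            "r_end_s": self.r_peaks[1:] / fs,
            "valid": self.valid,
            "reason": self.reasons,
        })


# ---------------------------------------------------------------------------
# R peaks and HR
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Detect R peaks with a Pan–Tompkins-style energy detector.

    Band-pass 5–30 Hz, differentiate, square, moving-window integrate,
    then threshold at 0.4x a blockwise 95th percentile of the integrated
    energy. The threshold is relative, so the output is invariant to
    positive rescaling of the ECG. A 240 ms refractory period caps the
    detected rate at 250 bpm. Peaks are refined to the local energy maximum
    of the band-passed signal.
    """
    ecg = np.asarray(ecg, float)
    fs = float(sampling_rate)
    if len(ecg) < 2 * fs:
        raise InsufficientDataError("need at least 2 s of ECG")
    if np.ptp(ecg) == 0:
        logger.warning("ECG is constant; no R peaks detected")
        return np.array([], dtype=int)

    sos = scipy.signal.butter(2, [5.0, 30.0], btype="bandpass", fs=fs, output="sos")
    band = scipy.signal.sosfiltfilt(sos, ecg)
    energy = np.gradient(band) ** 2
    integ = uniform_filter1d(energy, max(1, int(round(0.12 * fs))))

    # blockwise 95th percentile (5 s blocks) -> piecewise adaptive threshold
    block = max(1, int(round(5.0 * fs)))
    nblk = int(np.ceil(len(integ) / block))
    pct = np.array([np.percentile(integ[k * block:(k + 1) * block], 95)
                    for k in range(nblk)])
    thresh = 0.4 * np.repeat(pct, block)[:len(integ)]

    distance = max(1, int(round(REFRACTORY * fs)))
    peaks, _ = scipy.signal.find_peaks(integ, distance=distance)
    peaks = peaks[integ[peaks] > thresh[peaks]]

    # refine each detection to the nearby maximum of band-passed energy
    half = int(round(0.08 * fs))
    refined = []
    b2 = band ** 2
    for p in peaks:
        lo, hi = max(0, p - half), min(len(b2), p + half + 1)
        refined.append(lo + int(np.argmax(b2[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep: list[int] = []
    for p in refined:
        if not keep or p - keep[-1] >= distance:
            keep.append(int(p))
    return np.asarray(keep, dtype=int)


def estimate_hr(r_peaks: np.ndarray, sampling_rate: float) -> float:
    """Step heart rate: 60 / median RR interval (seconds)."""
    if len(r_peaks) < 3:
        raise InsufficientDataError("need at least 3 R peaks to estimate HR")
    rr = np.diff(np.asarray(r_peaks)) / float(sampling_rate)
    return 60.0 / float(np.median(rr))


# ---------------------------------------------------------------------------
# stability selection
# ---------------------------------------------------------------------------

def select_stable_segment(record: SignalRecord, r_peaks: np.ndarray,
                          min_duration: float = 180.0,
                          tolerance: float = 0.10) -> tuple[int, int]:
    """Longest contiguous window of hemodynamically stable beats.

    The per-beat stability proxy is the beat maximum of LVP when present,
    otherwise the beat's POX pulse amplitude. A window qualifies when every
    beat's proxy lies within ``+-tolerance`` of the window median. The
    search greedily extends each candidate start and keeps the longest
    qualifying window of at least ``min_duration`` seconds; if the whole
    record qualifies the full extent is returned.
    """
    r = np.asarray(r_peaks, dtype=int)
    if len(r) < 2:
        raise InsufficientDataError("need at least 2 R peaks")
    src = record.channels.get("LVP")
    if src is not None:
        proxy = np.array([np.max(src[r[i]:r[i + 1]]) for i in range(len(r) - 1)])
    else:
        pox = record.channels["POX"]
        proxy = np.array([np.ptp(pox[r[i]:r[i + 1]]) for i in range(len(r) - 1)])

    n = len(proxy)
    fs = record.sampling_rate
    best: tuple[int, int] | None = None
    best_dur = 0.0
    for i in range(n):
        vals: list[float] = []
        for j in range(i, n):
            vals.append(proxy[j])
            med = float(np.median(vals))
            if np.max(vals) > (1 + tolerance) * med or np.min(vals) < (1 - tolerance) * med:
                break
            dur = (r[j + 1] - r[i]) / fs
            if dur > best_dur:
                best_dur = dur
                best = (i, j)
    if best is None or best_dur < min_duration:
        raise NoStableSegmentError(best_dur)
    i, j = best
    if i == 0 and j == n - 1:
        return 0, record.n_samples
    return int(r[i]), int(r[j + 1])


# ---------------------------------------------------------------------------
# envelopes and MED
# ---------------------------------------------------------------------------

def compute_envelopes(mic: np.ndarray, sampling_rate: float,
                      method: str = "sliding_extrema",
                      window: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower amplitude envelopes of the phonocardiogram.

    ``sliding_extrema`` (default) takes a moving maximum/minimum over
    ``window`` seconds followed by a moving-average smoothing of the same
    width; it guarantees ``upper >= lower`` pointwise. ``spline_peaks``
    interpolates a cubic spline through local maxima/minima separated by at
    least ``window`` (closer to toolbox-style envelopes, but may overshoot).
    """
    mic = np.asarray(mic, float)
    w = int(round(window * sampling_rate))
    if w <= 2:
        raise ValueError("envelope window must span more than 2 samples")
    if method == "sliding_extrema":
        upper = uniform_filter1d(maximum_filter1d(mic, w), w)
        lower = uniform_filter1d(minimum_filter1d(mic, w), w)
        # guard against last-bit rounding in the smoothing filter
        np.minimum(lower, upper, out=lower)
        return upper, lower
    if method == "spline_peaks":
        from scipy.interpolate import CubicSpline
        idx = np.arange(len(mic))

        def spline_through(extrema: np.ndarray) -> np.ndarray:
            knots = np.unique(np.concatenate([[0], extrema, [len(mic) - 1]]))
            if len(knots) < 2:
                return np.full_like(mic, mic[0])
            return CubicSpline(knots, mic[knots])(idx)

        maxima, _ = scipy.signal.find_peaks(mic, distance=w)
        minima, _ = scipy.signal.find_peaks(-mic, distance=w)
        return spline_through(maxima), spline_through(minima)
    raise ValueError(f"unknown envelope method {method!r}")


def design_hr_bandpass(hr: float, sampling_rate: float,
                       rel_band: tuple[float, float] = (0.7, 1.3)) -> np.ndarray:
    """Second-order-section band-pass passing only the HR fundamental.

    Butterworth design with 4 poles (order-2 band-pass), passband
    ``rel_band`` x (hr/60) Hz, intended to be applied forward-backward.
    """
    f0 = hr / 60.0
    lo, hi = rel_band[0] * f0, rel_band[1] * f0
    if hi >= sampling_rate / 2:
        raise ValueError("passband upper edge reaches Nyquist")
    return scipy.signal.butter(2, [lo, hi], btype="bandpass",
                               fs=sampling_rate, output="sos")


def compute_med(upper: np.ndarray, lower: np.ndarray, hr: float,
                sampling_rate: float, method: str = "sliding_extrema") -> MedSignal:
    """MED = upper − lower, band-passed (zero phase) around the HR fundamental."""
    upper = np.asarray(upper, float)
    lower = np.asarray(lower, float)
    med_raw = upper - lower
    sos = design_hr_bandpass(hr, sampling_rate)
    med_filtered = scipy.signal.sosfiltfilt(sos, med_raw)
    # the passband excludes DC; remove the residual mean left by edge
    # transients and the incomplete final cycle
    med_filtered = med_filtered - med_filtered.mean()
    f0 = hr / 60.0
    return MedSignal(upper=upper, lower=lower, med_raw=med_raw,
                     med_filtered=med_filtered, method=method,
                     passband=(0.7 * f0, 1.3 * f0))


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_beats(med: MedSignal, r_peaks: np.ndarray,
                  sampling_rate: float, hr: float | None = None) -> BeatSegmentation:
    """Split each RR interval into systole and diastole at the MED minimum.

    The boundary of beat ``i`` is the deepest local minimum of the filtered
    MED within ``[0.2, 0.6]*RR`` after the R peak (earliest on ties). Beats
    with no local minimum in the window are flagged ``no_med_minimum``;
    beats shorter than 250 ms are flagged ``rr_too_short``.
    """
    r = np.asarray(r_peaks, dtype=int)
    if len(r) < 2:
        raise InsufficientDataError("need at least 2 R peaks to segment beats")
    fs = float(sampling_rate)
    if hr is None:
        hr = 60.0 / (float(np.median(np.diff(r))) / fs)

    x = med.med_filtered
    minima, _ = scipy.signal.find_peaks(-x)
    nb = len(r) - 1
    boundaries = np.full(nb, -1, dtype=int)
    valid = np.zeros(nb, dtype=bool)
    reasons = [""] * nb
    for i in range(nb):
        rr = r[i + 1] - r[i]
        if rr < MIN_RR * fs:
            reasons[i] = "rr_too_short"
            continue
        lo = r[i] + int(np.floor(BOUNDARY_WINDOW[0] * rr))
        hi = r[i] + int(np.ceil(BOUNDARY_WINDOW[1] * rr))
        cand = minima[(minima >= lo) & (minima <= hi)]
        if len(cand) == 0:
            reasons[i] = "no_med_minimum"
            continue
        boundaries[i] = int(cand[np.argmin(x[cand])])
        valid[i] = True
    return BeatSegmentation(r_peaks=r, hr=float(hr), boundaries=boundaries,
                            valid=valid, reasons=reasons)


def segment_record(record: SignalRecord,
                   envelope_method: str = "sliding_extrema",
                   envelope_window: float = 0.05) -> tuple[BeatSegmentation, MedSignal]:
    """Full non-invasive segmentation of one record: ECG -> R peaks/HR,
    MIC -> MED -> systole/diastole boundaries."""
    record.require("ECG", "MIC")
    fs = record.sampling_rate
    r = detect_r_peaks(record.channels["ECG"], fs)
    if len(r) < 3:
        raise InsufficientDataError("fewer than 3 R peaks detected")
    hr = estimate_hr(r, fs)
    upper, lower = compute_envelopes(record.channels["MIC"], fs,
                                     envelope_method, envelope_window)
    med = compute_med(upper, lower, hr, fs, envelope_method)
    seg = segment_beats(med, r, fs, hr)
    return seg, med
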