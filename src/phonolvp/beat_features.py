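"""The 18 per-beat predictors: invPTT plus 17 mel-spectral features.

For each beat, and separately for its systolic and diastolic phonocardiogram
segment, the mel spectrogram is computed and reduced to:

* set A — spectral flux, kurtosis, skewness and slope (4 features);
* set B — the 13 mel-frequency cepstral coefficients in second temporal
  derivative (delta-delta MFCCs).

The 18th predictor is the multiplicative inverse of the pulse transit time
(invPTT), the interval from the ECG R peak to the pulse-oximetry upstroke;
PTT correlates negatively with systolic pressure, making invPTT a
pressure-tracking predictor. A predictor vector for any regression target
is then [invPTT, set A (4), set B (13)] of the target's phase: 18 entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft
from scipy.ndimage import uniform_filter1d

from .preprocess_segment import BeatSegmentation, InsufficientDataError

logger = logging.getLogger(__name__)

SET_A_NAMES = ("flux", "kurtosis", "skewness", "slope")
N_MFCC = 13


class DegenerateSpectrumError(ValueError):
    """Every frame of the spectrogram is empty or has zero spread."""


@dataclass(frozen=True)
class SpectroConfig:
    """Mel-spectrogram parameters.

    Defaults: 50 ms Hann frames, 10 ms hop, 32 triangular mel bands spanning
    20–150 Hz (the band that carries heart-sound energy) on the HTK mel
    scale m = 2595*log10(1 + f/700); even the shortest analysis segment — a
    systole at 160 beats/min — still yields about 14 frames. The FFT is
    zero-padded to at least 256 points: at a 1 kHz sampling rate a 50-sample
    frame alone would give 20 Hz bins, coarser than the narrowest mel band.
    ``noise_gate_db``
    zeroes band energies more than that many dB below the segment's peak
    band energy (a spectral noise gate, analogous to the dynamic-range
    floor conventional in MFCC pipelines), so frames that contain only
    sensor noise behave like silent frames; ``None`` disables the gate.
    ``mfcc_first`` selects which cepstral coefficient starts set B (0 keeps
    the energy-like coefficient; 1 drops it).
    """

    frame: float = 0.050
    hop: float = 0.010
    n_bands: int = 32
    fmin: float = 20.0
    fmax: float = 150.0
    nfft: int | None = None
    log_floor: float = 1e-10
    floor_db: float | None = 27.0
    noise_gate_db: float | None = None
    delta_width: int = 2
    mfcc_first: int = 0

    def nfft_for(self, frame_samples: int) -> int:
        if self.nfft is not None:
            return self.nfft
        return max(256, 1 << int(np.ceil(np.log2(max(frame_samples, 2)))))


@dataclass
class MelSpectrogram:
    """Nonnegative band energies on a mel-spaced frequency axis."""

    frame_times: np.ndarray  # s, frame centres
    band_centers: np.ndarray  # Hz, strictly increasing
    energies: np.ndarray  # (frames, bands), >= 0
    frame_length: float  # s
    hop: float  # s

    @property
    def n_frames(self) -> int:
        return self.energies.shape[0]


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def mel_filterbank(sampling_rate: float, nfft: int, n_bands: int,
                   fmin: float, fmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank; returns (weights (bands, bins), centres Hz)."""
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_bands + 2))
    bins_hz = np.fft.rfftfreq(nfft, d=1.0 / sampling_rate)
    fb = np.zeros((n_bands, len(bins_hz)))
    for b in range(n_bands):
        lo, mid, hi = edges_hz[b], edges_hz[b + 1], edges_hz[b + 2]
        up = (bins_hz - lo) / (mid - lo)
        down = (hi - bins_hz) / (hi - mid)
        fb[b] = np.clip(np.minimum(up, down), 0.0, None)
    return fb, edges_hz[1:-1]


def mel_spectrogram(segment: np.ndarray, sampling_rate: float,
                    cfg: SpectroConfig | None = None) -> MelSpectrogram:
    """Framewise mel band energies of a phonocardiogram segment.

    Frame count is ``floor((L - frame)/hop) + 1`` for segments of at least
    one frame; shorter segments yield a single zero-padded frame.
    """
    cfg = cfg or SpectroConfig()
    fs = float(sampling_rate)
    if cfg.fmax > fs / 2:
        raise ValueError("mel band range exceeds Nyquist")
    x = np.asarray(segment, float)
    flen = int(round(cfg.frame * fs))
    hop = max(1, int(round(cfg.hop * fs)))
    if len(x) < flen:
        frames = np.zeros((1, flen))
        frames[0, :len(x)] = x
        starts = np.array([0])
    else:
        nfr = (len(x) - flen) // hop + 1
        starts = np.arange(nfr) * hop
        frames = np.lib.stride_tricks.sliding_window_view(x, flen)[::hop][:nfr]
    win = np.hanning(flen)
    nfft = cfg.nfft_for(flen)
    spec = np.abs(np.fft.rfft(frames * win, n=nfft, axis=1)) ** 2
    fb, centers = mel_filterbank(fs, nfft, cfg.n_bands, cfg.fmin, cfg.fmax)
    energies = spec @ fb.T
    if cfg.noise_gate_db is not None and energies.size and energies.max() > 0:
        thr = energies.max() * 10.0 ** (-cfg.noise_gate_db / 10.0)
        energies = np.where(energies < thr, 0.0, energies)
    times = (starts + flen / 2) / fs
    return MelSpectrogram(frame_times=times, band_centers=centers,
                          energies=energies, frame_length=flen / fs, hop=hop / fs)


# ---------------------------------------------------------------------------
# set A: spectral shape descriptors
# ---------------------------------------------------------------------------

def spectral_features_setA(spec: MelSpectrogram) -> tuple[float, float, float, float]:
    """(flux, kurtosis, skewness, slope), each averaged over frames.

    Per frame, with band energies s_k at centres f_k: the energy-weighted
    centroid/spread define skewness and kurtosis (third and fourth
    standardized moments); slope is the least-squares slope of s against f;
    flux is the Euclidean norm of the difference of unit-sum-normalized
    energies between consecutive frames. Empty frames (sum 0) are skipped
    everywhere; frames with zero spectral spread additionally contribute no
    skewness/kurtosis. Raises :class:`DegenerateSpectrumError` when every
    frame is degenerate.
    """
    s = spec.energies
    f = spec.band_centers
    total = s.sum(axis=1)
    nonempty = total > 0
    if not nonempty.any():
        raise DegenerateSpectrumError("all frames have zero spectral mass")

    sn = s[nonempty]
    tn = total[nonempty]
    mu = (sn * f).sum(axis=1) / tn
    var = (sn * (f - mu[:, None]) ** 2).sum(axis=1) / tn
    sd = np.sqrt(var)
    spread_ok = sd > 0
    if not spread_ok.any():
        raise DegenerateSpectrumError("all frames have zero spectral spread")
    m3 = (sn * (f - mu[:, None]) ** 3).sum(axis=1) / tn
    m4 = (sn * (f - mu[:, None]) ** 4).sum(axis=1) / tn
    skew = float(np.mean(m3[spread_ok] / sd[spread_ok] ** 3))
    kurt = float(np.mean(m4[spread_ok] / sd[spread_ok] ** 4))

    fbar = f.mean()
    denom = ((f - fbar) ** 2).sum()
    slopes = ((f - fbar) * (sn - sn.mean(axis=1, keepdims=True))).sum(axis=1) / denom
    slope = float(np.mean(slopes))

    # flux over consecutive originally-adjacent non-empty frame pairs
    norm = np.zeros_like(s)
    norm[nonempty] = s[nonempty] / total[nonempty, None]
    pair_ok = nonempty[1:] & nonempty[:-1]
    if pair_ok.any():
        d = norm[1:][pair_ok] - norm[:-1][pair_ok]
        flux = float(np.mean(np.linalg.norm(d, axis=1)))
    else:
        flux = 0.0
    return flux, kurt, skew, slope


# ---------------------------------------------------------------------------
# set B: delta-delta MFCCs
# ---------------------------------------------------------------------------

def _delta(c: np.ndarray, width: int) -> np.ndarray:
    """Regression-based temporal derivative with edge-replicated frames."""
    pad = np.concatenate([np.repeat(c[:1], width, axis=0), c,
                          np.repeat(c[-1:], width, axis=0)], axis=0)
    denom = 2 * sum(n * n for n in range(1, width + 1))
    out = np.zeros_like(c)
    for n in range(1, width + 1):
        out += n * (pad[width + n:width + n + len(c)] -
                    pad[width - n:width - n + len(c)])
    return out / denom


def mfcc_delta_delta(spec: MelSpectrogram,
                     cfg: SpectroConfig | None = None) -> np.ndarray:
    """The 13 delta-delta mel-frequency cepstral coefficients.

    Per frame: cepstra = orthonormal DCT-II of log(energy + floor), keeping
    13 coefficients starting at ``cfg.mfcc_first``; the delta operator (window
    2, edge replication) is applied twice; the result is the frame mean of
    the delta-delta vectors.

    The floor is the larger of ``cfg.log_floor`` and ``cfg.floor_db`` dB
    below the spectrogram's peak band energy: a dynamic-range floor (as is
    conventional in cepstral pipelines) that stops near-empty bands from
    dominating the log spectrum. Because the relative floor scales with the
    signal, a gain change still adds a pure constant to the log energies,
    which the delta operator removes — set B is exactly invariant to
    rescaling of the input segment.
    """
    cfg = cfg or SpectroConfig()
    floor = cfg.log_floor
    if cfg.floor_db is not None and spec.energies.size and spec.energies.max() > 0:
        floor = max(floor, spec.energies.max() * 10.0 ** (-cfg.floor_db / 10.0))
    logE = np.log(spec.energies + floor)
    cep = scipy.fft.dct(logE, type=2, norm="ortho", axis=1)
    cep = cep[:, cfg.mfcc_first:cfg.mfcc_first + N_MFCC]
    dd = _delta(_delta(cep, cfg.delta_width), cfg.delta_width)
    return dd.mean(axis=0)


# ---------------------------------------------------------------------------
# invPTT
# ---------------------------------------------------------------------------

@dataclass
class InvPttResult:
    ptt: np.ndarray  # s, NaN when invalid
    invptt: np.ndarray  # 1/s, NaN when invalid
    valid: np.ndarray
    reasons: list[str]


def compute_invptt(r_peaks: np.ndarray, pox: np.ndarray,
                   sampling_rate: float, smooth: float = 0.025) -> InvPttResult:
    """Per-beat inverse pulse transit time from ECG R peaks and POX.

    The pulse-arrival fiducial is the maximum of the first derivative of
    the POX waveform (smoothed over ``smooth`` seconds — symmetric, so the
    upslope instant is unbiased) within ``(r_i, r_i + 0.6*RR]``; maximum
    upslope is robust to baseline drift and, with smoothing, to channel
    noise. Beats without a positive upslope are flagged ``no_pox_upstroke``.
    """
    r = np.asarray(r_peaks, dtype=int)
    if len(r) < 2:
        raise InsufficientDataError("need at least 2 R peaks for PTT")
    fs = float(sampling_rate)
    pox = np.asarray(pox, float)
    w = max(1, int(round(smooth * fs)))
    sm = uniform_filter1d(pox, w) if w > 1 else pox
    d = np.gradient(sm) * fs

    nb = len(r) - 1
    ptt = np.full(nb, np.nan)
    valid = np.zeros(nb, dtype=bool)
    reasons = [""] * nb
    for i in range(nb):
        rr = r[i + 1] - r[i]
        lo = r[i] + 1
        hi = min(len(d), r[i] + int(np.ceil(0.6 * rr)) + 1)
        if hi <= lo:
            reasons[i] = "no_pox_upstroke"
            continue
        k = lo + int(np.argmax(d[lo:hi]))
        if d[k] <= 0:
            reasons[i] = "no_pox_upstroke"
            continue
        # sub-sample refinement: parabola through the three samples at the peak
        frac = 0.0
        if lo < k < hi - 1:
            y0, y1, y2 = d[k - 1], d[k], d[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                frac = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
        ptt[i] = (k + frac - r[i]) / fs
        valid[i] = True
    with np.errstate(divide="ignore", invalid="ignore"):
        invptt = 1.0 / ptt
    return InvPttResult(ptt=ptt, invptt=invptt, valid=valid, reasons=reasons)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _phase_columns(phase: str) -> list[str]:
    return [f"{phase}_{n}" for n in SET_A_NAMES] + \
        [f"{phase}_mfccdd_{k:02d}" for k in range(N_MFCC)]


def predictor_columns(phase: str) -> list[str]:
    """The 18 predictor column names for a target of the given phase."""
    return ["invptt"] + _phase_columns(phase)


@dataclass
class BeatFeatureTable:
    """Per-beat predictors for both phases, one row per segmented beat."""

    table: pd.DataFrame
    sampling_rate: float
    step_label: str = ""

    @property
    def n_valid(self) -> int:
        return int(self.table["valid"].sum())


def assemble_feature_table(seg: BeatSegmentation, mic: np.ndarray,
                           pox: np.ndarray, sampling_rate: float,
                           cfg: SpectroConfig | None = None,
                           step_label: str = "") -> BeatFeatureTable:
    """Compute all 18 predictors per valid beat (both phases).

    Rows for beats that fail segmentation, PTT detection, or produce a
    degenerate spectrum in either phase are flagged invalid with a reason
    and are excluded from regression downstream.
    """
    cfg = cfg or SpectroConfig()
    fs = float(sampling_rate)
    mic = np.asarray(mic, float)
    inv = compute_invptt(seg.r_peaks, pox, fs)

    rows = []
    r = seg.r_peaks
    for i in range(seg.n_beats):
        row: dict = {"beat_index": i, "valid": False, "reason": ""}
        for phase in ("sys", "dia"):
            for c in _phase_columns(phase):
                row[c] = np.nan
        row["invptt"] = inv.invptt[i] if inv.valid[i] else np.nan
        if not seg.valid[i]:
            row["reason"] = seg.reasons[i]
            rows.append(row)
            continue
        if not inv.valid[i]:
            row["reason"] = inv.reasons[i]
            rows.append(row)
            continue
        r0, b, r1 = int(r[i]), int(seg.boundaries[i]), int(r[i + 1])
        ok = True
        for phase, (lo, hi) in (("sys", (r0, b)), ("dia", (b, r1))):
            segment = mic[lo:hi]
            spec = mel_spectrogram(segment, fs, cfg)
            try:
                a = spectral_features_setA(spec)
            except DegenerateSpectrumError:
                row["reason"] = "degenerate_spectrum"
                ok = False
                break
            dd = mfcc_delta_delta(spec, cfg)
            for name, val in zip(SET_A_NAMES, a):
                row[f"{phase}_{name}"] = val
            for k in range(N_MFCC):
                row[f"{phase}_mfccdd_{k:02d}"] = dd[k]
        row["valid"] = ok
        rows.append(row)

    if not any(r_["valid"] for r_ in rows):
        logger.warning("feature table has no valid beats")
    cols = (["beat_index", "invptt"] + _phase_columns("sys") +
            _phase_columns("dia") + ["valid", "reason"])
    table = pd.DataFrame(rows, columns=cols)
    return BeatFeatureTable(table=table, sampling_rate=fs, step_label=step_label)
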