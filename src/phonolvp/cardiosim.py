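"""Synthetic four-channel cardiac recordings with known per-beat truth.

The simulator emulates the study conditions of an invasive pacing protocol
in minipigs: five measurement steps (spontaneous rhythm then right
ventricular pacing at 100/120/140/160 beats/min), each held long enough to
collect a few hundred beats, recorded as synchronized ECG, LVP, MIC
(phonocardiogram) and POX (pulse oximetry) channels at a nominal 1 kHz.

Every rendered record is backed by a :class:`GroundTruth` holding the
per-beat latent hemodynamics — end-diastolic pressure (EDP), end-systolic
pressure (ESP), peak pressure-rise rate (dP/dt_max) and pulse transit time
(PTT) — so every downstream stage (segmentation, feature extraction,
regression) can be scored against known values.

Design of the acoustic channel
------------------------------
S1 and S2 are amplitude-modulated tone bursts (default 40 and 65 Hz) whose
gain and centre frequency are affine in the beat's indices, so that the
mel-spectral predictors carry the information the regression stage is meant
to recover. The systole/diastole boundary detector downstream works on the
heart-rate-bandpassed envelope difference (MED) of MIC, which is nearly a
sinusoid at the HR fundamental. With S1 at phase 0 and S2 at phase theta of
the cycle, the fundamental's minimum is confined between half a cycle and
half a cycle past S2, whatever the burst weights; it coincides with the S2
instant only when theta is exactly half a cycle, where the phasor sum of
the two bursts is real (for S1 louder than S2) and the minimum is pinned at
mid-cycle independently of beat-to-beat loudness jitter. The simulator
therefore renders systole as exactly half the RR interval with an S1:S2
gain ratio of 1.8 — the geometry under which MED minima mark end-systole,
the property the paper's segmentation rests on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import SignalRecord

logger = logging.getLogger(__name__)

PACING_RATE_RANGE = (30.0, 250.0)


class SimulationError(ValueError):
    """Invalid protocol, preset or coupling configuration."""


# ---------------------------------------------------------------------------
# protocol and presets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolStep:
    label: str
    pacing_rate: float | None  # beats/min; None = spontaneous rhythm
    duration: float  # seconds

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise SimulationError(f"step {self.label!r}: duration must be > 0")
        if self.pacing_rate is not None and not (
                PACING_RATE_RANGE[0] <= self.pacing_rate <= PACING_RATE_RANGE[1]):
            raise SimulationError(
                f"step {self.label!r}: pacing rate {self.pacing_rate} outside "
                f"{PACING_RATE_RANGE} beats/min")


@dataclass(frozen=True)
class ProtocolSpec:
    """An ordered list of measurement steps."""

    steps: tuple[ProtocolStep, ...]

    def __len__(self) -> int:
        return len(self.steps)

    def labels(self) -> list[str]:
        return [s.label for s in self.steps]


def default_protocol(spontaneous_hr: float = 78.0,
                     step_duration: float = 180.0) -> ProtocolSpec:
    """The 5-step pacing protocol: spontaneous, then 100/120/140/160 bpm.

    ``step_duration`` defaults to 180 s (at least 3 min of stable
    hemodynamics per step); it must be >= 10 s.
    """
    if not (PACING_RATE_RANGE[0] <= spontaneous_hr <= PACING_RATE_RANGE[1]):
        raise SimulationError(f"spontaneous HR {spontaneous_hr} outside {PACING_RATE_RANGE}")
    if step_duration < 10:
        raise SimulationError("step_duration must be >= 10 s")
    steps = [ProtocolStep("spontaneous", None, step_duration)]
    steps += [ProtocolStep(f"{r}bpm", float(r), step_duration) for r in (100, 120, 140, 160)]
    return ProtocolSpec(tuple(steps))


@dataclass(frozen=True)
class HemodynamicPreset:
    """Mean per-beat hemodynamics around which beats are jittered."""

    label: str
    mean_hr: float  # beats/min
    mean_edp: float  # mmHg
    mean_esp: float  # mmHg
    mean_dpdtmax: float  # mmHg/s

    def __post_init__(self) -> None:
        if not (self.mean_esp > self.mean_edp > 0):
            raise SimulationError("preset requires mean_esp > mean_edp > 0")
        if self.mean_dpdtmax <= 0:
            raise SimulationError("preset requires mean_dpdtmax > 0")


def healthy_preset() -> HemodynamicPreset:
    """Baseline hemodynamics of the healthy control animal."""
    return HemodynamicPreset("healthy", mean_hr=78.0, mean_edp=5.70,
                             mean_esp=64.81, mean_dpdtmax=1168.75)


def hfref_preset() -> HemodynamicPreset:
    """Baseline hemodynamics of the tachypacing-induced HFrEF animal."""
    return HemodynamicPreset("hfref", mean_hr=78.0, mean_edp=15.45,
                             mean_esp=77.65, mean_dpdtmax=581.55)


PRESETS = {"healthy": healthy_preset, "hfref": hfref_preset}


# ---------------------------------------------------------------------------
# coupling and noise configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingConfig:
    """Beat-to-beat variability and index -> signal couplings.

    ``sigma`` is the marginal standard deviation of the per-index AR(1)
    perturbation as a fraction of the preset mean; ``rho`` its lag-1
    autocorrelation. PTT is affine in ESP with a negative slope
    (higher systolic pressure -> faster pulse arrival), floored at 50 ms.
    Acoustic couplings make S1 gain affine in dP/dt_max, S1 frequency
    affine in EDP, and S2 gain/frequency affine in ESP.
    """

    sigma: float = 0.05
    rho: float = 0.5
    rr_jitter: float = 0.002
    rr_rho: float = 0.0  # lag-1 autocorrelation of the RR jitter
    # PTT model: ptt = a + b*(esp - mean_esp), floored
    ptt_intercept: float = 0.150  # s
    ptt_slope: float = -0.002  # s per mmHg, must be <= 0
    ptt_floor: float = 0.050  # s
    # acoustic couplings (fractional response per fractional index deviation)
    s1_gain: float = 0.08  # mmHg, burst amplitude (HFrEF default; louder sounds)
    s1_s2_ratio: float = 1.8
    # S1 frequency tracks filling pressure (a stiffer, pressure-loaded
    # ventricle transmits higher-pitched closure sounds); S1 gain and the
    # S2 frequency track contractility; S2 gain tracks end-systolic
    # pressure (louder closure against higher aortic pressure).
    s1_freq: float = 40.0  # Hz
    s1_amp_slope: float = 1.0  # d(gain)/gain per d(dpdtmax)/mean
    s1_freq_slope: float = 3.5  # d(freq)/freq per d(edp)/mean
    s2_freq: float = 65.0  # Hz
    s2_amp_slope: float = 1.0  # d(gain)/gain per d(esp)/mean
    s2_freq_slope: float = 1.2  # d(freq)/freq per d(dpdtmax)/mean
    # mid-systolic ejection murmur filling the gap between S1 and S2; its
    # frequency/gain track contractility, giving dP/dt_max a spectral
    # channel present in every mid-systolic frame (no silent-frame
    # dilution). The matching mid-diastolic rumble (a filling murmur,
    # typical of elevated filling pressure) mirrors it about end-systole,
    # so the two phasors cancel in the MED fundamental and the minimum
    # stays pinned at end-systole.
    murmur_freq: float = 90.0  # Hz, systolic ejection murmur
    murmur_rel_amp: float = 0.0  # relative to the S1 gain (0 disables)
    murmur_freq_slope: float = 1.2  # d(freq)/freq per d(dpdtmax)/mean
    murmur_amp_slope: float = 1.0  # per d(dpdtmax)/mean
    rumble_freq: float = 55.0  # Hz, diastolic rumble
    rumble_rel_amp: float = 0.0  # relative to the S1 gain (0 disables)
    rumble_freq_slope: float = 0.8  # d(freq)/freq per d(esp)/mean
    rumble_amp_slope: float = 1.0  # per d(esp)/mean
    murmur_gap: float = 0.070  # s clearance from the S1/S2 burst centres
    murmur_taper: float = 0.020  # s raised-cosine taper at each murmur edge
    burst_duration: float = 0.120  # s
    burst_decay: float = 0.080  # s, exponential decay of the burst envelope
    # Both bursts are support-centred on their fiducials (S1 on the R peak,
    # S2 on end-systole). The exponential damping pulls each envelope
    # centroid slightly before the support centre by the same amount, so
    # the MED-fundamental minimum — which locks to the energy centroid —
    # carries only a small common offset from end-systole.
    pox_rise: float = 0.100  # s, POX anacrotic rise time (fast systolic upstroke)
    pox_amp_slope: float = 0.3  # POX pulse amplitude response per d(esp)/mean
    # LVP template constants
    peak_excess: float = 8.0  # mmHg above ESP at peak pressure
    fall_duration: float = 0.030  # s, isovolumic relaxation drop

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise SimulationError("AR(1) coefficient rho must be in [0, 1)")
        if self.ptt_slope > 0:
            raise SimulationError("PTT-ESP coupling slope must be <= 0 "
                                  "(transit time shortens as pressure rises)")
        if self.sigma < 0 or self.rr_jitter < 0:
            raise SimulationError("noise scales must be >= 0")


def default_coupling(preset: HemodynamicPreset | str | None = None) -> CouplingConfig:
    """Coupling defaults; the healthy preset renders quieter sounds."""
    label = preset.label if isinstance(preset, HemodynamicPreset) else preset
    if label == "healthy":
        return CouplingConfig(s1_gain=0.04)
    return CouplingConfig()


@dataclass(frozen=True)
class NoiseConfig:
    """Additive white Gaussian noise per channel, as SNR in dB.

    ``None`` disables noise on that channel. The noise standard deviation is
    rms(signal) / 10^(SNR/20).
    """

    ecg_snr_db: float | None = None
    lvp_snr_db: float | None = None
    mic_snr_db: float | None = None
    pox_snr_db: float | None = None

    @classmethod
    def uniform(cls, snr_db: float | None) -> "NoiseConfig":
        """The same SNR on all four channels (including invasive LVP)."""
        return cls(snr_db, snr_db, snr_db, snr_db)

    @classmethod
    def noninvasive(cls, snr_db: float | None) -> "NoiseConfig":
        """SNR on the non-invasive channels only; LVP stays clean, as the
        catheter pressure is the reference measurement, not the degraded
        acquisition under study."""
        return cls(ecg_snr_db=snr_db, lvp_snr_db=None,
                   mic_snr_db=snr_db, pox_snr_db=snr_db)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-beat latent truth for one protocol step.

    ``r_times`` holds ``n_beats + 1`` fence posts: beat ``i`` spans
    ``[r_times[i], r_times[i+1])``. All per-beat arrays have length
    ``n_beats``. ``end_systole_times[i]`` is the instant at which LVP passes
    through ``esp[i]`` with the most negative slope (S2 is centred there).
    """

    step_label: str
    pacing_rate: float | None
    duration: float
    r_times: np.ndarray
    end_systole_times: np.ndarray
    edp: np.ndarray
    esp: np.ndarray
    dpdtmax: np.ndarray
    ptt: np.ndarray

    @property
    def n_beats(self) -> int:
        return len(self.r_times) - 1

    def __post_init__(self) -> None:
        r = np.asarray(self.r_times, float)
        if len(r) < 2:
            raise SimulationError("ground truth needs at least one beat")
        if not np.all(np.diff(r) > 0):
            raise SimulationError("r_times must be strictly increasing")
        tes = np.asarray(self.end_systole_times, float)
        if not (np.all(tes > r[:-1]) and np.all(tes < r[1:])):
            raise SimulationError("end-systole times must lie inside their beat")
        if not np.all(self.esp > self.edp):
            raise SimulationError("esp must exceed edp on every beat")
        rr = np.diff(r)
        if not np.all((self.ptt > 0) & (self.ptt < 0.6 * rr)):
            raise SimulationError("ptt must lie in (0, 0.6*RR)")


#: s, raised-cosine slope blend at each end of the LVP upstroke
_BLEND = 0.020
#: systolic fraction of the RR interval; exactly one half, so that the
#: minimum of the HR-fundamental of the two-burst acoustic envelope falls
#: at end-systole (the phasor sum of S1 at phase 0 and S2 at phase pi is
#: real whenever S1 outweighs S2, pinning the minimum at half the cycle)
_SYSTOLIC_FRACTION = 0.5


def _ar1(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) with marginal std ``sigma``; clipped at +-3 sigma."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * np.sqrt(1 - rho ** 2), size=n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return np.clip(x, -3 * sigma, 3 * sigma)


def simulate_hemodynamics(protocol: ProtocolSpec,
                          preset: HemodynamicPreset,
                          coupling: CouplingConfig | None = None,
                          seed: int | None = 0) -> list[GroundTruth]:
    """Draw per-beat hemodynamics for every protocol step.

    Beat times follow the step's pacing rate with multiplicative RR jitter;
    EDP, ESP and dP/dt_max are independent AR(1) perturbations around the
    preset means; PTT is affine in ESP with the configured negative slope.
    Identical seeds give identical output.
    """
    coupling = coupling if coupling is not None else default_coupling(preset)
    root = np.random.SeedSequence([0x5EED, int(seed)])
    truths = []
    for step_seq, step in zip(root.spawn(len(protocol)), protocol.steps):
        rng = np.random.default_rng(step_seq)
        rate = step.pacing_rate if step.pacing_rate is not None else preset.mean_hr
        rr_mean = 60.0 / rate

        n_max = int(np.ceil(step.duration / rr_mean)) + 3
        jit = _ar1(rng, n_max, coupling.rr_jitter, coupling.rr_rho)
        r_times = [0.2]
        for j in jit:
            if r_times[-1] >= step.duration:
                break
            r_times.append(r_times[-1] + rr_mean * (1 + j))
        r = np.array(r_times)
        n = len(r) - 1
        rr = np.diff(r)

        edp = preset.mean_edp * (1 + _ar1(rng, n, coupling.sigma, coupling.rho))
        esp = preset.mean_esp * (1 + _ar1(rng, n, coupling.sigma, coupling.rho))
        dpdt = preset.mean_dpdtmax * (1 + _ar1(rng, n, coupling.sigma, coupling.rho))

        # Reciprocal-affine transit-time law: invPTT (the regression feature)
        # is exactly affine in ESP, while d(PTT)/d(ESP) at the operating
        # point equals ptt_slope (negative: the pulse travels faster at
        # higher systolic pressure).
        a = coupling.ptt_intercept
        inv_ptt = 1.0 / a - (coupling.ptt_slope / a ** 2) * (esp - preset.mean_esp)
        ptt = 1.0 / np.maximum(inv_ptt, 1e-6)
        ptt = np.maximum(ptt, coupling.ptt_floor)
        ptt = np.minimum(ptt, 0.55 * rr)  # keep the POX fiducial inside the beat

        # end-systole at half the RR interval, stretched (rarely) if the
        # upstroke — whose duration is fixed by dP/dt_max — would not fit
        p_peak = esp + coupling.peak_excess
        d_up = (p_peak - edp) / dpdt + _BLEND  # slope-blend overhead, see render
        t_es_rel = _SYSTOLIC_FRACTION * rr
        t_es_rel = np.maximum(t_es_rel, d_up + coupling.fall_duration / 2 + 0.005)
        t_es = r[:-1] + t_es_rel
        if np.any(t_es >= r[1:]):
            raise SimulationError(
                f"step {step.label!r}: systole does not fit inside the beat; "
                "preset/coupling combination is infeasible")

        truths.append(GroundTruth(step.label, step.pacing_rate, step.duration,
                                  r, t_es, edp, esp, dpdt, ptt))
    return truths


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _lvp_beat(t: np.ndarray, r0: float, r1: float, t_es: float,
              edp0: float, edp1: float, esp: float, dpdt: float,
              peak_excess: float, fall: float) -> np.ndarray:
    """Analytic LVP for one beat on the sample grid ``t`` (t in [r0, r1)).

    Piecewise C1 template: a slope-blended linear upstroke whose maximum
    slope is exactly ``dpdt`` and which rises from ``edp0`` to
    ``esp + peak_excess``; a plateau; a raised-cosine isovolumic fall whose
    midpoint (time ``t_es``, most negative slope) passes through ``esp``;
    and a slow raised-cosine diastolic decay to the next beat's EDP.
    """
    p_peak = esp + peak_excess
    p_min = esp - peak_excess
    dp = p_peak - edp0
    tb = _BLEND
    d_up = dp / dpdt + tb
    u = t - r0
    out = np.empty_like(t)

    # upstroke: slope ramps 0->S (cosine), holds S, ramps S->0
    s = dpdt
    seg1 = u <= tb
    seg2 = (u > tb) & (u <= d_up - tb)
    seg3 = (u > d_up - tb) & (u <= d_up)
    u1 = u[seg1]
    out[seg1] = edp0 + s * (u1 - (tb / np.pi) * np.sin(np.pi * u1 / tb)) / 2
    out[seg2] = edp0 + s * tb / 2 + s * (u[seg2] - tb)
    v = u[seg3] - (d_up - tb)
    out[seg3] = edp0 + s * (d_up - 2 * tb) + s * tb / 2 + \
        s * (v + (tb / np.pi) * np.sin(np.pi * v / tb)) / 2

    t_fall0 = t_es - fall / 2
    plateau = (u > d_up) & (t < t_fall0)
    out[plateau] = p_peak

    falling = (t >= t_fall0) & (t < t_fall0 + fall)
    out[falling] = esp + peak_excess * np.cos(np.pi * (t[falling] - t_fall0) / fall)

    t_dec0 = t_fall0 + fall
    decay = t >= t_dec0
    t2 = max(r1 - t_dec0, 1e-6)
    w = (t[decay] - t_dec0) / t2
    out[decay] = edp1 + (p_min - edp1) * (1 + np.cos(np.pi * w)) / 2
    return out


def _env_centroid(duration: float, decay: float | None,
                  attack: float | None) -> float:
    """Energy centroid (from burst onset) of the burst envelope.

    The band-passed MED fundamental locks its minimum to the acoustic
    energy centroid, so bursts are positioned by centroid, not by support
    midpoint.
    """
    u = np.linspace(0.0, duration, 512)
    env = np.sin(np.pi * u / duration) ** 2
    if decay is not None:
        env = env * np.exp(-u / decay)
    if attack is not None:
        env = env * np.exp((u - duration) / attack)
    w = env  # MED tracks the amplitude envelope, not its square
    return float((u * w).sum() / w.sum())


def _burst(t: np.ndarray, centroid_at: float, duration: float,
           decay: float | None, freq: float, amp: float,
           attack: float | None = None) -> np.ndarray:
    """Tone burst whose envelope energy centroid falls at ``centroid_at``.

    Envelope: Hann window times an exponential decay (``decay``) and/or a
    reversed-exponential attack (``attack``, slow swell with a sharp stop).
    """
    onset = centroid_at - _env_centroid(duration, decay, attack)
    u = t - onset
    mask = (u >= 0) & (u <= duration)
    out = np.zeros_like(t)
    um = u[mask]
    env = np.sin(np.pi * um / duration) ** 2
    if decay is not None:
        env = env * np.exp(-um / decay)
    if attack is not None:
        env = env * np.exp((um - duration) / attack)
    out[mask] = amp * env * np.sin(2 * np.pi * freq * um)
    return out


def _murmur(t: np.ndarray, t0: float, t1: float, taper: float,
            freq: float, amp: float) -> np.ndarray:
    """Sustained tone on [t0, t1] with raised-cosine tapers at both ends."""
    if t1 - t0 <= 2 * taper:
        return np.zeros_like(t)
    u = t - t0
    dur = t1 - t0
    mask = (u >= 0) & (u <= dur)
    out = np.zeros_like(t)
    um = u[mask]
    env = np.ones_like(um)
    head = um < taper
    tail = um > dur - taper
    env[head] = (1 - np.cos(np.pi * um[head] / taper)) / 2
    env[tail] = (1 - np.cos(np.pi * (dur - um[tail]) / taper)) / 2
    out[mask] = amp * env * np.sin(2 * np.pi * freq * um)
    return out


def render_signals(truth: GroundTruth,
                   sampling_rate: float = 1000.0,
                   noise: NoiseConfig | None = None,
                   seed: int | None = 0,
                   coupling: CouplingConfig | None = None,
                   preset: HemodynamicPreset | None = None) -> SignalRecord:
    """Render the four channels for one protocol step from its ground truth.

    Noise-free guarantees (each covered by a test):

    * LVP equals ``edp[i]`` at ``r_times[i]`` and ``esp[i]`` at
      ``end_systole_times[i]``; its maximum finite-difference slope in beat
      ``i`` equals ``dpdtmax[i]`` to within discretization error.
    * The POX maximum-upslope instant lags ``r_times[i]`` by ``ptt[i]``
      to within one sample.
    * MIC is exactly zero outside the S1/S2 burst supports.
    """
    if sampling_rate < 250:
        raise SimulationError("sampling_rate must be >= 250 Hz")
    if truth.n_beats < 1:
        raise SimulationError("ground truth is empty")
    coupling = coupling if coupling is not None else default_coupling(preset)
    noise = noise or NoiseConfig()

    fs = float(sampling_rate)
    n = int(round(truth.duration * fs))
    t = np.arange(n) / fs
    r = truth.r_times
    nb = truth.n_beats

    mean_edp = float(np.mean(truth.edp))
    mean_esp = float(np.mean(truth.esp))
    mean_dpdt = float(np.mean(truth.dpdtmax))

    ecg = np.zeros(n)
    lvp = np.full(n, truth.edp[0])
    mic = np.zeros(n)
    pox = np.zeros(n)

    def clip_idx(t0: float, t1: float) -> slice:
        return slice(max(0, int(np.floor(t0 * fs))), min(n, int(np.ceil(t1 * fs)) + 1))

    for i in range(nb):
        r0, r1, t_es = r[i], r[i + 1], truth.end_systole_times[i]
        rr = r1 - r0
        edp1 = truth.edp[i + 1] if i + 1 < nb else truth.edp[i]
        sl = clip_idx(r0, r1)
        tt = t[sl]
        if len(tt) == 0:
            continue
        inbeat = (tt >= r0) & (tt < r1)
        lvp[sl][...] = np.where(
            inbeat,
            _lvp_beat(tt, r0, r1, t_es, truth.edp[i], edp1, truth.esp[i],
                      truth.dpdtmax[i], coupling.peak_excess, coupling.fall_duration),
            lvp[sl])

        # ECG: Gaussian R bump at r0 plus a broader T bump before end-systole
        # (acoustic couplings computed below use these per-beat fractions)
        qsl = clip_idx(r0 - 0.04, r0 + 0.04)
        ecg[qsl] += 0.8e-3 * np.exp(-0.5 * ((t[qsl] - r0) / 0.006) ** 2)
        tsl = clip_idx(t_es - 0.12, t_es + 0.04)
        ecg[tsl] += 0.2e-3 * np.exp(-0.5 * ((t[tsl] - (t_es - 0.04)) / 0.02) ** 2)

        # MIC: S1 complex at the R peak, S2 at end-systole
        ed_frac = (truth.edp[i] - mean_edp) / mean_edp
        es_frac = (truth.esp[i] - mean_esp) / mean_esp
        dd_frac = (truth.dpdtmax[i] - mean_dpdt) / mean_dpdt
        a1 = coupling.s1_gain * (1 + coupling.s1_amp_slope * dd_frac)
        f1 = coupling.s1_freq * (1 + coupling.s1_freq_slope * ed_frac)
        a2 = (coupling.s1_gain / coupling.s1_s2_ratio) * (
            1 + coupling.s2_amp_slope * es_frac)
        f2 = coupling.s2_freq * (1 + coupling.s2_freq_slope * dd_frac)
        # support-centre both bursts: centroid_at = fiducial + (centroid - D/2)
        c_off = _env_centroid(coupling.burst_duration, coupling.burst_decay,
                              None) - coupling.burst_duration / 2
        s1_at = r0 + c_off
        s1l = clip_idx(s1_at - coupling.burst_duration, s1_at + coupling.burst_duration)
        mic[s1l] += _burst(t[s1l], s1_at, coupling.burst_duration,
                           coupling.burst_decay, f1, max(a1, 0.0))

        # ejection murmur (mid-systole) and rumble (mid-diastole), mirrored
        # about end-systole
        fm = coupling.murmur_freq * (1 + coupling.murmur_freq_slope * dd_frac)
        am = coupling.s1_gain * coupling.murmur_rel_amp * (
            1 + coupling.murmur_amp_slope * dd_frac)
        g = coupling.murmur_gap
        msl = clip_idx(r0 + g, t_es - g)
        mic[msl] += _murmur(t[msl], r0 + g, t_es - g, coupling.murmur_taper,
                            fm, max(am, 0.0))
        fr = coupling.rumble_freq * (1 + coupling.rumble_freq_slope * es_frac)
        ar = coupling.s1_gain * coupling.rumble_rel_amp * (
            1 + coupling.rumble_amp_slope * es_frac)
        dsl = clip_idx(t_es + g, r1 - g)
        mic[dsl] += _murmur(t[dsl], t_es + g, r1 - g, coupling.murmur_taper,
                            fr, max(ar, 0.0))
        s2_at = t_es + c_off
        s2l = clip_idx(s2_at - coupling.burst_duration, s2_at + coupling.burst_duration)
        mic[s2l] += _burst(t[s2l], s2_at, coupling.burst_duration,
                           coupling.burst_decay, f2, max(a2, 0.0))

        # POX: asymmetric plethysmographic pulse — fast raised-cosine rise
        # (maximum upslope at its midpoint, lagging r0 by exactly ptt),
        # slower raised-cosine decay
        tr_ = coupling.pox_rise
        td = min(0.30, max(0.10, 0.8 * rr - tr_))
        t0 = r0 + truth.ptt[i] - tr_ / 2
        amp = 1.0 * (1 + coupling.pox_amp_slope * (truth.esp[i] - mean_esp) / mean_esp)
        psl = clip_idx(t0, t0 + tr_ + td)
        up = t[psl] - t0
        rising = (up >= 0) & (up <= tr_)
        falling = (up > tr_) & (up <= tr_ + td)
        pulse = np.zeros_like(up)
        pulse[rising] = amp * (1 - np.cos(np.pi * up[rising] / tr_)) / 2
        pulse[falling] = amp * (1 + np.cos(np.pi * (up[falling] - tr_) / td)) / 2
        pox[psl] += pulse

    # fill any samples after the last fence post (should not happen: the
    # generator always overshoots the duration) and before the first beat
    lvp[t < r[0]] = truth.edp[0]

    channels = {"ECG": ecg, "LVP": lvp, "MIC": mic, "POX": pox}
    snrs = {"ECG": noise.ecg_snr_db, "LVP": noise.lvp_snr_db,
            "MIC": noise.mic_snr_db, "POX": noise.pox_snr_db}
    root = np.random.SeedSequence([0x0153, int(seed or 0)])
    for (name, x), seq in zip(channels.items(), root.spawn(4)):
        snr = snrs[name]
        if snr is not None:
            rms = float(np.sqrt(np.mean(x ** 2)))
            std = rms / 10 ** (snr / 20.0)
            x += np.random.default_rng(seq).normal(0.0, std, size=n)

    return SignalRecord(sampling_rate=fs, channels=channels,
                        step_label=truth.step_label)


def simulate_study(protocol: ProtocolSpec | None = None,
                   preset: HemodynamicPreset | str = "hfref",
                   coupling: CouplingConfig | None = None,
                   noise: NoiseConfig | None = None,
                   sampling_rate: float = 1000.0,
                   seed: int = 0) -> list[tuple[SignalRecord, GroundTruth]]:
    """Simulate a full pacing study: one (record, truth) pair per step."""
    if isinstance(preset, str):
        preset = PRESETS[preset]()
    protocol = protocol or default_protocol(spontaneous_hr=preset.mean_hr)
    coupling = coupling if coupling is not None else default_coupling(preset)
    truths = simulate_hemodynamics(protocol, preset, coupling, seed)
    out = []
    for k, truth in enumerate(truths):
        record = render_signals(truth, sampling_rate, noise,
                                seed=int(seed) * 1000 + k, coupling=coupling)
        out.append((record, truth))
    return out


def write_study(pairs: list[tuple[SignalRecord, GroundTruth]],
                out_dir, manifest: dict | None = None) -> None:
    """Write per-step signal CSVs, a ground-truth CSV and a JSON manifest."""
    import json
    from pathlib import Path

    from .signal_io import write_record

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["step,beat_index,r_time_s,r_time_end_s,end_systole_s,"
            "edp_mmHg,esp_mmHg,dpdtmax_mmHg_s,ptt_s"]
    for record, truth in pairs:
        write_record(record, out_dir / f"signals_{truth.step_label}.csv", "csv")
        for i in range(truth.n_beats):
            rows.append(f"{truth.step_label},{i},{truth.r_times[i]:.6f},"
                        f"{truth.r_times[i + 1]:.6f},{truth.end_systole_times[i]:.6f},"
                        f"{truth.edp[i]:.6f},{truth.esp[i]:.6f},"
                        f"{truth.dpdtmax[i]:.6f},{truth.ptt[i]:.6f}")
    (out_dir / "ground_truth.csv").write_text("\n".join(rows) + "\n")
    if manifest is not None:
        (out_dir / "simulation_manifest.json").write_text(json.dumps(manifest, indent=2))
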